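"""Phylogeny stage: degap/concatenate/fill rules, p-distances, NJ
correctness on additive matrices (with an independent library
cross-check), bootstrap supports, and the group-indel scan."""

from __future__ import annotations

import numpy as np
import pytest

from treeutils import (
    leaf_dist_from_tree_node as _leaf_dist_from_tree_node,
    random_tree as _random_tree,
    tree_distance_matrix as _tree_distance_matrix,
    two_clade_supermatrix as _two_clade_supermatrix,
)

from sigbin.phylo import (
    MarkerAlignment,
    TreeNode,
    bipartitions,
    bootstrap_supports,
    concatenate,
    degap,
    find_group_indels,
    nj_tree,
    p_distance_matrix,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def aln(marker="m", **rows):
    return MarkerAlignment(marker_id=marker, rows=dict(rows))


# --- degap ------------------------------------------------------------


def test_degap_leaves_gapless_alignment_unchanged():
    a = aln(g1="MKV", g2="MKL")
    assert degap(a).rows == a.rows


def test_degap_removes_any_gapped_column_by_default():
    a = aln(g1="MKVLA", g2="MK-LA")
    d = degap(a)
    assert d.rows == {"g1": "MKLA", "g2": "MKLA"}
    assert d.length == a.length - 1


def test_degap_matches_column_scan_oracle_and_is_idempotent():
    rng = np.random.default_rng(5)
    n, L = 6, 80
    rows = {}
    for i in range(n):
        chars = rng.choice(list(AA), size=L)
        gaps = rng.random(L) < 0.1
        rows[f"g{i}"] = "".join("-" if g else c for c, g in zip(chars, gaps))
    a = MarkerAlignment(marker_id="m", rows=rows)
    keep = [
        j
        for j in range(L)
        if all(rows[f"g{i}"][j] != "-" for i in range(n))
    ]
    d = degap(a)
    for i in range(n):
        assert d.rows[f"g{i}"] == "".join(rows[f"g{i}"][j] for j in keep)
    assert degap(d).rows == d.rows


def test_degap_all_columns_removed_is_an_error():
    with pytest.raises(ValueError):
        degap(aln(g1="M-", g2="-M"))


# --- concatenation + fill rule ---------------------------------------


def test_concatenation_adds_marker_lengths():
    m1 = aln("m1", g1="MKVLAKTTLE", g2="MKVLAKTTLD")
    m2 = aln("m2", g1="WYADECES", g2="WYADECEC")
    sm = concatenate([m1, m2], ["g1", "g2"])
    assert sm.length == 18
    assert sm.boundaries == [("m1", 0, 10), ("m2", 10, 18)]


def test_missing_genome_gets_gap_fill_of_degapped_length():
    m1 = aln("m1", g1="MKVLAKTTLE", g2="MKVLAKTTLD", g3="MKVLAKTSLD")
    m2 = aln("m2", g1="WYADECES", g2="WYADECEC")
    sm = concatenate([m1, m2], ["g1", "g2", "g3"])
    assert sm.rows["g3"][10:18] == "-" * 8
    assert sm.rows["g3"][:10] == "MKVLAKTSLD"


def test_genome_absent_from_all_markers_is_an_error():
    m1 = aln("m1", g1="MKV", g2="MKL")
    with pytest.raises(ValueError):
        concatenate([m1], ["g1", "g2", "ghost"])


def test_marker_order_does_not_change_p_distances():
    m1 = aln("m1", g1="MKVLAKTTLE", g2="MKVLAKTTLD", g3="MKVAAKTSLD")
    m2 = aln("m2", g1="WYADECES", g2="WYADECEC", g3="WYLDECEC")
    d12 = p_distance_matrix(concatenate([m1, m2], ["g1", "g2", "g3"]))
    d21 = p_distance_matrix(concatenate([m2, m1], ["g1", "g2", "g3"]))
    np.testing.assert_allclose(d12, d21)


# --- p-distance -------------------------------------------------------


def test_p_distance_basic_counts():
    sm = concatenate([aln("m", a="AAAA", b="AAAT", c="AAAA")], ["a", "b", "c"])
    D = p_distance_matrix(sm)
    assert D[0, 1] == pytest.approx(0.25)
    assert D[0, 2] == 0.0
    assert (np.diag(D) == 0).all()


def test_fill_rule_gaps_excluded_from_denominator():
    """Hand-counted 3-genome toy: the filled region does not count as
    mismatch or as comparable length."""
    m1 = aln("m1", a="MKVL", b="MKVI", c="MKVL")
    m2 = aln("m2", a="WYAD", b="WYAD")  # c missing -> filled with '----'
    sm = concatenate([m1, m2], ["a", "b", "c"])
    D = p_distance_matrix(sm)
    # a vs c: comparable columns = 4 (marker 1 only), 0 mismatches
    assert D[0, 2] == 0.0
    # b vs c: comparable columns = 4, 1 mismatch (L vs I)
    assert D[1, 2] == pytest.approx(1 / 4)
    # a vs b: comparable columns = 8, 1 mismatch
    assert D[0, 1] == pytest.approx(1 / 8)


# --- neighbor joining -------------------------------------------------


def test_three_taxon_closed_form():
    D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = nj_tree(D, ["a", "b", "c"])
    lengths = {c.name: c.length for c in tree.children}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2, abs=1e-9)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2, abs=1e-9)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2, abs=1e-9)


def test_four_taxon_additive_topology():
    # tree ((A,B),(C,D)) with internal branch 0.2
    D = np.array(
        [
            [0.0, 0.3, 0.9, 1.0],
            [0.3, 0.0, 1.0, 1.1],
            [0.9, 1.0, 0.0, 0.5],
            [1.0, 1.1, 0.5, 0.0],
        ]
    )
    tree = nj_tree(D, list("ABCD"))
    assert frozenset("AB") in bipartitions(tree) or frozenset("CD") in bipartitions(tree)


@pytest.mark.parametrize("trial", range(20))
def test_nj_recovers_random_additive_trees_exactly(trial):
    """Generate a random 5–8 taxon tree, read off its additive distance
    matrix, and demand exact topology and branch-length recovery."""
    rng = np.random.default_rng(300 + trial)
    n = int(rng.integers(5, 9))
    parent, lengths = _random_tree(rng, n)
    D = _tree_distance_matrix(parent, lengths, n)
    labels = [f"t{i}" for i in range(n)]
    tree = nj_tree(D, labels)
    names, D_rec = _leaf_dist_from_tree_node(tree)
    order = [names.index(l) for l in labels]
    np.testing.assert_allclose(D_rec[np.ix_(order, order)], D, atol=1e-9)


def test_nj_topology_agrees_with_independent_library():
    """Cross-check against scikit-bio's neighbour joining on a noisy
    (non-additive) matrix: same unrooted topology."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(77)
    n = 7
    parent, lengths = _random_tree(rng, n)
    D = _tree_distance_matrix(parent, lengths, n)
    D += rng.uniform(0, 0.02, size=D.shape)
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    labels = [f"t{i}" for i in range(n)]
    ours = bipartitions(nj_tree(D, labels))
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
    theirs = set()
    for node in sk_tree.non_tips():
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < n - 1:
            side = frozenset(labels) - below if "t0" in below else below
            theirs.add(side)
    assert ours == theirs


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1], [2, 0]]), ["a", "b"])


# --- bootstrap --------------------------------------------------------


def test_single_replicate_supports_are_binary():
    sm = _two_clade_supermatrix(seed=1)
    tree = bootstrap_supports(sm, n_reps=1, seed=3)
    sup = [n.support for n in _internal_nodes(tree)]
    assert sup and all(s in (0.0, 1.0) for s in sup)


def test_bootstrap_reproducible_under_fixed_seed():
    sm = _two_clade_supermatrix(seed=2)
    t1 = bootstrap_supports(sm, n_reps=25, seed=9)
    t2 = bootstrap_supports(sm, n_reps=25, seed=9)
    assert t1.to_newick() == t2.to_newick()


def _internal_nodes(tree):
    out = []

    def walk(n):
        for c in n.children:
            if not c.is_leaf:
                out.append(c)
                walk(c)

    walk(tree)
    return out


# --- group indels -----------------------------------------------------


def _planted_indel_alignment(n_group=4, n_other=5, L=60, span=(20, 22), seed=0):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(AA), size=L))
    rows = {}
    for i in range(n_group):
        rows[f"G{i}"] = base[: span[0]] + "-" * (span[1] - span[0]) + base[span[1] :]
    for i in range(n_other):
        rows[f"O{i}"] = base
    return MarkerAlignment(marker_id="leuS_like", rows=rows)


def test_planted_two_column_deletion_found_as_single_block():
    a = _planted_indel_alignment()
    blocks = find_group_indels(a, [f"G{i}" for i in range(4)])
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.start, b.end, b.kind, b.length) == (20, 22, "deletion", 2)


def test_partial_group_gap_is_not_reported():
    a = _planted_indel_alignment()
    rows = dict(a.rows)
    # one NON-group row also gains a gap inside the block -> not exclusive
    rows["O0"] = rows["O0"][:20] + "-" + rows["O0"][21:]
    a2 = MarkerAlignment(marker_id="m", rows=rows)
    blocks = find_group_indels(a2, [f"G{i}" for i in range(4)])
    assert all(not (b.start <= 20 < b.end) for b in blocks)


def test_insertion_kind_detected():
    a = _planted_indel_alignment()
    # swap roles: gaps in the complement = insertion relative to the group
    blocks = find_group_indels(a, [f"O{i}" for i in range(5)])
    assert len(blocks) == 1 and blocks[0].kind == "insertion"


def test_indel_scan_invariant_under_row_reordering():
    a = _planted_indel_alignment()
    rows_rev = dict(reversed(list(a.rows.items())))
    b1 = find_group_indels(a, [f"G{i}" for i in range(4)])
    b2 = find_group_indels(
        MarkerAlignment(marker_id="leuS_like", rows=rows_rev),
        [f"G{i}" for i in range(4)],
    )
    assert b1 == b2


def test_group_must_be_proper_subset():
    a = _planted_indel_alignment()
    with pytest.raises(ValueError):
        find_group_indels(a, list(a.rows))
    with pytest.raises(ValueError):
        find_group_indels(a, ["nope"])
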