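"""Binning stage: mapping filter, depth accumulation, trimmed-mean
coverage, TNF fingerprints, embedding behaviour, seeded components,
refinement and marker-based QC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

from sigbin import binning
from sigbin.binning import (
    assess_bin,
    coverage_from_mappings,
    embed,
    filter_mappings,
    refine_bin,
    retain_bins,
    reverse_complement,
    seeded_bins,
    tnf,
    tpmean,
)
from sigbin.records import Bin, Contig, CoverageTrack, MappingRecord


def rec(cid, start, end, ident=99.0, frac=0.95, rid="r"):
    return MappingRecord(
        read_id=rid, contig_id=cid, start=start, end=end,
        identity_pct=ident, aligned_fraction=frac,
    )


# --- mapping filter ---------------------------------------------------


def test_filter_keeps_and_drops_at_published_thresholds():
    records = [
        rec("c", 0, 10, ident=96.0, frac=0.95),   # passes
        rec("c", 0, 10, ident=99.0, frac=0.89),   # aligned fraction too low
        rec("c", 0, 10, ident=94.9, frac=0.99),   # identity too low
        rec("c", 0, 10, ident=95.0, frac=0.90),   # exactly at both cuts: kept
    ]
    kept = filter_mappings(records)
    assert kept == [records[0], records[3]]


def test_filter_rejects_malformed_interval_naming_the_record():
    with pytest.raises(ValueError, match="badread"):
        filter_mappings([rec("c", 5, 5, rid="badread")])


def test_filter_is_order_preserving_and_can_empty():
    bad = [rec("c", 0, 9, ident=80.0) for _ in range(5)]
    assert filter_mappings(bad) == []


# --- coverage ---------------------------------------------------------


def test_single_full_length_record_gives_unit_depth():
    track = coverage_from_mappings(("c", 10), [rec("c", 0, 10)])
    assert (track.depth == 1).all()


def test_overlapping_records_stack():
    track = coverage_from_mappings(("c", 10), [rec("c", 0, 6), rec("c", 4, 10)])
    assert track.depth.tolist() == [1, 1, 1, 1, 2, 2, 1, 1, 1, 1]


def test_coverage_matches_per_base_counting_oracle():
    rng = np.random.default_rng(12)
    L = 200
    records = []
    for i in range(50):
        a = int(rng.integers(0, L - 1))
        b = int(rng.integers(a + 1, L + 1))
        records.append(rec("c", a, b, rid=f"r{i}"))
    track = coverage_from_mappings(("c", L), records)
    expected = [
        sum(1 for r in records if r.start <= pos < r.end) for pos in range(L)
    ]
    assert track.depth.tolist() == expected


# --- tpmean -----------------------------------------------------------


def test_tpmean_constant_depth_is_invariant_under_trim():
    track = CoverageTrack("c", np.full(100, 7))
    for trim in (0.0, 0.1, 0.25):
        assert tpmean(track, trim) == 7.0


def test_tpmean_hand_worked_example():
    depths = np.array([0, 0, 5, 5, 5, 5, 5, 5, 100, 100])
    assert tpmean(CoverageTrack("c", depths), 0.10) == pytest.approx(16.25)


def test_tpmean_zero_trim_is_plain_mean():
    rng = np.random.default_rng(0)
    d = rng.integers(0, 50, size=37)
    assert tpmean(CoverageTrack("c", d), 0.0) == pytest.approx(d.mean())


def test_tpmean_errors_when_trim_swallows_everything():
    with pytest.raises(ValueError):
        tpmean(CoverageTrack("c", np.array([1, 2])), 0.5)


@given(
    st.lists(st.integers(min_value=0, max_value=1000), min_size=10, max_size=200)
)
def test_tpmean_equals_sort_and_slice_oracle(depths):
    d = np.array(depths)
    k = int(np.floor(0.1 * d.size))
    expected = float(np.mean(sorted(depths)[k : d.size - k]))
    assert tpmean(CoverageTrack("c", d), 0.10) == expected


# --- TNF --------------------------------------------------------------


def test_homopolymer_mass_splits_between_kmer_and_its_complement():
    v = tnf("A" * 50)
    idx = {k: i for i, k in enumerate(binning.TETRAMERS)}
    assert v[idx["AAAA"]] == pytest.approx(0.5)
    assert v[idx["TTTT"]] == pytest.approx(0.5)
    assert v.sum() == pytest.approx(1.0)


@given(st.text(alphabet="ACGTN", min_size=4, max_size=400))
def test_tnf_reverse_complement_invariance(seq):
    np.testing.assert_allclose(tnf(seq), tnf(reverse_complement(seq)), atol=1e-12)


def test_tnf_matches_window_enumeration_oracle():
    seq = "ACGTACGGTTACGATCCGGA"
    counts = {}
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - 3):
            w = s[i : i + 4]
            counts[w] = counts.get(w, 0) + 1
    total = sum(counts.values())
    v = tnf(seq)
    for i, kmer in enumerate(binning.TETRAMERS):
        assert v[i] == pytest.approx(counts.get(kmer, 0) / total)


def test_tnf_skips_ambiguous_windows_and_handles_all_n():
    v = tnf("N" * 100)
    assert (v == 0).all()
    with pytest.raises(ValueError):
        tnf("ACG")


# --- embedding --------------------------------------------------------


def _random_seq(rng, length, gc):
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("GCAT"), size=length, p=p))


def test_embedding_separates_gc_classes():
    """Two genome-like GC classes (0.54 vs 0.46) are separable in the
    t-SNE projection of their TNF fingerprints."""
    rng = np.random.default_rng(42)
    seqs = [_random_seq(rng, 3000, 0.54) for _ in range(25)] + [
        _random_seq(rng, 3000, 0.46) for _ in range(25)
    ]
    labels = [0] * 25 + [1] * 25
    X = np.vstack([tnf(s) for s in seqs])
    emb = embed(X, seed=0)
    assert silhouette_score(emb, labels) > 0.25


def test_embedding_deterministic_and_consistent_for_identical_rows():
    rng = np.random.default_rng(3)
    X = rng.dirichlet(np.ones(256), size=10)
    X = np.vstack([X, X[0]])  # duplicate row
    e1 = embed(X, seed=7)
    e2 = embed(X, seed=7)
    np.testing.assert_array_equal(e1, e2)
    np.testing.assert_allclose(e1[0], e1[-1], atol=1e-6)


def test_embedding_requires_three_rows():
    with pytest.raises(ValueError):
        embed(np.zeros((2, 256)), seed=0)


# --- seeded bins ------------------------------------------------------


def _toy_contigs(rng, n, gc, sample="S", prefix="c", length=3000):
    return [
        Contig(
            id=f"{prefix}{i}", sample_id=sample,
            sequence=_random_seq(rng, length, gc),
        )
        for i in range(n)
    ]


def test_short_contig_excluded_before_binning():
    """A 2.4 kb signature-bearing contig falls below the 2.5 kb floor and
    never seeds a bin."""
    rng = np.random.default_rng(8)
    long_contigs = _toy_contigs(rng, 6, 0.5, prefix="L")
    short = Contig(id="short", sample_id="S", sequence=_random_seq(rng, 2400, 0.5))
    contigs = long_contigs + [short]
    emb = np.array([[i, 0.0] for i in range(len(contigs))])
    bins = seeded_bins(contigs, emb, seed_contigs={"short"}, link_radius_quantile=0.5)
    assert bins == []


def test_no_seeds_means_no_bins():
    rng = np.random.default_rng(9)
    contigs = _toy_contigs(rng, 6, 0.5)
    emb = np.zeros((6, 2))
    assert seeded_bins(contigs, emb, seed_contigs=set()) == []


def test_seeded_component_collects_its_cluster_only():
    rng = np.random.default_rng(10)
    contigs = _toy_contigs(rng, 4, 0.54, prefix="a") + _toy_contigs(
        rng, 4, 0.46, prefix="b"
    )
    emb = np.array(
        [[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1], [50, 50], [50.1, 50], [50, 50.1], [50.1, 50.1]]
    )
    bins = seeded_bins(contigs, emb, seed_contigs={"a0"}, link_radius_quantile=0.25)
    assert len(bins) == 1
    assert sorted(bins[0].contig_ids) == ["a0", "a1", "a2", "a3"]


# --- refinement -------------------------------------------------------


def _const_track(cid, depth, length=1000):
    return CoverageTrack(cid, np.full(length, depth))


def test_refinement_removes_coverage_outlier():
    rng = np.random.default_rng(11)
    ids = [f"c{i}" for i in range(7)]
    contigs = {c.id: c for c in _toy_contigs(rng, 7, 0.50)}
    tracks = {cid: _const_track(cid, 30) for cid in ids}
    tracks["c6"] = _const_track("c6", 10)  # 10 < 30 / 2
    b = Bin(id="b", contig_ids=ids, seed_contigs=["c0"])
    refined = refine_bin(b, contigs, tracks)
    assert "c6" not in refined.contig_ids
    assert set(refined.contig_ids) == set(ids) - {"c6"}


def test_refinement_removes_gc_outlier_but_never_seeds():
    rng = np.random.default_rng(13)
    contigs = {c.id: c for c in _toy_contigs(rng, 6, 0.50)}
    outlier = Contig(id="odd", sample_id="S", sequence=_random_seq(rng, 3000, 0.70))
    contigs["odd"] = outlier
    seed_outlier = Contig(id="seed_odd", sample_id="S",
                          sequence=_random_seq(rng, 3000, 0.70))
    contigs["seed_odd"] = seed_outlier
    ids = sorted(contigs)
    tracks = {cid: _const_track(cid, 25) for cid in ids}
    b = Bin(id="b", contig_ids=ids, seed_contigs=["seed_odd"])
    refined = refine_bin(b, contigs, tracks)
    assert "odd" not in refined.contig_ids
    assert "seed_odd" in refined.contig_ids


def test_refinement_fixed_point_and_order_independence():
    rng = np.random.default_rng(14)
    contigs = {c.id: c for c in _toy_contigs(rng, 9, 0.50)}
    ids = sorted(contigs)
    depths = dict(zip(ids, [30, 31, 29, 30, 28, 32, 10, 90, 30]))
    tracks = {cid: _const_track(cid, d) for cid, d in depths.items()}
    results = []
    for perm_seed in range(5):
        order = list(np.random.default_rng(perm_seed).permutation(ids))
        b = Bin(id="b", contig_ids=order, seed_contigs=[])
        results.append(frozenset(refine_bin(b, contigs, tracks).contig_ids))
    assert len(set(results)) == 1
    (final,) = set(results)
    assert final == frozenset(ids) - {ids[6], ids[7]}
    # a homogeneous bin is already a fixed point
    hom = Bin(id="h", contig_ids=ids[:5], seed_contigs=[])
    tracks_h = {cid: _const_track(cid, 30) for cid in ids[:5]}
    assert refine_bin(hom, contigs, tracks_h).contig_ids == ids[:5]


# --- assessment / retention ------------------------------------------


def test_assess_requires_markers_and_scores_empty_bin_zero():
    b = Bin(id="b", contig_ids=[])
    with pytest.raises(ValueError):
        assess_bin(b, {})
    comp, cont = assess_bin(b, {f"m{i}": 0 for i in range(10)})
    assert comp == 0.0 and cont == 0.0


def test_retention_requires_both_conditions():
    def mk(comp, cont):
        b = Bin(id=f"b{comp}_{cont}", contig_ids=["c"])
        b.completeness_pct, b.contamination_pct = comp, cont
        return b

    bins = [mk(85.0, 9.9), mk(31.0, 9.9), mk(29.0, 0.0), mk(85.0, 50.0)]
    kept = retain_bins(bins)
    assert [b.id for b in kept] == ["b85.0_9.9", "b31.0_9.9"]
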