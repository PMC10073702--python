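"""Concatenated conserved-marker phylogeny and group-specific indel scan.

Workflow: per-marker protein alignments are degapped (any column containing
a gap is removed, by default), tandemly concatenated into a supermatrix —
a genome missing a marker receives a run of ``-`` of that marker's degapped
length — and a neighbor-joining tree is built on p-distances, with
column-bootstrap support values. Group-specific indels are detected on the
*original* (pre-degap) alignments, since degapping removes exactly the
columns of interest.

p-distances are uncorrected (no Poisson/JTT correction); topology-level
agreement, not likelihood, is the contract of the NJ step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MarkerAlignment",
    "Supermatrix",
    "TreeNode",
    "IndelBlock",
    "degap",
    "concatenate",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "find_group_indels",
    "bipartitions",
]

_GAP = "-"
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")


@dataclass
class MarkerAlignment:
    """One marker's multiple protein alignment: genome id -> aligned row."""

    marker_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"marker {self.marker_id!r}: empty alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"marker {self.marker_id!r}: unequal row lengths")
        bad = set("".join(self.rows.values()).upper()) - _ALPHABET
        if bad:
            raise ValueError(
                f"marker {self.marker_id!r}: characters outside 20 aa + X + '-': "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def genomes(self) -> list[str]:
        return list(self.rows)


@dataclass
class Supermatrix:
    """Tandem concatenation of degapped marker alignments."""

    genomes: list[str]
    rows: dict[str, str]
    boundaries: list[tuple[str, int, int]]  # (marker_id, start, end)

    def __post_init__(self) -> None:
        lengths = {len(self.rows[g]) for g in self.genomes}
        if len(lengths) != 1:
            raise ValueError("supermatrix rows have unequal lengths")
        (L,) = lengths
        if self.boundaries:
            if self.boundaries[0][1] != 0 or self.boundaries[-1][2] != L:
                raise ValueError("marker boundaries do not partition the length")
            for (_, _, e), (_, s, _) in zip(self.boundaries, self.boundaries[1:]):
                if e != s:
                    raise ValueError("marker boundaries do not partition the length")

    @property
    def length(self) -> int:
        return len(self.rows[self.genomes[0]])

    def to_array(self) -> np.ndarray:
        """(n_genomes, L) uint8 view of the rows, in genome order."""
        return np.frombuffer(
            "".join(self.rows[g] for g in self.genomes).encode("ascii"),
            dtype=np.uint8,
        ).reshape(len(self.genomes), self.length)


@dataclass
class TreeNode:
    """Node of an unrooted tree, stored rooted at an internal trifurcation.

    ``length`` is the branch to the parent; ``support`` is a bootstrap
    proportion in [0, 1] annotated on internal nodes.
    """

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def to_newick(self, *, with_supports: bool = True) -> str:
        return f"{self._newick(with_supports, root=True)};"

    def _newick(self, with_supports: bool, root: bool = False) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick(with_supports) for c in self.children)
        label = ""
        if with_supports and self.support is not None:
            label = f"{self.support:.4g}"
        elif self.name:
            label = self.name
        if root:
            return f"({inner}){label}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass(frozen=True)
class IndelBlock:
    """A maximal run of columns gapped in every group member and
    residue-bearing in every non-member (``deletion``), or the reverse
    (``insertion``). Columns index the ORIGINAL marker alignment,
    0-based half-open.
    """

    marker_id: str
    start: int
    end: int
    kind: str  # "deletion" | "insertion"
    group: str

    @property
    def length(self) -> int:
        return self.end - self.start


def degap(aln: MarkerAlignment, max_gap_frac: float = 0.0) -> MarkerAlignment:
    """Remove every column whose gap fraction exceeds ``max_gap_frac``
    (default: any gap removes the column). Idempotent; preserves row order.
    """
    genomes = list(aln.rows)
    mat = np.array([list(aln.rows[g]) for g in genomes])
    gap_frac = (mat == _GAP).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    if not keep.any():
        raise ValueError(f"marker {aln.marker_id!r}: degapping removed all columns")
    return MarkerAlignment(
        marker_id=aln.marker_id,
        rows={g: "".join(mat[i, keep]) for i, g in enumerate(genomes)},
    )


def concatenate(
    alns: Sequence[MarkerAlignment], genomes: Sequence[str]
) -> Supermatrix:
    """Tandemly connect degapped marker alignments in the given order.

    A genome absent from a marker receives a run of ``-`` of that marker's
    (degapped) length — the fill rule — so all rows stay equal-length.
    """
    genomes = list(genomes)
    present = {g for aln in alns for g in aln.rows}
    orphans = [g for g in genomes if g not in present]
    if orphans:
        raise ValueError(f"genomes missing from every marker: {orphans}")
    parts: dict[str, list[str]] = {g: [] for g in genomes}
    boundaries = []
    offset = 0
    for aln in alns:
        L = aln.length
        boundaries.append((aln.marker_id, offset, offset + L))
        offset += L
        for g in genomes:
            parts[g].append(aln.rows.get(g, _GAP * L))
    return Supermatrix(
        genomes=genomes,
        rows={g: "".join(parts[g]) for g in genomes},
        boundaries=boundaries,
    )


def p_distance_matrix(sm: Supermatrix) -> np.ndarray:
    """Pairwise p-distance: mismatches over columns where both rows are
    non-gap. Errors when some pair has zero comparable columns."""
    n = len(sm.genomes)
    if n < 2:
        raise ValueError("p-distance needs >= 2 genomes")
    arr = sm.to_array()
    gap = ord(_GAP)
    nongap = arr != gap
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {sm.genomes[i]!r} "
                    f"and {sm.genomes[j]!r}"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            D[i, j] = D[j, i] = mism / m
    return D


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou–Nei neighbor joining.

    At each step the pair minimizing Q(i, j) = (n-2) d_ij - r_i - r_j is
    joined; ties break on the smallest (i, j) index pair in current node
    order. Negative branch lengths are clamped to zero with the deficit
    shifted to the sister branch. Returns an unrooted tree rooted at the
    final trifurcation (for n = 3, the closed form).
    """
    d = np.asarray(d, dtype=np.float64)
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix and labels are inconsistent")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(d, d.T) or (np.diag(d) != 0).any() or (d < 0).any():
        raise ValueError("matrix must be symmetric, non-negative, zero-diagonal")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    D = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) pair among minimizers, row-major
        flat = np.argmin(Q)
        best = Q.flat[flat]
        ii, jj = np.divmod(flat, m)
        for i in range(m):
            done = False
            for j in range(i + 1, m):
                if Q[i, j] <= best + 1e-12 * max(1.0, abs(best)):
                    ii, jj = i, j
                    done = True
                    break
            if done:
                break
        li = 0.5 * D[ii, jj] + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = D[ii, jj] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[nodes[ii], nodes[jj]])
        nodes[ii].length, nodes[jj].length = li, lj
        dnew = 0.5 * (D[ii, :] + D[jj, :] - D[ii, jj])
        keep = [k for k in range(m) if k not in (ii, jj)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # final trifurcation, closed form
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted tree, each encoded as the
    leaf-name side *not* containing the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = all_leaves - below if anchor in below else below
            splits.add(side)
        return below

    walk(tree)
    return splits


def bootstrap_supports(
    sm: Supermatrix,
    *,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with column-bootstrap supports.

    Columns are resampled with replacement (uniformly over the whole
    supermatrix, ignoring marker boundaries), p-distances and NJ are
    recomputed per replicate, and each internal node of the original tree
    is annotated with the fraction of replicates containing its
    bipartition. Reproducible under a fixed seed.
    """
    tree = nj_tree(p_distance_matrix(sm), sm.genomes)
    counts = {split: 0 for split in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    arr = sm.to_array()
    L = sm.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = arr[:, cols]
        rep_rows = {
            g: rep[i].tobytes().decode("ascii") for i, g in enumerate(sm.genomes)
        }
        rep_sm = Supermatrix(
            genomes=sm.genomes, rows=rep_rows, boundaries=[("all", 0, L)]
        )
        rep_tree = nj_tree(p_distance_matrix(rep_sm), sm.genomes)
        for split in bipartitions(rep_tree):
            if split in counts:
                counts[split] += 1

    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = all_leaves - below if anchor in below else below
            node.support = counts[side] / n_reps
        return below

    annotate(tree)
    return tree


def find_group_indels(
    aln: MarkerAlignment,
    group: Iterable[str],
    *,
    min_len: int = 1,
) -> list[IndelBlock]:
    """Detect group-exclusive indels on the ORIGINAL marker alignment.

    A column is group-deleted iff every group row has ``-`` and every
    non-group row has a residue; group-inserted iff the reverse. Maximal
    runs of same-kind qualifying columns of length >= ``min_len`` are
    reported. Strict exclusivity: one disagreeing row disqualifies the
    column.
    """
    group = set(group)
    rows = set(aln.rows)
    if not group <= rows:
        raise ValueError(f"group genomes not in alignment: {sorted(group - rows)}")
    if not group or not (rows - group):
        raise ValueError("group and its complement must both be non-empty")
    genomes = list(aln.rows)
    mat = np.array([list(aln.rows[g]) for g in genomes])
    in_group = np.array([g in group for g in genomes])
    is_gap = mat == _GAP
    deleted = is_gap[in_group].all(axis=0) & (~is_gap[~in_group]).all(axis=0)
    inserted = (~is_gap[in_group]).all(axis=0) & is_gap[~in_group].all(axis=0)

    blocks: list[IndelBlock] = []
    for kind, mask in (("deletion", deleted), ("insertion", inserted)):
        start = None
        for i, flag in enumerate(list(mask) + [False]):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start >= min_len:
                    blocks.append(
                        IndelBlock(
                            marker_id=aln.marker_id,
                            start=start,
                            end=i,
                            kind=kind,
                            group="group",
                        )
                    )
                start = None
    blocks.sort(key=lambda b: (b.start, b.kind))
    return blocks
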