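"""Signature-seeded genome binning from metagenomic contigs.

The stage chain mirrors a MAG-recovery workflow: filter read placements
(aligned fraction >= 0.90, identity >= 95%), accumulate per-base depth,
summarise it as a trimmed mean (drop the top and bottom 10% of depth
values), embed tetranucleotide frequencies in 2-D with t-SNE, link contigs
within a small radius of each other in the embedding, keep only connected
components that contain a signature-bearing seed contig, refine bins by
coverage/GC consistency, and retain bins with >30% completeness and <10%
contamination estimated from single-copy marker counts.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .records import Bin, Contig, CoverageTrack, MappingRecord

__all__ = [
    "filter_mappings",
    "coverage_from_mappings",
    "tpmean",
    "tnf",
    "embed",
    "seeded_bins",
    "refine_bin",
    "assess_bin",
    "retain_bins",
    "TETRAMERS",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
TETRAMERS: tuple[str, ...] = tuple(
    "".join(k) for k in itertools.product(_BASES, repeat=4)
)
_TETRAMER_INDEX = {k: i for i, k in enumerate(TETRAMERS)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def filter_mappings(
    records: Iterable[MappingRecord],
    *,
    min_aligned_fraction: float = 0.90,
    min_identity: float = 95.0,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[MappingRecord]:
    """Keep read placements with aligned fraction >= 0.90 and identity
    >= 95% (both inclusive, as printed); order-preserving."""
    kept = []
    for rec in records:
        rec.validate(
            contig_lengths.get(rec.contig_id) if contig_lengths else None
        )
        if (
            rec.aligned_fraction >= min_aligned_fraction
            and rec.identity_pct >= min_identity
        ):
            kept.append(rec)
    return kept


def coverage_from_mappings(
    contig: Contig | tuple[str, int],
    records: Iterable[MappingRecord],
) -> CoverageTrack:
    """Per-base depth: depth[i] = number of filtered records covering i."""
    if isinstance(contig, Contig):
        cid, length = contig.id, contig.length
    else:
        cid, length = contig
    diff = np.zeros(length + 1, dtype=np.int64)
    for rec in records:
        if rec.contig_id != cid:
            continue
        rec.validate(length)
        diff[rec.start] += 1
        diff[rec.end] -= 1
    return CoverageTrack(contig_id=cid, depth=np.cumsum(diff[:-1]))


def tpmean(track: CoverageTrack | np.ndarray, trim_frac: float = 0.10) -> float:
    """Trimmed-mean depth: sort per-base depths, discard the lowest and
    highest ``floor(trim_frac * L)`` values, average the remainder."""
    depth = track.depth if isinstance(track, CoverageTrack) else np.asarray(track)
    if not 0.0 <= trim_frac < 0.5 + 1e-12:
        raise ValueError("trim_frac must be in [0, 0.5]")
    n = depth.size
    k = math.floor(trim_frac * n)
    if n - 2 * k <= 0:
        raise ValueError(
            f"trim {trim_frac} removes all {n} depth values (contig too short)"
        )
    ordered = np.sort(depth, kind="stable")
    return float(ordered[k : n - k].mean())


def tnf(sequence: str | Contig) -> np.ndarray:
    """Tetranucleotide-frequency fingerprint: counts of all overlapping
    4-mers of the sequence *and* its reverse complement, normalized to sum
    to 1. Windows containing non-ACGT characters are skipped; an
    all-skipped sequence yields the zero vector.
    """
    seq = (sequence.sequence if isinstance(sequence, Contig) else sequence).upper()
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 bp has no tetranucleotides")
    counts = np.zeros(256, dtype=np.float64)
    for s in (seq, reverse_complement(seq)):
        counts += _kmer_counts(s)
    total = counts.sum()
    return counts / total if total > 0 else counts


def _kmer_counts(s: str) -> np.ndarray:
    """Overlapping 4-mer counts; windows with non-ACGT bases are skipped."""
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    code = np.full(raw.size, -1, dtype=np.int64)
    for value, base in enumerate(b"ACGT"):
        code[raw == base] = value
    w0, w1, w2, w3 = code[:-3], code[1:-2], code[2:-1], code[3:]
    ok = (w0 >= 0) & (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
    idx = (w0 * 64 + w1 * 16 + w2 * 4 + w3)[ok]
    return np.bincount(idx, minlength=256).astype(np.float64)


def tnf_matrix(contigs: Sequence[Contig]) -> np.ndarray:
    return np.vstack([tnf(c) for c in contigs])


def embed(
    tnf_mat: np.ndarray,
    *,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """2-D embedding of the TNF matrix for visual/graph binning.

    t-SNE (exact gradient, PCA initialization, fixed seed) by default;
    ``method="pca"`` gives a plain linear projection. The perplexity is
    capped at ``(n - 1) / 3`` so small fixtures remain embeddable.
    Deterministic under a fixed seed.
    """
    X = np.asarray(tnf_mat, dtype=np.float64)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"embedding requires >= 3 contigs, got {n}")
    if method == "pca":
        return PCA(n_components=2, random_state=seed).fit_transform(X)
    if method != "tsne":
        raise ValueError(f"unknown embedding method: {method!r}")
    eff_perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        init="pca",
        random_state=seed,
        method="exact",
        learning_rate="auto",
    )
    return tsne.fit_transform(X)


def seeded_bins(
    contigs: Sequence[Contig],
    embedding: np.ndarray,
    seed_contigs: Iterable[str],
    *,
    length_min: int = 2500,
    link_radius_quantile: float = 0.05,
    tpmeans: Mapping[str, float] | None = None,
    bin_prefix: str = "bin",
) -> list[Bin]:
    """Connected-component binning seeded by signature-bearing contigs.

    Contigs shorter than ``length_min`` (2.5 kb) are excluded first; the
    remaining contigs are linked when their embedding distance is at most
    the ``link_radius_quantile`` quantile of all pairwise distances, and
    each connected component containing at least one seed contig becomes a
    bin. Deterministic replacement for manual boundary drawing on the
    embedding plot.
    """
    if len(contigs) != len(embedding):
        raise ValueError("embedding must cover all contigs passing the length filter")
    seeds = set(seed_contigs)
    keep = [i for i, c in enumerate(contigs) if c.length >= length_min]
    if not any(contigs[i].id in seeds for i in keep):
        logger.warning("no seed contig survives the %d bp length filter", length_min)
        return []
    pts = np.asarray(embedding, dtype=np.float64)[keep]
    kept_contigs = [contigs[i] for i in keep]
    m = len(kept_contigs)
    if m == 1:
        comp_labels = np.zeros(1, dtype=int)
    else:
        dists = pdist(pts)
        radius = float(np.quantile(dists, link_radius_quantile))
        adj = squareform(dists) <= radius
        np.fill_diagonal(adj, False)
        _, comp_labels = connected_components(csr_matrix(adj), directed=False)

    bins: list[Bin] = []
    for label in np.unique(comp_labels):
        members = [kept_contigs[i] for i in np.flatnonzero(comp_labels == label)]
        member_ids = sorted(c.id for c in members)
        comp_seeds = sorted(set(member_ids) & seeds)
        if not comp_seeds:
            continue
        b = Bin(
            id=f"{bin_prefix}{len(bins) + 1}",
            contig_ids=member_ids,
            seed_contigs=comp_seeds,
            median_gc=float(np.median([c.gc for c in members])),
        )
        if tpmeans is not None:
            b.tpmean_coverage = float(
                np.median([tpmeans[c] for c in member_ids if c in tpmeans])
            )
        bins.append(b)
    return bins


def refine_bin(
    bin_: Bin,
    contigs: Mapping[str, Contig],
    tracks: Mapping[str, CoverageTrack],
    *,
    coverage_fold_tol: float = 2.0,
    gc_abs_tol: float = 0.05,
    trim_frac: float = 0.10,
) -> Bin:
    """Coverage/GC consistency refinement (automated rebinning).

    Iterates to a fixed point: at each pass, the bin's median tpmean and
    median GC are computed over current members and every non-seed contig
    whose tpmean falls outside ``[median / fold_tol, median * fold_tol]``
    or whose GC deviates from the median by more than ``gc_abs_tol`` is
    removed (all at once, so the result is independent of contig order).
    Seed contigs are never removed.
    """
    member_ids = list(bin_.contig_ids)
    seeds = set(bin_.seed_contigs)
    tp = {cid: tpmean(tracks[cid], trim_frac) for cid in member_ids}
    gc = {cid: contigs[cid].gc for cid in member_ids}
    while True:
        med_tp = float(np.median([tp[c] for c in member_ids]))
        med_gc = float(np.median([gc[c] for c in member_ids]))
        lo, hi = med_tp / coverage_fold_tol, med_tp * coverage_fold_tol
        drop = [
            c
            for c in member_ids
            if c not in seeds
            and (not (lo <= tp[c] <= hi) or abs(gc[c] - med_gc) > gc_abs_tol)
        ]
        if not drop:
            break
        member_ids = [c for c in member_ids if c not in set(drop)]
    return Bin(
        id=bin_.id,
        contig_ids=member_ids,
        seed_contigs=sorted(seeds),
        tpmean_coverage=float(np.median([tp[c] for c in member_ids])),
        median_gc=float(np.median([gc[c] for c in member_ids])),
        completeness_pct=bin_.completeness_pct,
        contamination_pct=bin_.contamination_pct,
    )


def assess_bin(
    bin_: Bin, marker_copy_counts: Mapping[str, int]
) -> tuple[float, float]:
    """Single-copy-marker completeness and contamination.

    completeness = 100 * (markers present at least once) / |markers|;
    contamination = 100 * sum(max(0, copies - 1)) / |markers|.
    The copy counts come from searching single-copy marker proteins
    against the bin's predicted proteins.
    """
    if not marker_copy_counts:
        raise ValueError("marker set must be non-empty")
    n = len(marker_copy_counts)
    present = sum(1 for c in marker_copy_counts.values() if c >= 1)
    excess = sum(max(0, c - 1) for c in marker_copy_counts.values())
    completeness = 100.0 * present / n
    contamination = 100.0 * excess / n
    bin_.completeness_pct = completeness
    bin_.contamination_pct = contamination
    return completeness, contamination


def retain_bins(
    bins: Sequence[Bin],
    *,
    min_completeness: float = 30.0,
    max_contamination: float = 10.0,
) -> list[Bin]:
    """Keep bins with completeness strictly above 30% and contamination
    strictly below 10% (strict inequalities, as printed)."""
    return [
        b
        for b in bins
        if b.completeness_pct > min_completeness
        and b.contamination_pct < max_contamination
    ]
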