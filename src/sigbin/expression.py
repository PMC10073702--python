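"""Per-gene transcriptional depth statistics.

Gene depths are trimmed means of the per-base coverage track restricted to
the gene's coding interval — the same 10% sort-and-trim rule used for
contig coverage — computed from reads that are assumed to be already
rRNA-depleted (ribosomal-read removal is upstream of this package). The
summary reports the overall mean depth, the fraction of genes strictly
above it, and gene lists above each high-expression threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import tpmean
from .records import CoverageTrack, GeneDepth, GeneInterval

__all__ = ["gene_depths", "depth_summary", "DepthSummary"]

DEFAULT_HIGH_THRESHOLDS = (200.0, 700.0, 1000.0)


def gene_depths(
    genes: Sequence[GeneInterval],
    tracks: Mapping[str, CoverageTrack],
    *,
    trim_frac: float = 0.10,
    trim: bool = True,
) -> list[GeneDepth]:
    """Trimmed-mean depth per gene, ranked descending (ties by gene id).

    ``trim=False`` switches to a plain mean over the coding interval.
    """
    raw: list[tuple[str, float]] = []
    for g in genes:
        if g.contig_id not in tracks:
            raise ValueError(f"gene {g.gene_id!r}: no coverage track for contig "
                             f"{g.contig_id!r}")
        depth = tracks[g.contig_id].depth
        if g.end > depth.size:
            raise ValueError(
                f"gene {g.gene_id!r} interval [{g.start}, {g.end}) exceeds "
                f"contig {g.contig_id!r} length {depth.size}"
            )
        window = depth[g.start : g.end]
        value = tpmean(window, trim_frac) if trim else float(np.mean(window))
        raw.append((g.gene_id, value))
    raw.sort(key=lambda t: (-t[1], t[0]))
    return [
        GeneDepth(gene_id=gid, mean_depth=v, rank=i + 1)
        for i, (gid, v) in enumerate(raw)
    ]


@dataclass
class DepthSummary:
    """Summary of a per-gene depth distribution."""

    n_genes: int
    mean_depth: float
    fraction_above_mean: float
    high_expression: dict[float, list[str]]  # threshold -> gene ids, depth-desc

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"statistic": "n_genes", "value": self.n_genes},
            {"statistic": "mean_depth", "value": self.mean_depth},
            {"statistic": "fraction_above_mean", "value": self.fraction_above_mean},
        ]
        for t, genes in sorted(self.high_expression.items()):
            rows.append({"statistic": f"n_genes_above_{t:g}x", "value": len(genes)})
        return pd.DataFrame(rows)


def depth_summary(
    depths: Sequence[GeneDepth] | Mapping[str, float] | pd.DataFrame,
    *,
    high_thresholds: Sequence[float] = DEFAULT_HIGH_THRESHOLDS,
) -> DepthSummary:
    """Overall mean depth, fraction of genes strictly above it, and the
    genes with depth strictly above each high-expression threshold.

    Accepts the output of :func:`gene_depths`, a ``{gene_id: depth}``
    mapping, or a DataFrame with ``gene_id``/``depth`` columns.
    """
    if isinstance(depths, pd.DataFrame):
        items = list(zip(depths["gene_id"], depths["depth"].astype(float)))
    elif isinstance(depths, Mapping):
        items = [(g, float(v)) for g, v in depths.items()]
    else:
        items = [(d.gene_id, d.mean_depth) for d in depths]
    if not items:
        raise ValueError("no gene depths supplied")
    values = np.array([v for _, v in items])
    mean = float(values.mean())
    frac_above = float((values > mean).mean())
    items_desc = sorted(items, key=lambda t: (-t[1], t[0]))
    high = {
        float(t): [g for g, v in items_desc if v > t] for t in high_thresholds
    }
    return DepthSummary(
        n_genes=len(items),
        mean_depth=mean,
        fraction_above_mean=frac_above,
        high_expression=high,
    )
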