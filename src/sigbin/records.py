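"""Core record types shared across the pipeline.

All coordinates are 0-based half-open throughout the package; any 1-based
interchange format is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeRecord",
    "ProteinRecord",
    "HomologyHit",
    "Contig",
    "MappingRecord",
    "CoverageTrack",
    "Bin",
    "GeneInterval",
    "GeneDepth",
]


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide genome sequence with its (synthetic-only) genus label."""

    id: str
    sequence: str
    genus: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence.upper()
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (s.count("G") + s.count("C")) / acgt


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with its genome of origin."""

    id: str
    sequence: str
    genome_id: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise local protein alignment passing the caller's thresholds.

    ``identity_pct`` is computed over aligned residue pairs (gap columns
    excluded); ``query_cov_pct`` is the aligned query span over the full
    query length. Spans are 0-based half-open.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    query_cov_pct: float
    raw_score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")
        if not (0.0 <= self.query_cov_pct <= 100.0):
            raise ValueError(f"query_cov_pct out of range: {self.query_cov_pct}")


@dataclass(frozen=True)
class Contig:
    """An assembled nucleotide sequence belonging to one sample."""

    id: str
    sample_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence.upper()
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (s.count("G") + s.count("C")) / acgt


@dataclass(frozen=True)
class MappingRecord:
    """A read placement on a contig (no read sequence is kept).

    ``aligned_fraction`` is the fraction of the read's length that aligned,
    mirroring the read-filter semantics of BamM-style "coverage".
    """

    read_id: str
    contig_id: str
    start: int
    end: int
    identity_pct: float
    aligned_fraction: float

    def validate(self, contig_length: int | None = None) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"mapping record {self.read_id!r} on {self.contig_id!r}: "
                f"malformed interval [{self.start}, {self.end})"
            )
        if contig_length is not None and self.end > contig_length:
            raise ValueError(
                f"mapping record {self.read_id!r}: end {self.end} exceeds "
                f"contig {self.contig_id!r} length {contig_length}"
            )


@dataclass
class CoverageTrack:
    """Per-base read depth over one contig."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")


@dataclass
class Bin:
    """A set of contigs recovered as one putative genome."""

    id: str
    contig_ids: list[str]
    seed_contigs: list[str] = field(default_factory=list)
    tpmean_coverage: float = float("nan")
    median_gc: float = float("nan")
    completeness_pct: float = float("nan")
    contamination_pct: float = float("nan")

    def __post_init__(self) -> None:
        missing = set(self.seed_contigs) - set(self.contig_ids)
        if missing:
            raise ValueError(f"seed contigs not in bin: {sorted(missing)}")


@dataclass(frozen=True)
class GeneInterval:
    """A coding region on a contig, 0-based half-open."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must precede end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneDepth:
    """Trimmed-mean transcriptional depth of one gene, with its rank."""

    gene_id: str
    mean_depth: float
    rank: int

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
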