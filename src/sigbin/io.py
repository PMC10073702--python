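"""File formats: FASTA, aligned FASTA, Newick, tab-separated tables.

All tables are tab-delimited with a header row, UTF-8, ``\\n`` line
endings (CRLF input is accepted and normalized). FASTA wraps at 80
columns. Coordinates on disk are 0-based half-open, matching the
in-memory convention. Newick support values are stored as internal node
labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import MarkerAlignment, TreeNode
from .records import Contig, GenomeRecord, MappingRecord, ProteinRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "read_proteins",
    "read_contigs",
    "write_alignment",
    "read_alignment",
    "write_mappings",
    "read_mappings",
    "mappings_to_records",
    "write_newick",
    "read_newick",
    "write_table",
    "read_table",
]

MAPPING_COLUMNS = [
    "read_id",
    "contig_id",
    "start",
    "end",
    "identity_pct",
    "aligned_fraction",
]


def write_fasta(
    records: Iterable[GenomeRecord | ProteinRecord | Contig | tuple[str, str]],
    path: str | Path,
) -> None:
    """Write sequences as FASTA, wrapped at 80 columns."""
    seqs = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec
        else:
            rid, seq = rec.id, rec.sequence
        seqs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seqs)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) pairs."""
    try:
        return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTA ({exc})") from exc


def read_proteins(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rid, sequence=seq, genome_id=genome_id)
        for rid, seq in read_fasta(path)
    ]


def read_contigs(path: str | Path, sample_id: str = "sample") -> list[Contig]:
    return [
        Contig(id=rid, sample_id=sample_id, sequence=seq)
        for rid, seq in read_fasta(path)
    ]


def write_alignment(aln: MarkerAlignment, path: str | Path) -> None:
    write_fasta(list(aln.rows.items()), path)


def read_alignment(path: str | Path, marker_id: str | None = None) -> MarkerAlignment:
    rows = dict(read_fasta(path))
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return MarkerAlignment(
        marker_id=marker_id or Path(path).stem, rows=rows
    )


def write_mappings(mappings: pd.DataFrame, path: str | Path) -> None:
    mappings.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_mappings(path: str | Path) -> pd.DataFrame:
    """Read the tabular mapping dialect; CRLF line endings are normalized."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises several parse error types
        raise ValueError(f"{path}: malformed mapping table ({exc})") from exc
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mapping table lacks columns {missing}")
    return df[MAPPING_COLUMNS]


def mappings_to_records(df: pd.DataFrame) -> list[MappingRecord]:
    return [
        MappingRecord(
            read_id=str(r.read_id),
            contig_id=str(r.contig_id),
            start=int(r.start),
            end=int(r.end),
            identity_pct=float(r.identity_pct),
            aligned_fraction=float(r.aligned_fraction),
        )
        for r in df.itertuples(index=False)
    ]


def write_newick(tree: TreeNode, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> TreeNode:
    """Parse Newick (supports stored as internal labels) into a TreeNode."""
    try:
        clade = Phylo.read(str(path), "newick").root
    except Exception as exc:
        raise ValueError(f"{path}: malformed Newick ({exc})") from exc

    def convert(c) -> TreeNode:
        node = TreeNode(
            name=c.name if not c.clades else None,
            length=float(c.branch_length or 0.0),
        )
        if c.clades:
            node.children = [convert(k) for k in c.clades]
            label = c.name if c.name else (
                str(c.confidence) if c.confidence is not None else None
            )
            if label is not None:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        return node

    return convert(clade)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
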