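"""Pairwise protein homology search.

This is the computational primitive behind signature-protein discovery and
sample screening: optimal local (Smith–Waterman) alignment under BLOSUM62
with affine gaps, thresholded on percent identity and query coverage.

Conventions
-----------
* A gap of length ``k`` costs ``gap_open + k * gap_extend`` (BLAST-style;
  defaults 11 and 1).
* ``identity_pct`` is ``100 * identical / aligned residue pairs`` — gap
  columns are excluded from the denominator.
* ``query_cov_pct`` is the aligned query span over the full query length
  ("query-cover": coverage is of the query only).
* The e-value cut-off used by BLAST-style searches is replaced by a raw
  alignment-score floor (default 50), since e-value calibration requires
  database-size statistics that are out of scope here.
* Among co-optimal alignments the aligner's first reported traceback is
  used.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .records import Contig, HomologyHit, ProteinRecord

__all__ = [
    "AMINO_ACIDS",
    "align_pair",
    "search",
    "find_orfs",
    "make_aligner",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
_ALLOWED = AMINO_ACIDS | {"X"}

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_SCORE_FLOOR = 50.0

_STOPS = {"TAA", "TAG", "TGA"}


def _check_protein(seq: str, role: str) -> str:
    if not seq:
        raise ValueError(f"{role} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(
            f"{role} sequence contains residues outside the 20 amino acids + X: "
            f"{sorted(bad)}"
        )
    return seq


@lru_cache(maxsize=8)
def make_aligner(
    matrix_name: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    """Build a local protein aligner.

    The substitution matrix is patched so that the ambiguity residue X
    scores 0 against everything.
    """
    matrix = substitution_matrices.load(matrix_name)
    matrix = matrix.copy()
    if "X" in matrix.alphabet:
        for a in matrix.alphabet:
            matrix["X", a] = 0.0
            matrix[a, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # PairwiseAligner charges open_gap_score for the first gap position, so
    # open + k*extend overall means open_gap_score = -(open + extend).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    query: str | ProteinRecord,
    subject: str | ProteinRecord,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> HomologyHit | None:
    """Optimal local alignment of two protein sequences.

    Returns ``None`` when no positive-scoring local alignment exists
    (e.g. fully dissimilar sequences), otherwise a :class:`HomologyHit`
    with identity, query coverage, score and 0-based half-open spans.
    """
    qid = query.id if isinstance(query, ProteinRecord) else "query"
    sid = subject.id if isinstance(subject, ProteinRecord) else "subject"
    qseq = _check_protein(
        query.sequence if isinstance(query, ProteinRecord) else query, "query"
    )
    sseq = _check_protein(
        subject.sequence if isinstance(subject, ProteinRecord) else subject, "subject"
    )
    aligner = make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(qseq, sseq)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(qseq, sseq)))
    blocks_q, blocks_s = alignment.aligned
    identical = 0
    aligned_pairs = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        aligned_pairs += qe - qs
        identical += sum(
            1 for a, b in zip(qseq[qs:qe], sseq[ss:se]) if a == b
        )
    if aligned_pairs == 0:
        return None
    qstart, qend = int(blocks_q[0][0]), int(blocks_q[-1][1])
    sstart, send = int(blocks_s[0][0]), int(blocks_s[-1][1])
    return HomologyHit(
        query_id=qid,
        subject_id=sid,
        identity_pct=100.0 * identical / aligned_pairs,
        query_cov_pct=100.0 * (qend - qstart) / len(qseq),
        raw_score=float(score),
        query_span=(qstart, qend),
        subject_span=(sstart, send),
    )


def search(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    *,
    min_identity: float = 50.0,
    min_qcov: float = 80.0,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[HomologyHit]:
    """All-vs-all thresholded search: best hit per (query, subject) pair.

    A hit is retained when identity >= ``min_identity``, query coverage >=
    ``min_qcov`` and raw score >= ``score_floor`` (all inclusive). The raw
    score is computed first so that sub-floor pairs skip the traceback.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    aligner = make_aligner(matrix, gap_open, gap_extend)
    hits: list[HomologyHit] = []
    for q in queries:
        qseq = _check_protein(q.sequence, f"query {q.id!r}")
        for s in subjects:
            sseq = _check_protein(s.sequence, f"subject {s.id!r}")
            if aligner.score(qseq, sseq) < score_floor:
                continue
            hit = align_pair(
                q, s, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend
            )
            if hit is None:
                continue
            if (
                hit.identity_pct >= min_identity
                and hit.query_cov_pct >= min_qcov
                and hit.raw_score >= score_floor
            ):
                hits.append(hit)
    return hits


def _translate(codons: str) -> str:
    """Translate a codon string; any codon containing a non-ACGT base → X."""
    return str(Seq(codons).translate())


def find_orfs(
    contig: str | Contig,
    min_len_aa: int = 60,
    *,
    id_prefix: str | None = None,
) -> list[ProteinRecord]:
    """Naive six-frame ORF scan: maximal start(ATG)-to-stop open reading
    frames of at least ``min_len_aa`` residues, translated with the
    standard genetic code.

    For each frame and each stop-to-stop segment, the ORF runs from the
    first ATG to the stop codon (exclusive); codons containing N translate
    to X. Output order is deterministic: frames 0..2 forward then 0..2
    reverse, by position within frame. Ids encode frame and 0-based codon
    start as ``<prefix>|orf|<strand><frame>|<pos>``.
    """
    if isinstance(contig, Contig):
        seq = contig.sequence.upper()
        prefix = id_prefix if id_prefix is not None else contig.id
        genome_id = contig.id
    else:
        seq = contig.upper()
        prefix = id_prefix if id_prefix is not None else "contig"
        genome_id = None
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"contig contains non-DNA characters: {sorted(bad)}")

    orfs: list[ProteinRecord] = []
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            start_codon: int | None = None
            n_codons = (len(s) - frame) // 3
            for ci in range(n_codons):
                pos = frame + 3 * ci
                codon = s[pos : pos + 3]
                if codon in _STOPS:
                    if start_codon is not None:
                        aa_len = (pos - start_codon) // 3
                        if aa_len >= min_len_aa:
                            pep = _translate(s[start_codon:pos])
                            orfs.append(
                                ProteinRecord(
                                    id=f"{prefix}|orf|{strand}{frame}|{start_codon}",
                                    sequence=pep,
                                    genome_id=genome_id,
                                )
                            )
                    start_codon = None
                elif start_codon is None and codon == "ATG":
                    start_codon = pos
    return orfs
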