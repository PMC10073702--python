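"""Synthetic community generator with planted ground truth.

Everything the pipeline consumes can be generated here: genomes of a
target genus plus neighbor genera with a controlled GC contrast, planted
genus-exclusive signature genes, universal single-copy marker genes (one
carrying a genus-specific deletion), per-sample contig mixtures with known
coverage, read-to-contig mapping records (with a corrupted fraction to
exercise the mapping filter), and per-gene RNA depth profiles.

Pan-genome structure
--------------------
Three gene classes make signature discovery exact on the fixture:

* *markers* — universal single-copy proteins conserved across genera
  (~70% cross-genus identity), so they fail the absence condition;
* *accessory fillers* — genus-specific genes present in fewer targets
  than the presence threshold requires, so they fail the presence
  condition (<40% identity to anything outside their genus);
* *signatures* — present in (almost) all target genomes, absent
  everywhere else; only these pass both conditions.

Genes evolve by point substitution only (mutated copies of per-genus
ancestors; ~1% within a genus, ~15% genus-to-ancestor for markers), so
marker alignments are exact by construction and the planted indel is the
only gap. GC is controlled by genus-biased codon choice plus compensating
intergenic composition. All randomness derives from the single config
seed; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .phylo import MarkerAlignment
from .records import Contig, GenomeRecord, ProteinRecord

__all__ = [
    "SimConfig",
    "TruthTable",
    "GeneLocation",
    "simulate_genomes",
    "simulate_marker_alignments",
    "simulate_community",
    "simulate_rna_depth",
    "sample_designations",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

# amino acid -> synonymous codons (standard code)
_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

TARGET_GENUS = "TGT"

# per-genome substitution rate from the genus ancestor; keeps within-genus
# signature copies at >= ~96% mutual identity
WITHIN_GENUS_RATE = 0.01
# genus-ancestor divergence from the universal marker ancestor; leaves
# cross-genus marker identity ~70%, comfortably above the 50/80 thresholds
MARKER_GENUS_RATE = 0.15

DESIGNATION_POSITIVE = "positive"
DESIGNATION_CONTAMINATED = "contaminated"
DESIGNATION_NEGATIVE_ZERO = "negative_zero"
DESIGNATION_NEGATIVE_ONE = "negative_one"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic community.

    Defaults mirror the statistical structure of the study this package
    operationalizes: 10 target genomes vs 12 neighbor-genus genomes, a
    0.54-vs-0.46 GC contrast, 3 planted signature genes, 12 universal
    markers (a desk-scale stand-in for the 120-marker set) with a
    2-residue genus-specific deletion in one of them, and 20 samples.
    """

    seed: int = 0
    n_target_genomes: int = 10
    n_neighbor_genera: int = 3
    genomes_per_neighbor: int = 4
    target_gc: float = 0.54
    neighbor_gc: float = 0.46
    genome_length: int = 60_000
    n_genes_per_genome: int = 30
    n_signature_genes: int = 3
    n_markers: int = 12
    marker_length_aa: int = 150
    planted_indel_length: int = 2
    n_samples: int = 20
    contig_length_range: tuple[int, int] = (2_500, 4_500)
    coverage_range: tuple[float, float] = (10.0, 50.0)
    read_length: int = 150
    mean_gene_length_aa: int = 120
    presence_frac: float = 0.9
    corrupt_frac: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "n_target_genomes",
            "n_neighbor_genera",
            "genomes_per_neighbor",
            "genome_length",
            "n_genes_per_genome",
            "n_markers",
            "marker_length_aa",
            "n_samples",
            "read_length",
            "mean_gene_length_aa",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_signature_genes", "planted_indel_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("target_gc", "neighbor_gc"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be strictly between 0 and 1")
        if self.planted_indel_length > self.marker_length_aa - 20:
            raise ValueError("planted indel length exceeds the marker length")
        mean_gene_nt = 3 * self.mean_gene_length_aa + 3
        if self.n_genes_per_genome * mean_gene_nt > self.genome_length:
            raise ValueError(
                "contradictory sizes: n_genes_per_genome * mean gene length "
                f"({self.n_genes_per_genome * mean_gene_nt} bp) exceeds "
                f"genome_length ({self.genome_length} bp)"
            )
        if self.n_genes_per_genome < self.n_markers + self.n_signature_genes + 1:
            raise ValueError(
                "n_genes_per_genome must exceed n_markers + n_signature_genes"
            )
        lo, hi = self.contig_length_range
        if not 0 < lo <= hi:
            raise ValueError("contig_length_range must be a positive (lo, hi) pair")
        lo, hi = self.coverage_range
        if not 0 < lo <= hi:
            raise ValueError("coverage_range must be a positive (lo, hi) pair")
        if not 0.0 < self.presence_frac <= 1.0:
            raise ValueError("presence_frac must be in (0, 1]")
        if not 0.0 <= self.corrupt_frac < 1.0:
            raise ValueError("corrupt_frac must be in [0, 1)")


@dataclass(frozen=True)
class GeneLocation:
    """Placement of one gene family instance on its genome, 0-based
    half-open, including the stop codon."""

    gene: str
    genome: str
    start: int
    end: int
    strand: str


@dataclass
class TruthTable:
    """Planted ground truth for every downstream stage."""

    genome_to_genus: dict[str, str]
    signature_ids: list[str]
    marker_ids: list[str]
    indel_marker: str | None
    indel_span: tuple[int, int] | None
    genome_sequences: dict[str, str] = field(default_factory=dict, repr=False)
    proteins: dict[str, dict[str, str]] = field(default_factory=dict, repr=False)
    gene_locations: dict[str, list[GeneLocation]] = field(
        default_factory=dict, repr=False
    )
    contig_to_genome: dict[str, str] = field(default_factory=dict)
    contig_signatures: dict[str, list[str]] = field(default_factory=dict)
    contig_true_depth: dict[str, float] = field(default_factory=dict)
    sample_designations: dict[str, str] = field(default_factory=dict)
    sample_coverages: dict[str, dict[str, float]] = field(default_factory=dict)
    rna_true_mean: float | None = None
    rna_fraction_above_mean: float | None = None
    rna_high_genes: dict[float, list[str]] | None = None

    @property
    def target_genomes(self) -> list[str]:
        return sorted(
            g for g, genus in self.genome_to_genus.items() if genus == TARGET_GENUS
        )

    @property
    def background_genomes(self) -> list[str]:
        return sorted(
            g for g, genus in self.genome_to_genus.items() if genus != TARGET_GENUS
        )

    def target_contigs(self, sample_id: str | None = None) -> set[str]:
        targets = set(self.target_genomes)
        out = set()
        for cid, genome in self.contig_to_genome.items():
            if genome not in targets:
                continue
            if sample_id is not None and not cid.startswith(f"{sample_id}|"):
                continue
            out.add(cid)
        return out


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream derived from the single config seed."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(_AA), size=length - 1))
    return "M" + body


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    """Point substitutions at the given per-site rate; position 0 (the
    start methionine) is never mutated so genes stay ATG-initiated."""
    chars = list(protein)
    for i in range(1, len(chars)):
        if rng.random() < rate:
            choices = [a for a in _AA if a != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _delete(protein: str, start: int, length: int) -> str:
    return protein[:start] + protein[start + length :]


def _codon_weights(gc: float) -> dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities from i.i.d. base sampling at the
    genus GC target — the GC knob for coding regions."""
    out = {}
    for aa, codons in _CODONS.items():
        w = np.array(
            [
                np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in codon])
                for codon in codons
            ]
        )
        out[aa] = w / w.sum()
    return out


def _reverse_translate(
    rng: np.random.Generator, protein: str, weights: Mapping[str, np.ndarray]
) -> str:
    parts = []
    for aa in protein:
        codons = _CODONS[aa]
        parts.append(codons[rng.choice(len(codons), p=weights[aa])])
    parts.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(parts)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def _genus_names(cfg: SimConfig) -> list[str]:
    return [TARGET_GENUS] + [f"NB{chr(65 + i)}" for i in range(cfg.n_neighbor_genera)]


def _genome_names(cfg: SimConfig) -> dict[str, list[str]]:
    width = max(2, len(str(cfg.n_target_genomes)))
    out = {
        TARGET_GENUS: [
            f"{TARGET_GENUS}{i + 1:0{width}d}" for i in range(cfg.n_target_genomes)
        ]
    }
    for gi in range(cfg.n_neighbor_genera):
        genus = f"NB{chr(65 + gi)}"
        out[genus] = [
            f"{genus}_{j + 1:02d}" for j in range(cfg.genomes_per_neighbor)
        ]
    return out


def simulate_genomes(
    cfg: SimConfig,
) -> tuple[list[GenomeRecord], dict[str, list[ProteinRecord]], TruthTable]:
    """Generate nucleotide genomes and proteomes with planted truth.

    Returns the genome records, per-genome protein lists (protein ids are
    ``<genome>|<gene family>``), and the :class:`TruthTable` that later
    stages extend.
    """
    rng = _rng(cfg, 1)
    genera = _genus_names(cfg)
    names = _genome_names(cfg)
    marker_ids = [f"M{i + 1:02d}" for i in range(cfg.n_markers)]
    signature_ids = [f"SG{i + 1}" for i in range(cfg.n_signature_genes)]
    n_filler = cfg.n_genes_per_genome - cfg.n_markers - cfg.n_signature_genes

    # universal marker ancestors and the planted genus-specific deletion
    marker_anc = {m: _random_protein(rng, cfg.marker_length_aa) for m in marker_ids}
    indel_marker = marker_ids[0] if cfg.planted_indel_length > 0 else None
    indel_span: tuple[int, int] | None = None
    if indel_marker is not None:
        lo = 10
        hi = cfg.marker_length_aa - 10 - cfg.planted_indel_length
        p = int(rng.integers(lo, hi))
        indel_span = (p, p + cfg.planted_indel_length)

    # per-genus marker ancestors (the target genus carries the deletion)
    genus_marker_anc: dict[str, dict[str, str]] = {}
    for genus in genera:
        anc = {
            m: _mutate(rng, marker_anc[m], MARKER_GENUS_RATE) for m in marker_ids
        }
        if genus == TARGET_GENUS and indel_marker is not None:
            anc[indel_marker] = _delete(
                anc[indel_marker], indel_span[0], cfg.planted_indel_length
            )
        genus_marker_anc[genus] = anc

    # signature ancestors exist only in the target genus
    sig_anc = {
        s: _random_protein(rng, cfg.mean_gene_length_aa) for s in signature_ids
    }

    # accessory fillers: genus-specific families; target families are
    # present in fewer genomes than the presence threshold requires
    filler_families: dict[str, dict[str, str]] = {}  # genus -> family -> ancestor
    filler_presence: dict[str, dict[str, list[str]]] = {}  # genus -> family -> genomes
    for genus in genera:
        genomes = names[genus]
        fams: dict[str, str] = {}
        pres: dict[str, list[str]] = {}
        if genus == TARGET_GENUS:
            max_present = max(2, math.ceil(cfg.presence_frac * len(genomes)) - 1)
            max_present = min(max_present, len(genomes))
            n_families = max(n_filler * 2, 1)
            for k in range(n_families):
                fam = f"TF{k + 1:02d}"
                fams[fam] = _random_protein(rng, cfg.mean_gene_length_aa)
                size = int(rng.integers(2, max_present + 1))
                members = rng.choice(genomes, size=size, replace=False)
                pres[fam] = sorted(members)
        else:
            for k in range(n_filler):
                fam = f"{genus}F{k + 1:02d}"
                fams[fam] = _random_protein(rng, cfg.mean_gene_length_aa)
                pres[fam] = list(genomes)
        filler_families[genus] = fams
        filler_presence[genus] = pres

    genome_to_genus: dict[str, str] = {}
    proteins: dict[str, dict[str, str]] = {}
    for genus in genera:
        for g in names[genus]:
            genome_to_genus[g] = genus
            fam_seqs: dict[str, str] = {}
            for m in marker_ids:
                fam_seqs[m] = _mutate(
                    rng, genus_marker_anc[genus][m], WITHIN_GENUS_RATE
                )
            if genus == TARGET_GENUS:
                for s in signature_ids:
                    fam_seqs[s] = _mutate(rng, sig_anc[s], WITHIN_GENUS_RATE)
            for fam, members in filler_presence[genus].items():
                if g in members:
                    fam_seqs[fam] = _mutate(
                        rng, filler_families[genus][fam], WITHIN_GENUS_RATE
                    )
            proteins[g] = fam_seqs

    truth = TruthTable(
        genome_to_genus=genome_to_genus,
        signature_ids=signature_ids,
        marker_ids=marker_ids,
        indel_marker=indel_marker,
        indel_span=indel_span,
        proteins=proteins,
    )

    # assemble nucleotide genomes
    genomes_out: list[GenomeRecord] = []
    proteomes: dict[str, list[ProteinRecord]] = {}
    weights_by_genus = {
        genus: _codon_weights(cfg.target_gc if genus == TARGET_GENUS else cfg.neighbor_gc)
        for genus in genera
    }
    for genus in genera:
        gc_target = cfg.target_gc if genus == TARGET_GENUS else cfg.neighbor_gc
        for g in names[genus]:
            seq, locs = _assemble_genome(
                rng, cfg, g, proteins[g], weights_by_genus[genus], gc_target
            )
            truth.genome_sequences[g] = seq
            truth.gene_locations[g] = locs
            genomes_out.append(GenomeRecord(id=g, sequence=seq, genus=genus))
            proteomes[g] = [
                ProteinRecord(id=f"{g}|{fam}", sequence=s, genome_id=g)
                for fam, s in sorted(proteins[g].items())
            ]
    return genomes_out, proteomes, truth


def _assemble_genome(
    rng: np.random.Generator,
    cfg: SimConfig,
    genome_id: str,
    fam_seqs: Mapping[str, str],
    codon_weights: Mapping[str, np.ndarray],
    gc_target: float,
) -> tuple[str, list[GeneLocation]]:
    """Lay genes (reverse-translated with GC-biased codons, random strand)
    on a backbone of intergenic DNA whose composition is solved to bring
    the whole genome to the genus GC target."""
    fams = list(fam_seqs)
    order = [fams[i] for i in rng.permutation(len(fams))]
    gene_nts = {fam: _reverse_translate(rng, fam_seqs[fam], codon_weights) for fam in order}
    coding_nt = sum(len(s) for s in gene_nts.values())
    intergenic_total = cfg.genome_length - coding_nt
    if intergenic_total < len(order) + 1:
        raise ValueError(
            f"genome {genome_id!r}: genes do not fit in genome_length"
        )
    # split intergenic DNA into n_genes + 1 spacers
    cuts = np.sort(rng.integers(0, intergenic_total + 1, size=len(order)))
    spacer_lens = np.diff(np.concatenate([[0], cuts, [intergenic_total]]))
    coding_gc = sum(_gc_count(s) for s in gene_nts.values())
    p_gc = (gc_target * cfg.genome_length - coding_gc) / intergenic_total
    p_gc = float(np.clip(p_gc, 0.02, 0.98))

    def spacer(n: int) -> str:
        if n == 0:
            return ""
        bases = rng.choice(
            list("GCAT"),
            size=n,
            p=[p_gc / 2, p_gc / 2, (1 - p_gc) / 2, (1 - p_gc) / 2],
        )
        return "".join(bases)

    parts: list[str] = []
    locs: list[GeneLocation] = []
    pos = 0
    for i, fam in enumerate(order):
        sp = spacer(int(spacer_lens[i]))
        parts.append(sp)
        pos += len(sp)
        nt = gene_nts[fam]
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(nt if strand == "+" else _revcomp(nt))
        locs.append(
            GeneLocation(
                gene=fam, genome=genome_id, start=pos, end=pos + len(nt), strand=strand
            )
        )
        pos += len(nt)
    parts.append(spacer(int(spacer_lens[-1])))
    return "".join(parts), locs


def simulate_marker_alignments(
    cfg: SimConfig,
    truth: TruthTable,
    *,
    drop: tuple[str, str] | None = None,
) -> list[MarkerAlignment]:
    """Per-marker protein alignments, exact by construction.

    All marker copies are substitution-only derivatives of one ancestor,
    so rows align column-to-column; the planted deletion appears as a gap
    block spanning ``truth.indel_span`` in every target-genus row of
    ``truth.indel_marker`` and nowhere else. ``drop=(marker_id,
    genome_id)`` omits one row to exercise the supermatrix fill rule.
    """
    if not truth.proteins:
        raise ValueError("simulate_genomes must run first")
    alns: list[MarkerAlignment] = []
    targets = set(truth.target_genomes)
    for m in truth.marker_ids:
        rows: dict[str, str] = {}
        for g in sorted(truth.genome_to_genus):
            if drop is not None and drop == (m, g):
                continue
            seq = truth.proteins[g][m]
            if m == truth.indel_marker and g in targets:
                s, e = truth.indel_span
                seq = seq[:s] + "-" * (e - s) + seq[s:]
            rows[g] = seq
        alns.append(MarkerAlignment(marker_id=m, rows=rows))
    return alns


def sample_designations(cfg: SimConfig) -> dict[str, str]:
    """Deterministic sample manifest designations.

    Roughly half the samples are clean positives (one target genome plus
    neighbors), one sample is a planted-contamination case (two same-genus
    target genomes whose merged bin must fail the contamination cut),
    ~20% are negatives carrying exactly one signature gene, and the rest
    are target-free negatives.
    """
    n = cfg.n_samples
    n_pos = max(1, round(0.5 * n))
    n_contam = 1 if n >= 6 and cfg.n_target_genomes >= 2 else 0
    n_neg_one = max(1, round(0.2 * n)) if n - n_pos - n_contam > 1 else 0
    if cfg.n_signature_genes == 0:
        n_neg_one = 0
    width = max(2, len(str(n)))
    out: dict[str, str] = {}
    for i in range(n):
        sid = f"S{i + 1:0{width}d}"
        if i < n_pos:
            out[sid] = DESIGNATION_POSITIVE
        elif i < n_pos + n_contam:
            out[sid] = DESIGNATION_CONTAMINATED
        elif i < n_pos + n_contam + n_neg_one:
            out[sid] = DESIGNATION_NEGATIVE_ONE
        else:
            out[sid] = DESIGNATION_NEGATIVE_ZERO
    return out


def _fragment(
    rng: np.random.Generator,
    seq_len: int,
    lo: int,
    hi: int,
    protect: Sequence[tuple[int, int]] = (),
) -> list[tuple[int, int]]:
    """Cut [0, seq_len) into contiguous fragments with lengths ~U(lo, hi);
    cut points never fall inside a protected interval (a signature gene)."""
    cuts = []
    pos = 0
    while pos < seq_len:
        end = pos + int(rng.integers(lo, hi + 1))
        if end >= seq_len:
            end = seq_len
        else:
            for s, e in protect:
                if s < end < e:
                    end = e
                    break
        cuts.append((pos, min(end, seq_len)))
        pos = end
    return cuts


def simulate_community(
    cfg: SimConfig,
    truth: TruthTable,
) -> tuple[list[Contig], pd.DataFrame, pd.DataFrame]:
    """Per-sample contig mixtures with mapping records and a manifest.

    Returns ``(contigs, mappings, manifest)``. ``mappings`` is a DataFrame
    with columns ``read_id, contig_id, start, end, identity_pct,
    aligned_fraction`` (0-based half-open). Each contig's post-filter mean
    depth equals its genome's per-sample coverage up to Poisson noise; an
    extra ``corrupt_frac`` of records fails the identity or
    aligned-fraction filter by construction. Contig ids encode
    ``<sample>|<genome>|c<k>`` and the truth table records every contig's
    source genome, intact signature genes and true depth.
    """
    if not truth.genome_sequences:
        raise ValueError("simulate_genomes must run first")
    rng = _rng(cfg, 2)
    designations = sample_designations(cfg)
    truth.sample_designations = dict(designations)
    targets = truth.target_genomes
    neighbors = truth.background_genomes
    lo, hi = cfg.contig_length_range
    cov_lo, cov_hi = cfg.coverage_range

    contigs: list[Contig] = []
    map_rows: list[pd.DataFrame] = []
    manifest_rows: list[dict] = []
    target_cycle = 0

    for sid, desig in designations.items():
        # (genome, id tag, coverage); the contaminated sample carries two
        # strain replicates of one genome at near-identical coverage so
        # their merged bin duplicates every single-copy marker
        emissions: list[tuple[str, str, float]] = []
        partial_sig: tuple[str, str] | None = None  # (genome, sig family)
        if desig == DESIGNATION_POSITIVE:
            g = targets[target_cycle % len(targets)]
            target_cycle += 1
            emissions.append((g, g, round(float(rng.uniform(cov_lo, cov_hi)), 1)))
        elif desig == DESIGNATION_CONTAMINATED:
            g = targets[target_cycle % len(targets)]
            target_cycle += 1
            base = float(rng.uniform(cov_lo, cov_hi))
            emissions.append((g, f"{g}a", round(base, 1)))
            emissions.append((g, f"{g}b", round(base * 1.1, 1)))
        elif desig == DESIGNATION_NEGATIVE_ONE:
            g = targets[int(rng.integers(len(targets)))]
            sigs_on_g = [
                l for l in truth.gene_locations[g] if l.gene in truth.signature_ids
            ]
            partial_sig = (g, sigs_on_g[int(rng.integers(len(sigs_on_g)))].gene)
        n_nbr = min(2 if desig != DESIGNATION_CONTAMINATED else 1, len(neighbors))
        picked = rng.choice(len(neighbors), size=n_nbr, replace=False)
        emissions.extend(
            (neighbors[i], neighbors[i], round(float(rng.uniform(cov_lo, cov_hi)), 1))
            for i in picked
        )

        truth.sample_coverages[sid] = {tag: cov for _, tag, cov in emissions}
        n_sigs_expected = 0

        for g, tag, cov in emissions:
            seq = truth.genome_sequences[g]
            sig_spans = [
                (l.start, l.end)
                for l in truth.gene_locations[g]
                if l.gene in truth.signature_ids
            ]
            frags = _fragment(rng, len(seq), lo, hi, protect=sig_spans)
            n_sigs_expected += _emit_contig_set(
                cfg, rng, truth, contigs, map_rows, sid, g, seq, frags, cov,
                tag=tag,
            )

        if partial_sig is not None:
            g, fam = partial_sig
            cov = round(float(rng.uniform(cov_lo, cov_hi)), 1)
            truth.sample_coverages[sid][g] = cov
            loc = next(
                l for l in truth.gene_locations[g] if l.gene == fam
            )
            pad = int(rng.integers(300, 800))
            a = max(0, loc.start - pad)
            b = min(len(truth.genome_sequences[g]), loc.end + pad)
            # shrink away any second signature caught in the window
            for l in truth.gene_locations[g]:
                if l.gene in truth.signature_ids and l.gene != fam:
                    if a < l.end <= loc.start:
                        a = l.end
                    if loc.end <= l.start < b:
                        b = l.start
            n_sigs_expected += _emit_contig_set(
                cfg, rng, truth, contigs, map_rows, sid, g,
                truth.genome_sequences[g], [(a, b)], cov, tag=g,
            )

        manifest_rows.append(
            {
                "sample_id": sid,
                "designation": desig,
                "genomes": ";".join(sorted(set(truth.sample_coverages[sid]))),
                "n_signature_genes": n_sigs_expected,
            }
        )

    columns = [
        "read_id",
        "contig_id",
        "start",
        "end",
        "identity_pct",
        "aligned_fraction",
    ]
    if map_rows:
        mappings = pd.concat(map_rows, ignore_index=True)[columns]
    else:
        mappings = pd.DataFrame(columns=columns)
    manifest = pd.DataFrame(manifest_rows)
    return contigs, mappings, manifest


def _emit_contig_set(
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: TruthTable,
    contigs: list[Contig],
    map_rows: list[pd.DataFrame],
    sid: str,
    genome: str,
    seq: str,
    frags: Sequence[tuple[int, int]],
    coverage: float,
    *,
    tag: str | None = None,
) -> int:
    """Append contigs for one genome in one sample plus their mapping
    records; returns the number of intact signature genes emitted."""
    n_sigs = 0
    tag = tag or genome
    sig_locs = [
        l for l in truth.gene_locations[genome] if l.gene in truth.signature_ids
    ]
    for k, (a, b) in enumerate(frags):
        cid = f"{sid}|{tag}|c{k + 1:02d}"
        contigs.append(Contig(id=cid, sample_id=sid, sequence=seq[a:b]))
        truth.contig_to_genome[cid] = genome
        intact = sorted(
            l.gene for l in sig_locs if a <= l.start and l.end <= b
        )
        truth.contig_signatures[cid] = intact
        n_sigs += len(intact)
        truth.contig_true_depth[cid] = coverage
        _emit_mappings(cfg, rng, map_rows, cid, b - a, coverage)
    return n_sigs


def _emit_mappings(
    cfg: SimConfig,
    rng: np.random.Generator,
    map_rows: list[pd.DataFrame],
    cid: str,
    length: int,
    coverage: float,
) -> None:
    rl = min(cfg.read_length, length)
    n_good = int(rng.poisson(coverage * length / rl))
    n_bad = (
        int(rng.poisson(cfg.corrupt_frac * max(n_good, 1)))
        if cfg.corrupt_frac > 0
        else 0
    )
    n = n_good + n_bad
    starts = rng.integers(0, max(1, length - rl + 1), size=n)
    idents = np.round(rng.uniform(96.0, 100.0, size=n), 2)
    fracs = np.round(rng.uniform(0.92, 1.0, size=n), 3)
    read_ids = [f"{cid}|r{i}" for i in range(n_good)] + [
        f"{cid}|x{i}" for i in range(n_bad)
    ]
    # corrupted records fail exactly one of the two filters
    bad_ident = rng.random(n_bad) < 0.5
    bi = np.flatnonzero(bad_ident) + n_good
    bf = np.flatnonzero(~bad_ident) + n_good
    idents[bi] = np.round(rng.uniform(80.0, 94.9, size=bi.size), 2)
    fracs[bf] = np.round(rng.uniform(0.50, 0.899, size=bf.size), 3)
    map_rows.append(
        pd.DataFrame(
            {
                "read_id": read_ids,
                "contig_id": cid,
                "start": starts.astype(np.int64),
                "end": starts.astype(np.int64) + rl,
                "identity_pct": idents,
                "aligned_fraction": fracs,
            }
        )
    )


def simulate_rna_depth(
    cfg: SimConfig,
    truth: TruthTable,
) -> pd.DataFrame:
    """Per-gene transcriptional depths for the reference target genome.

    Depths are log-normal across genes with designated high tiers: two
    secretion-system stand-ins above 1,000x, two translocase stand-ins in
    (700, 1,000], three robustly expressed genes in (200, 700]. The truth
    table records the realized mean, the fraction of genes strictly above
    it, and the gene lists above each threshold, all recomputed from the
    emitted table itself so downstream statistics can be checked exactly.
    """
    if not truth.proteins:
        raise ValueError("simulate_genomes must run first")
    rng = _rng(cfg, 3)
    ref = truth.target_genomes[0]
    genes = sorted(truth.proteins[ref])
    n = len(genes)
    depths = np.round(rng.lognormal(mean=np.log(40.0), sigma=1.2, size=n), 1)
    tiers = ["" for _ in genes]
    order = rng.permutation(n)
    tier_plan = [
        ("t2ss_like", 2, (1200.0, 3000.0)),
        ("translocase_like", 2, (750.0, 1000.0)),
        ("secreted_enzyme_like", 3, (250.0, 700.0)),
    ]
    idx = 0
    for name, count, (a, b) in tier_plan:
        for _ in range(min(count, n - idx)):
            gi = order[idx]
            depths[gi] = round(float(rng.uniform(a, b)), 1)
            tiers[gi] = name
            idx += 1
    table = pd.DataFrame(
        {"gene_id": genes, "depth": depths, "tier": tiers}
    ).sort_values("gene_id", ignore_index=True)

    mean = float(table["depth"].mean())
    truth.rna_true_mean = mean
    truth.rna_fraction_above_mean = float((table["depth"] > mean).mean())
    truth.rna_high_genes = {
        t: sorted(table.loc[table["depth"] > t, "gene_id"])
        for t in (200.0, 700.0, 1000.0)
    }
    return table
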