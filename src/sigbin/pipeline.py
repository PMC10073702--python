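"""End-to-end orchestration: discover → screen → bin → QC, with optional
phylogeny/indel and expression stages.

Every stage writes its outputs into the run directory together with a
machine-readable manifest (config hash, package version, stage status).
Identical config + seed gives identical outputs. A stage failure halts the
run with a stage-named error; outputs of completed stages are preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, binning, expression, homology, io, phylo, signatures
from .records import Bin, Contig, CoverageTrack, ProteinRecord
from .simulate import (
    SimConfig,
    TruthTable,
    simulate_community,
    simulate_genomes,
    simulate_marker_alignments,
    simulate_rna_depth,
)

__all__ = ["PipelineConfig", "PipelineInputs", "RunResult", "run_pipeline",
           "simulate_inputs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds with their published defaults."""

    min_identity: float = 50.0  # homology identity %, presence and absence
    min_qcov: float = 80.0  # query-coverage %
    score_floor: float = 50.0  # raw-score stand-in for the e-value cut
    presence_frac: float = 0.9  # fraction of target genomes per signature
    min_hits: int = 2  # distinct signatures for a positive sample
    min_aligned_fraction: float = 0.90  # read filter: aligned fraction
    min_map_identity: float = 95.0  # read filter: identity %
    trim_frac: float = 0.10  # tpmean trim
    length_min: int = 2500  # contig length floor for binning, bp
    link_radius_quantile: float = 0.05  # embedding link radius
    coverage_fold_tol: float = 2.0  # refinement coverage window
    gc_abs_tol: float = 0.05  # refinement GC window
    min_completeness: float = 30.0  # bin retention (strict >)
    max_contamination: float = 10.0  # bin retention (strict <)
    n_bootstrap: int = 1000
    tsne_perplexity: float = 30.0
    high_thresholds: tuple[float, ...] = (200.0, 700.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.min_identity <= 100, "min_identity in [0, 100]"),
            (0 <= self.min_qcov <= 100, "min_qcov in [0, 100]"),
            (0 <= self.min_map_identity <= 100, "min_map_identity in [0, 100]"),
            (0 <= self.min_aligned_fraction <= 1, "min_aligned_fraction in [0, 1]"),
            (0 < self.presence_frac <= 1, "presence_frac in (0, 1]"),
            (self.min_hits >= 1, "min_hits >= 1"),
            (0 <= self.trim_frac < 0.5, "trim_frac in [0, 0.5)"),
            (self.length_min >= 0, "length_min >= 0"),
            (0 < self.link_radius_quantile <= 1, "link_radius_quantile in (0, 1]"),
            (self.coverage_fold_tol >= 1, "coverage_fold_tol >= 1"),
            (self.gc_abs_tol >= 0, "gc_abs_tol >= 0"),
            (self.n_bootstrap >= 1, "n_bootstrap >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"PipelineConfig: {msg}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "high_thresholds" in data:
            data["high_thresholds"] = tuple(data["high_thresholds"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["high_thresholds"] = list(self.high_thresholds)
        return d


@dataclass
class PipelineInputs:
    """Parsed inputs for one run; any optional block switches its stage on."""

    target_proteomes: dict[str, list[ProteinRecord]]
    background_proteomes: dict[str, list[ProteinRecord]]
    contigs: list[Contig]
    mappings: pd.DataFrame
    marker_proteins: list[ProteinRecord]
    marker_alignments: list[phylo.MarkerAlignment] | None = None
    indel_group: list[str] | None = None
    rna_depth_table: pd.DataFrame | None = None
    manifest: pd.DataFrame | None = None


@dataclass
class RunResult:
    outdir: Path
    signature_set: signatures.SignatureSet
    screen_report: pd.DataFrame
    bins: list[Bin]
    retained: list[Bin]
    tree: phylo.TreeNode | None = None
    indels: list[phylo.IndelBlock] = field(default_factory=list)
    depth_summary: expression.DepthSummary | None = None


def simulate_inputs(
    sim_cfg: SimConfig,
) -> tuple[PipelineInputs, TruthTable]:
    """Generate a complete synthetic input bundle with its truth table."""
    genomes, proteomes, truth = simulate_genomes(sim_cfg)
    contigs, mappings, manifest = simulate_community(sim_cfg, truth)
    alns = simulate_marker_alignments(sim_cfg, truth)
    rna = simulate_rna_depth(sim_cfg, truth)
    targets = set(truth.target_genomes)
    ref = truth.target_genomes[0]
    marker_proteins = [
        ProteinRecord(id=f"{ref}|{m}", sequence=truth.proteins[ref][m], genome_id=ref)
        for m in truth.marker_ids
    ]
    inputs = PipelineInputs(
        target_proteomes={g: p for g, p in proteomes.items() if g in targets},
        background_proteomes={g: p for g, p in proteomes.items() if g not in targets},
        contigs=contigs,
        mappings=mappings,
        marker_proteins=marker_proteins,
        marker_alignments=alns,
        indel_group=sorted(targets),
        rna_depth_table=rna,
        manifest=manifest,
    )
    return inputs, truth


def _filter_mappings_df(
    df: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    keep = (df["aligned_fraction"] >= cfg.min_aligned_fraction) & (
        df["identity_pct"] >= cfg.min_map_identity
    )
    return df.loc[keep]


def _coverage_tracks(
    contigs: Sequence[Contig], filtered: pd.DataFrame
) -> dict[str, CoverageTrack]:
    tracks: dict[str, CoverageTrack] = {}
    by_contig = dict(tuple(filtered.groupby("contig_id", sort=False)))
    for c in contigs:
        diff = np.zeros(c.length + 1, dtype=np.int64)
        sub = by_contig.get(c.id)
        if sub is not None:
            np.add.at(diff, sub["start"].to_numpy(), 1)
            np.add.at(diff, sub["end"].to_numpy(), -1)
        tracks[c.id] = CoverageTrack(contig_id=c.id, depth=np.cumsum(diff[:-1]))
    return tracks


def _marker_copy_counts(
    bin_: Bin,
    orfs_by_contig: Mapping[str, list[ProteinRecord]],
    marker_proteins: Sequence[ProteinRecord],
    cfg: PipelineConfig,
) -> dict[str, int]:
    bin_orfs = [o for cid in bin_.contig_ids for o in orfs_by_contig.get(cid, [])]
    counts = {m.id: 0 for m in marker_proteins}
    if not bin_orfs:
        return counts
    hits = homology.search(
        list(marker_proteins),
        bin_orfs,
        min_identity=cfg.min_identity,
        min_qcov=cfg.min_qcov,
        score_floor=cfg.score_floor,
    )
    per_marker: dict[str, set[str]] = {m.id: set() for m in marker_proteins}
    for h in hits:
        per_marker[h.query_id].add(h.subject_id)
    for m, subjects in per_marker.items():
        counts[m] = len(subjects)
    return counts


def run_pipeline(
    cfg: PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
) -> RunResult:
    """Execute discover → screen → bin → qc (and optional phylo, indel,
    expression stages) on parsed inputs, writing all outputs to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "sigbin",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    def _finish_stage(name: str, **info) -> None:
        manifest["stages"][name] = {"status": "ok", **info}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    def _fail_stage(name: str, exc: Exception) -> None:
        manifest["stages"][name] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        logger.error("stage %s failed: %s", name, exc)

    # ---- discover ----------------------------------------------------
    try:
        sigs = signatures.discover_signatures(
            inputs.target_proteomes,
            inputs.background_proteomes,
            presence_frac=cfg.presence_frac,
            min_identity=cfg.min_identity,
            min_qcov=cfg.min_qcov,
            score_floor=cfg.score_floor,
        )
        io.write_fasta(sigs.signatures, outdir / "signatures.faa")
        sigs.presence_matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        _finish_stage("discover", n_signatures=len(sigs))
        logger.info("discover: %d signature proteins", len(sigs))
    except Exception as exc:
        _fail_stage("discover", exc)
        raise RuntimeError(f"stage 'discover' failed: {exc}") from exc

    # ---- screen ------------------------------------------------------
    samples = sorted({c.sample_id for c in inputs.contigs})
    contigs_by_sample: dict[str, list[Contig]] = {s: [] for s in samples}
    for c in inputs.contigs:
        contigs_by_sample[c.sample_id].append(c)
    orfs_by_contig: dict[str, list[ProteinRecord]] = {}
    screen_rows = []
    flagged: dict[str, set[str]] = {}  # sample -> seed contig ids
    try:
        for s in samples:
            sample_orfs: list[ProteinRecord] = []
            for c in contigs_by_sample[s]:
                orfs = homology.find_orfs(c)
                orfs_by_contig[c.id] = orfs
                sample_orfs.extend(orfs)
            flag, hits = (
                signatures.screen_sample(
                    sample_orfs, sigs, min_hits=cfg.min_hits,
                    score_floor=cfg.score_floor,
                )
                if sample_orfs
                else (False, [])
            )
            n_distinct = len({h.query_id for h in hits})
            screen_rows.append(
                {"sample_id": s, "n_signatures_hit": n_distinct, "flag": flag}
            )
            if flag:
                # ORF ids are "<contig>|orf|<strand><frame>|<pos>"
                flagged[s] = {h.subject_id.rsplit("|orf|", 1)[0] for h in hits}
        screen_report = pd.DataFrame(screen_rows)
        io.write_table(screen_report, outdir / "screen_report.tsv")
        _finish_stage("screen", n_flagged=len(flagged))
        logger.info("screen: %d/%d samples flagged", len(flagged), len(samples))
    except Exception as exc:
        _fail_stage("screen", exc)
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    # ---- bin + qc ----------------------------------------------------
    all_bins: list[Bin] = []
    retained: list[Bin] = []
    try:
        filtered = _filter_mappings_df(inputs.mappings, cfg)
        bins_dir = outdir / "bins"
        bins_dir.mkdir(exist_ok=True)
        embed_rows = []
        for s in sorted(flagged):
            sample_contigs = [
                c for c in contigs_by_sample[s] if c.length >= cfg.length_min
            ]
            seeds = flagged[s] & {c.id for c in sample_contigs}
            if len(sample_contigs) < 3 or not seeds:
                logger.warning("sample %s: nothing to bin", s)
                continue
            tracks = _coverage_tracks(sample_contigs, filtered)
            tpmeans = {
                c.id: binning.tpmean(tracks[c.id], cfg.trim_frac)
                for c in sample_contigs
            }
            emb = binning.embed(
                binning.tnf_matrix(sample_contigs),
                seed=cfg.seed,
                perplexity=cfg.tsne_perplexity,
            )
            for c, (x, y) in zip(sample_contigs, emb):
                embed_rows.append(
                    {"sample_id": s, "contig_id": c.id, "x": x, "y": y}
                )
            sample_bins = binning.seeded_bins(
                sample_contigs,
                emb,
                seeds,
                length_min=cfg.length_min,
                link_radius_quantile=cfg.link_radius_quantile,
                tpmeans=tpmeans,
                bin_prefix=f"{s}_bin",
            )
            contig_map = {c.id: c for c in sample_contigs}
            for b in sample_bins:
                b = binning.refine_bin(
                    b,
                    contig_map,
                    tracks,
                    coverage_fold_tol=cfg.coverage_fold_tol,
                    gc_abs_tol=cfg.gc_abs_tol,
                    trim_frac=cfg.trim_frac,
                )
                counts = _marker_copy_counts(
                    b, orfs_by_contig, inputs.marker_proteins, cfg
                )
                binning.assess_bin(b, counts)
                all_bins.append(b)
                io.write_fasta(
                    [(cid, contig_map[cid].sequence) for cid in b.contig_ids],
                    bins_dir / f"{b.id}.fna",
                )
        retained = binning.retain_bins(
            all_bins,
            min_completeness=cfg.min_completeness,
            max_contamination=cfg.max_contamination,
        )
        retained_ids = {b.id for b in retained}
        bins_table = pd.DataFrame(
            [
                {
                    "bin_id": b.id,
                    "n_contigs": len(b.contig_ids),
                    "tpmean": round(b.tpmean_coverage, 3),
                    "gc": round(b.median_gc, 4),
                    "completeness": round(b.completeness_pct, 2),
                    "contamination": round(b.contamination_pct, 2),
                    "retained": b.id in retained_ids,
                }
                for b in all_bins
            ],
            columns=[
                "bin_id", "n_contigs", "tpmean", "gc",
                "completeness", "contamination", "retained",
            ],
        )
        io.write_table(bins_table, outdir / "bins.tsv")
        io.write_table(pd.DataFrame(
            embed_rows, columns=["sample_id", "contig_id", "x", "y"]
        ), outdir / "embedding.tsv")
        _finish_stage("bin_qc", n_bins=len(all_bins), n_retained=len(retained))
        logger.info("bin+qc: %d bins, %d retained", len(all_bins), len(retained))
    except Exception as exc:
        _fail_stage("bin_qc", exc)
        raise RuntimeError(f"stage 'bin_qc' failed: {exc}") from exc

    # ---- phylo + indels (optional) -----------------------------------
    tree = None
    indels: list[phylo.IndelBlock] = []
    if inputs.marker_alignments:
        try:
            degapped = [phylo.degap(a) for a in inputs.marker_alignments]
            genomes = sorted({g for a in degapped for g in a.rows})
            sm = phylo.concatenate(degapped, genomes)
            io.write_alignment(
                phylo.MarkerAlignment(marker_id="supermatrix", rows=sm.rows),
                outdir / "supermatrix.afa",
            )
            tree = phylo.bootstrap_supports(
                sm, n_reps=cfg.n_bootstrap, seed=cfg.seed
            )
            io.write_newick(tree, outdir / "tree.nwk")
            if inputs.indel_group:
                for aln in inputs.marker_alignments:
                    indels.extend(
                        phylo.find_group_indels(aln, inputs.indel_group)
                    )
                io.write_table(
                    pd.DataFrame(
                        [
                            {
                                "marker_id": b.marker_id,
                                "start": b.start,
                                "end": b.end,
                                "kind": b.kind,
                                "length": b.length,
                            }
                            for b in indels
                        ],
                        columns=["marker_id", "start", "end", "kind", "length"],
                    ),
                    outdir / "indels.tsv",
                )
            _finish_stage("phylo", n_indels=len(indels))
        except Exception as exc:
            _fail_stage("phylo", exc)
            raise RuntimeError(f"stage 'phylo' failed: {exc}") from exc

    # ---- expression (optional) ---------------------------------------
    summary = None
    if inputs.rna_depth_table is not None:
        try:
            summary = expression.depth_summary(
                inputs.rna_depth_table, high_thresholds=cfg.high_thresholds
            )
            io.write_table(summary.to_frame(), outdir / "summary.tsv")
            table = inputs.rna_depth_table.sort_values(
                ["depth", "gene_id"], ascending=[False, True]
            ).reset_index(drop=True)
            table["rank"] = np.arange(1, len(table) + 1)
            io.write_table(table, outdir / "gene_depths.tsv")
            _finish_stage(
                "expression",
                mean_depth=summary.mean_depth,
                fraction_above_mean=summary.fraction_above_mean,
            )
        except Exception as exc:
            _fail_stage("expression", exc)
            raise RuntimeError(f"stage 'expression' failed: {exc}") from exc

    return RunResult(
        outdir=outdir,
        signature_set=sigs,
        screen_report=screen_report,
        bins=all_bins,
        retained=retained,
        tree=tree,
        indels=indels,
        depth_summary=summary,
    )
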