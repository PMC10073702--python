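# Methods

This note documents the models, rules and numerical choices behind
`sigbin`, the assumptions they rest on, and what the synthetic ground
truth does and does not establish about real data.

## Homology primitive

All presence/absence decisions reduce to optimal local alignment
(Smith–Waterman) of protein pairs under BLOSUM62 with affine gap costs:
a gap of length *k* costs `gap_open + k · gap_extend` with the
conventional protein-search defaults `gap_open = 11`, `gap_extend = 1`
(both configurable). The engine is Biopython's `PairwiseAligner`; the
test suite checks its scores cell-for-cell against an independent
brute-force dynamic program on random pairs up to length 50.

* **Identity** is `100 × identical / aligned residue pairs`; gap columns
  are excluded from the denominator, matching common BLAST-style
  reporting.
* **Coverage** is of the query only (`query-cover`): aligned query span
  over full query length.
* **Thresholds are inclusive** (`≥ 50%` identity, `≥ 80%` coverage by
  default).
* **E-value substitution.** BLAST's e-value cut (1e-5) needs
  database-size statistics that have no analogue in an in-memory
  all-vs-all search, so it is deliberately replaced by a raw
  alignment-score floor, default 50 (roughly 25 identical residues'
  worth of signal). This is a design substitution, stated here and in
  the module docstring.
* **Ties.** Among co-optimal alignments the aligner's first canonical
  traceback is used; enumerating all co-optima can be combinatorial and
  the downstream statistics (identity, coverage) rarely differ between
  them.
* The residue `X` scores 0 against everything; `N`-containing codons
  translate to `X`.

The ORF scanner is intentionally naive — maximal ATG-to-stop frames
≥ 60 aa across all six frames — and stands in for a real gene caller.
It is strand-symmetric by construction and is only used to turn contigs
into candidate proteins for screening and marker counting.

## Signature discovery and the two-hit screen

Candidates are the proteins of the lexicographically first target
proteome (a bounded, deterministic choice; clustering the union of all
target proteins would widen the candidate space at significant cost and
is not implemented). A candidate is a signature when

1. it is present in `≥ ceil(presence_frac · n_targets)` target
   proteomes, and
2. it has **zero** passing hits in every background proteome at the
   **same** thresholds.

`presence_frac` defaults to 0.9 — "almost all" rather than "all" —
because requiring strict universality makes discovery brittle to a
single mis-annotated target proteome; it is configurable to 1.0.
Near-identical retained candidates (mutual hit ≥ 95% identity) collapse
to the smallest id; this de-duplication is a package choice, not a rule
inherited from any reference workflow.

A sample is flagged only when **≥ 2 distinct** signatures are hit
(`min_hits = 2`). Distinctness is counted over signature ids, not over
hits, so many copies of a single signature gene never flag a sample.

## Binning

* **Read filter:** `aligned_fraction ≥ 0.90` (fraction of the read
  aligned — the mapping-tool semantics of "coverage") and
  `identity ≥ 95%`, inclusive.
* **tpmean:** per-base depths are sorted and the lowest and highest
  `floor(0.10 · L)` values discarded before averaging. Trimming is by
  **value rank**, not by contig end regions: the rule targets extreme
  *depth* values wherever they occur.
* **TNF:** 256-vector of overlapping 4-mer counts of the contig *and*
  its reverse complement, normalised to sum 1; windows containing
  non-ACGT bases are skipped. Reverse-complement invariance is exact by
  construction.
* **Embedding:** exact-gradient t-SNE (perplexity 30, capped at
  `(n−1)/3` for small inputs; PCA initialisation; fixed seed). Any
  embedding satisfying the neighborhood contract would do; no test
  depends on exact coordinates, only on cluster structure (silhouette,
  component membership).
* **Seeded components:** after excluding contigs < 2,500 bp, contigs
  are linked when their embedding distance is at most the 5% quantile
  of all pairwise distances (`link_radius_quantile`, the single knob of
  this stage), and only components containing a signature-bearing
  contig are emitted. This replaces interactive boundary-drawing on the
  embedding plot with a deterministic rule.
* **Refinement** iterates simultaneous removal of non-seed contigs with
  tpmean outside `[median/2, median×2]` or GC beyond ±0.05 of the bin
  median, recomputing medians to a fixed point. Removing all violators
  per pass (rather than one at a time) makes the result independent of
  contig order. Bin GC is the unweighted median over contigs.
* **QC:** completeness and contamination from single-copy marker copy
  counts (counted as distinct ORFs hit per marker), retention strictly
  `> 30%` complete and `< 10%` contaminated. The marker set is
  user-supplied; the synthetic fixtures use the simulator's marker
  list. Lineage-specific marker selection is out of scope.
* Coverage is computed for all contigs, but only contigs ≥ 2.5 kb enter
  binning.

## Phylogeny and indels

Degapping removes every column whose gap fraction exceeds
`max_gap_frac = 0` (any gap ⇒ removed); the common 50% alternative is a
knob. Concatenation follows the fill rule: a genome missing a marker
receives that marker's degapped length in `-`, and those columns are
excluded from the p-distance denominator for that genome's pairs.

The tree is classical Saitou–Nei neighbor joining on uncorrected
p-distances: Q-matrix minimisation with ties broken on the smallest
index pair, negative branch lengths clamped to zero with the deficit
shifted to the sister branch, and the 3-taxon closed form at the final
join. No Poisson/JTT distance correction and no likelihood heuristics
are applied — topology-level agreement is the contract, and NJ is exact
on additive matrices (verified on 100 random 5–8-taxon trees).
Bootstrap supports resample columns uniformly across the whole
supermatrix (site bootstrap, ignoring marker boundaries) and annotate
the original tree's bipartitions; no consensus tree is built.

Indel detection runs on the **original** (pre-degap) alignments, since
degapping deletes exactly the columns of interest. A column qualifies
only under strict exclusivity — gapped in *every* group row and in *no*
other row (or the reverse, for insertions) — and maximal same-kind runs
of length ≥ `min_len` are reported. One partially gapped outsider
disqualifies a column.

## Expression

Gene depth is the tpmean (same 10% trim; a no-trim option exists) of
the per-base track restricted to the gene's coding interval. Inputs are
declared non-ribosomal: rRNA read removal is an upstream step outside
this package. "Above the average" is strict (`>`), and depths are raw
fold-coverage per base with no read-length normalisation. The
high-expression lists use strict thresholds at 200× / 700× / 1,000× by
default.

## Synthetic community

The generator plants every structure the pipeline is supposed to find,
at desk scale:

* **Genomes:** 10 target-genus + 3 × 4 neighbor-genus genomes of 60 kb
  (a deliberate ~50-fold size reduction; 2.5–4.5 kb contigs then give
  ~15–20 contigs per genome, enough for the radius-graph binning rule
  to form connected clusters), ~30 genes each.
* **GC contrast:** target 0.54 vs neighbors 0.46, imposed by
  GC-weighted codon choice in coding regions plus intergenic
  composition solved to hit the genome target exactly (realised GC is
  within ±0.02 and the genus gap exceeds 0.03 under defaults). These
  match the reported GC ranges of the study system this package
  emulates (≈52–56% vs ≈45–47%).
* **Pan-genome classes:** 12 universal single-copy markers (150 aa,
  ~15% genus-ancestor divergence → ~70% cross-genus identity, so they
  fail the absence condition), genus-specific accessory fillers
  (present in fewer targets than the presence threshold requires and
  < 40% identity across genera, so they fail the presence condition),
  and 3 signatures present in all targets and nowhere else. Only the
  signatures pass both conditions, which is what makes exact recovery a
  meaningful test.
* **Evolution model:** point substitutions only (~1% within a genus),
  no indels outside the planted block — alignments are exact by
  construction and truth stays exact. The planted 2-residue deletion
  sits in the first marker in every target genome, mirroring the
  two-residue genus-diagnostic deletion reported for the emulated
  system's leucyl-tRNA synthetase.
* **Samples:** of 20, ten clean positives (one target genome + two
  neighbors), one contamination plant (the same target genome emitted
  twice as strain replicates at near-identical coverage, so the merged
  bin duplicates every marker and must fail the <10% cut), four
  negatives carrying exactly one signature gene, five target-free
  negatives. Fragment cut points never split a signature gene, so the
  planted per-sample signature counts are exact.
* **Mapping records** are generated directly (no read sequences):
  Poisson read counts at the planted coverage, plus an extra ~10% of
  records corrupted to fail exactly one of the two filter conditions.
  Post-filter tpmean equals planted coverage up to Poisson noise.
  Contigs shorter than the read length are an edge case where
  `aligned_fraction` is drawn as a quality attribute rather than
  derived from geometry.
* **RNA depths** are log-normal (median 40×, σ = 1.2) with designated
  tiers forced above 1,000× / into (700, 1,000] / into (200, 700].
  The recorded truth (mean, fraction above mean, threshold lists) is
  recomputed from the emitted table itself, so downstream statistics
  can be checked for exact equality.
* **Determinism:** one global integer seed; every submodule derives an
  independent stream from it; fixed seed ⇒ byte-identical outputs.

**What passing on this fixture does not show:** real metagenomes have
uneven strain mixtures, sequencing error, chimeric contigs, horizontal
transfer blurring the pan-genome classes, compositional biases beyond
GC, and gene callers far better than the naive ORF scan. The synthetic
results validate the *rules and their implementation*, not the field
performance of TNF binning or signature screening.

## Degenerate inputs and numeric details

* `tpmean` errors when trimming would discard every value; trim 0 is a
  plain mean.
* `tnf` errors below 4 bp; an all-ambiguous sequence yields the zero
  vector (not renormalised).
* `embed` requires ≥ 3 rows; identical rows map to identical
  coordinates.
* `p_distance_matrix` errors (naming the pair) when two genomes share
  zero comparable columns.
* `nj_tree` requires a symmetric, non-negative, zero-diagonal matrix
  and ≥ 3 taxa.
* Unknown configuration keys are rejected rather than ignored; all
  coordinates are 0-based half-open internally and on disk.

## Problem sizes used by the test suite and acceptance script

The default community (22 genomes × 60 kb, 20 samples, ~650k mapping
records, 200 bootstrap replicates in the acceptance run; 100 in the
suite) was chosen so that a complete end-to-end run, including
discovery's ~20k pairwise alignments, finishes in well under a minute
on one CPU while every stage still operates in its intended regime.
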