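# Methods

`crossomix` implements a crosswise multi-omics workflow: co-expression
networks built from group-fold-change (GFC) patterns in RNA-seq and
promoter-ATAC-seq data, horizontal (between cell lines) and vertical
(between omic layers) network integration, perturbation-informed
drug-sensitivity signatures, single-sample enrichment scoring, and a
self-supervised L1 model that reproduces the scores from basal
transcriptomes alone. This note records the models, the tunables that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Preprocessing

Counts are filtered on row totals: RNA keeps features with total
strictly greater than `rna_min_total` (default 100), ATAC keeps peaks with
total at least `atac_min_total` (default 20). Normalization is
median-of-ratios: the size factor of sample *j* is the median, over
features with all-positive counts, of `count_ij / geometric_mean_i`.
Expression is then `log2(count / factor + pseudocount)` with pseudocount 1.
This log transform stands in for a variance-stabilizing transform: it is
monotone and flattens variance at the expression levels that matter here,
but unlike a fitted VST it does not model the mean-dispersion trend.
Differential testing is a per-feature two-sided Welch t-test on log-scale
values with Benjamini–Hochberg adjustment. A negative-binomial Wald test
with shrinkage and weighted multiple-testing would be more powerful at
n = 3 per group; any precomputed differential table with columns
`log2fc/p/padj` can be injected wherever a DE table is consumed, so an
external NB pipeline remains usable. Degenerate zero-variance contrasts
map to p = 1 when the means agree and to the smallest positive float when
they differ.

The **GFC** of feature *i* in condition group *g* is
`mean_g(log2 expr_i) − mean over groups of the group means`. Uncapped rows
therefore sum to zero exactly (tested to 1e-9); an optional symmetric cap
(default ±2 log2 units, the convention of GFC-based network tools)
clips outliers and is the only operation allowed to break the sum rule.

ATAC peaks reduce to one reference promoter peak per protein-coding gene.
Two rules are provided: highest variance of normalized accessibility
across all samples (used for network construction) and lowest p-value in a
specific contrast (used for pairwise DE/DAR concordance). Ties break to
the lexicographically smaller peak id so reruns are reproducible.

## Networks

Co-expression is measured in GFC space: the edge weight between two
features is the Pearson correlation of their GFC vectors across condition
groups, and only positive correlations at or above the cutoff (inclusive)
become edges. Correlating regulation patterns rather than per-sample
values makes the networks describe *how features respond to conditions*;
per-sample correlation is available but non-default. Networks are built
per cell line (so edges do not simply encode cell-type differences) from
each line's own condition groups, then merged horizontally: union of nodes
and edges, with shared edges re-weighted as the mean of the parent
weights. The merge is commutative and idempotent by construction.

The correlation cutoff is empirical. `cutoff_scan` reports nodes, edges
and the R² of a log-log fit to the degree distribution per candidate
cutoff; `choose_cutoff` defaults to the smallest cutoff with R² ≥ 0.8 and,
when no cutoff fits (planted-block graphs are nothing like scale-free),
falls back to the most stringent cutoff that keeps the maximal node count.
Pass an explicit cutoff for production analyses.

Communities come from walktrap (4 steps, deterministic), infomap (seeded)
or Leiden (seeded) on the weighted graph; communities below
`min_module_size` (default 15 nodes) are pooled into `unassigned`.
Modules are named by size-ordered color names, the field's convention.

## Vertical integration

Module pairs across layers are matched by the Pearson correlation of their
mean GFC vectors. At a cross-layer cutoff *c*, the integrated graph is the
union of both layers' nodes (namespaced `rna::`/`atac::`) and all
intra-layer edges, plus cross-layer edges between members of matched pairs
whose feature-level GFC correlation is ≥ *c* (weight = that correlation).
The published description of this step leaves the edge-transfer rule open;
restricting cross edges to matched module pairs and thresholding both the
module-level and the feature-level correlation at the same cutoff
reproduces the intended behavior (matched modules merge on reclustering,
unmatched modules stay layer-pure) with one tunable. The integrated graph
is reclustered with the same algorithms and minimum size.

The cutoff is chosen to maximize layer mixture: `crosslayer_cutoff_scan`
reruns the integration per candidate and reports the mean normalized
Shannon entropy of each module's (RNA fraction, ATAC fraction) — 0 iff all
modules are layer-pure, 1 iff all are 50/50 — and recommends the argmax,
ties resolving to the higher (more conservative) cutoff. The scorer is
pluggable.

## Signature construction

For each integrated module and cell line, ΔGFC = mean GFC(treated, 6 h) −
mean GFC(control, 6 h); the early time point is the default because
chromatin and early transcriptional responses carry the
discriminating signal, and it is configurable. The threshold score is
thr_score = ΔGFC(sensitive) − ΔGFC(resistant); modules strictly above the
median thr_score (q50, midpoint interpolation for even counts, computed
over all integrated modules) are selected. "Strictly above" means an
all-equal score vector selects nothing — the boundary case is tested.
Selected-module genes (layer namespace stripped, so a gene present in both
layers counts once) intersect with the baseline contrast between the two
untreated cell lines (defaults padj < 0.01, |log2FC| > 1; the fold-change
margin is per-drug configurable): baseline-up genes form the up signature,
baseline-down genes the down signature. Random and top-|log2FC| control
signatures of matched size support specificity checks.

## Scoring

The GSVA-style route transforms expression (samples × genes) into per-gene
cumulative statistics with a kernel CDF across samples — Gaussian kernel
with bandwidth sd/4 for continuous data, Poisson kernel (rate x+0.5) for
counts; zero-variance genes map to 0.5 everywhere. Per sample, genes are
ranked by decreasing statistic (ties keep stable input order) and a
weighted Kolmogorov–Smirnov walk steps up by |statistic|^τ (normalized)
at in-set genes and down by 1/(N−m) otherwise. The enrichment score is
the largest positive deviation plus the (negative) largest negative
deviation (`maxdiff`, default, τ = 1) or the single largest-magnitude
deviation (`maxdev`). The ssGSEA variant skips the kernel step, ranks raw
expression within each sample and integrates the walk (sum of deviations
over N). The sensitivity score is ES(up) − ES(down); swapping the sets
negates it exactly.

The two routes rank samples concordantly but are *not* sign-compatible:
the kernel CDF centers every gene across the cohort, so GSVA scores split
at the cohort median, while within-sample ranking gives ssGSEA scores a
cohort-dependent offset. The test suite asserts rank agreement
(Spearman ≥ 0.9) between the routes, not sign agreement.

## Self-supervised prediction

A LASSO regression (continuous target, despite "classifier" being the
customary name for this step) learns the sensitivity scores from basal
expression. Features are standardized with training-split statistics only
(a test perturbation-invariance check guards against leakage); the penalty
is chosen by 10-fold CV on the training split over a 50-value path
(`min` rule by default; `1se` available), and performance is reported as
Pearson r and RMSE on an untouched 20% split. The robustness check drops
every signature gene from the feature matrix *before* splitting and
retrains; with a background block correlated with the latent factor
(ρ = 0.9 in the benchmark cohort), predictive capacity should survive the
exclusion. Coordinate-descent tolerance defaults to scikit-learn's 1e-4
(exposed as a parameter); tightening it to 1e-7 changes the benchmark
metrics by far less than their seed-to-seed spread while costing minutes
of CPU.

## Synthetic data

The perturbation generator mirrors the study conditions: 2 cell lines ×
{control + two drugs} × {6 h, 12 h} × 3 replicates, RNA genes plus
promoter ATAC peaks (optionally several peaks per gene so the reference-
peak tie-break is exercised). A planted module is a block of features
sharing a GFC pattern (per-group log2 offsets), optionally with a baseline
log2 shift in one cell line and optionally present in both layers. Counts
are negative binomial with var = μ + αμ², per-feature baselines ~
N(8, 1) in log2, and log-normal library-size factors (CV 0.1). The
default dispersion is 0.02–0.1 depending on scenario: 0.02 reflects
tight cell-line replicates and is used where the Welch test at n = 3 must
reach adjusted significance (a fitted NB test would need less signal);
mean-recovery checks use near-Poisson noise with 50 replicates.

The cohort generator draws a latent sensitivity s ~ U(0,1) per sample;
up genes follow base + effect·s + N(0, σ), down genes base − effect·s +
N(0, σ), and half of the background genes correlate with s at ρ
(default benchmark ρ = 0.9) while the rest are independent noise. The
phenotype (viability decrease or −log IC50 analogue) is a monotone
function of s — linear, sign-flipped linear or logistic — plus Gaussian
noise.

What the generator does *not* emulate: batch effects and surrogate
variables, mean-dispersion trends, gene–gene correlation beyond the
planted blocks, length/GC biases, distal (non-promoter) regulatory peaks,
and tumor heterogeneity in cohorts. Passing benchmarks therefore
demonstrate that the machinery recovers known structure at realistic
noise, not that the workflow's biological conclusions transfer to any
real dataset.

## Benchmark problem sizes

The recovery experiments (`crossomix.experiments`, rerun by
`scripts/acceptance.py`) use: 4 × 50-feature planted RNA modules + 100
background genes over 12 condition groups; a 30 + 30 cross-layer module
with one 30-feature unpaired module per layer; the full two-cell-line
end-to-end scenario with 2 × 40 signature features per layer, three
distractor modules and 300 background features per layer; cohorts of 60
samples (scoring, 20 seeds) and 500 samples × 2000 genes (prediction).
These sizes keep a full run in a couple of minutes on one core while
preserving the study's structure.

## Known limitations

- The Welch/BH substitute for an NB Wald test is conservative at n = 3;
  inject external DE tables when exact parity with an NB pipeline matters.
- Cutoff selection heuristics are decision aids; published analyses of
  this kind choose cutoffs empirically per dataset, and so should users.
- Infomap determinism relies on seeding igraph's RNG; partitions can
  differ across igraph versions.
- GSVA's exact published implementation differs in detail (rank
  symmetrization); equivalence is asserted against an independent
  reimplementation of the documented statistic, not against the R package.
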