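# Methods

`fibromark` implements a small-cohort multi-omics biomarker workflow for
oral submucous fibrosis (OSF): transcriptome-wide differential expression
hardened by bootstrap stability selection, cross-cohort consensus,
delta-beta methylation calling, direction-consistent integration of the
two layers into a candidate signature, external validation by per-gene
ROC analysis, machine-learning evaluation under leakage-safe protocols,
and cell-type enrichment scoring in spatial single-cell data. Every
stage can be exercised end to end on synthetic data with planted ground
truth. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Differential expression and bootstrap stability

Counts are normalized to log2(CPM + 1). CPM stands in for TPM: gene
lengths are not modelled anywhere in the package, and within-gene
between-group comparisons are unaffected by the length term. The default
DE engine is a per-gene Welch t-test on log2(CPM + 1) with
Benjamini-Hochberg adjustment; log2 fold changes are computed on
group-mean CPM with a +1 pseudocount so they stay finite at zero counts.
A negative-binomial Wald engine (method-of-moments common dispersion per
gene, delta-method standard errors on the log mean ratio) is available
behind the same interface; the two engines agree on planted effects and
the internal Welch engine is additionally cross-checked against an
independent NB fit (pydeseq2) in the test suite. The stability
framework — the part of the workflow that carries the scientific claim —
is engine-agnostic.

Calling thresholds default to |log2FC| >= 1 with BH-FDR <= 0.05; a
relaxed raw-p mode exists for cohorts too small for the FDR to retain
anything (n = 2 per group). Genes with zero variance in *both* groups
receive p = 1 regardless of their group means: with no within-group
spread there is no error model to test against, and this convention also
makes degenerate bootstrap draws (a group collapsing onto one distinct
sample) count as not-significant rather than crash.

Bootstrap stability selection resamples sample indices with replacement
independently within the case and within the control group, preserving
group sizes, and reruns the DE test plus threshold calls in each of B
iterations (default B = 500). The stability score of a gene is the
fraction of iterations in which it was called up or down; genes
*exceeding* 0.6 (strict `>`, matching the "exceeding a predefined
threshold" wording; an inclusive flag exists) are retained. Each
iteration draws from its own numbered RNG substream, so results are
independent of execution order and stable if iterations are ever
parallelized. Whether bootstrap iterations reuse the cohort's own
significance criterion (FDR vs raw p) is not externally fixed; the
cohort's criterion is reused by default and is configurable.

## Consensus and overlap statistics

A gene is a consensus DEG when called in the same direction in at least
`min_freq` cohorts (default 2). Genes reaching the frequency cutoff with
discordant directions are quarantined in a `conflicts` set and excluded
from both consensuses — a consensus biomarker must be direction-
consistent, and silent merging would hide exactly the failure mode the
consensus is meant to catch. Overlap percentages are reported as
100·k/n rounded half-away-from-zero to one decimal, the convention the
printed values follow.

## Methylome calls and integration

Methylation effects are measured per CpG probe as delta-beta = mean beta
in cases minus mean beta in controls (positive = hypermethylated in
disease). When replicate betas are supplied, group means and a
two-sided Welch p are computed per probe. A probe is hyper-significant
at delta-beta >= 0.1 and p <= 0.05 (hypo at <= −0.1); both filters are
applied conjunctively. Raw p is the default significance measure — in
the source data the FDR-adjusted list was near-empty, so the documented
analysis choice is raw p; an FDR mode is provided. Probes annotated to
several genes (delimiter `;`, configurable) count toward each gene. A
gene is hyper-/hypomethylated if *any* of its probes qualifies — the
most inclusive aggregation rule; the per-probe call table is emitted for
audit, and genes qualifying in both directions are flagged ambiguous but
kept in both sets rather than dropped.

The integrated signature is (up ∩ hypo) ∪ (down ∩ hyper): promoter
hypomethylation is permissive for expression and hypermethylation
repressive, so only direction-consistent pairs are credible
epigenetically-driven markers. Output is alphabetically ordered for
determinism and annotated with upstream statistics where available.

## External validation

Per-gene discrimination is the ROC AUC with cases positive, computed as
the Mann-Whitney U statistic over n_case · n_control with ties counted
one half; direction is `case_high` iff AUC >= 0.5. Group log2 ratios
follow the linear-scale convention: data flagged as log-scale is
de-logged (2^x) before group means are taken, so the reported quantity
is log2(mean case / mean control) on the measurement scale. Heatmap
z-scores standardise each gene row to mean 0 and population sd 1;
zero-variance rows become all-zero and are flagged rather than NaN.
Dysplasia and non-dysplasia case subgroups are pooled for ROC analysis
by default, with subgroup labels carried for stratified views.
Cell-fraction statistics downstream of deconvolution (the deconvolution
itself is consumed as input, not reimplemented) are Spearman
correlations among cell types computed on case samples only, and a
two-sided Mann-Whitney test per cell type between groups; constant cell
types yield missing correlations, never zeros.

## Machine-learning evaluation

Five model families are supported (linear SVM, random forest, AdaBoost,
gradient boosting, extremely randomized trees) with small hyperparameter
grids centred on the best-reported settings (e.g. SVM C = 1, linear
kernel; RF 500 trees, min leaf 4). Under LOOCV each of the n folds
holds out one sample; hyperparameters are tuned by stratified k-fold CV
*inside the training fold only*, and the single held-out score per fold
is pooled so AUROC/AUPRC are computed once over n scores — one held-out
sample admits no per-fold ROC, so pooling is the only coherent
aggregation. Held-out scores are positive-class probabilities where the
family provides them, else the decision function. Nested CV uses
stratified 3×3 folds, reporting mean ± sd AUROC over outer folds. The
permutation test shuffles labels N times (default 1000) and repeats the
*entire* nested procedure per shuffle; p is the raw proportion of
permuted statistics >= observed, with an add-one (r+1)/(N+1) option for
conservatism. RFE removes the least-important feature one at a time
(absolute linear coefficients or impurity importances) until the top-k
(default 5) remain; sklearn's `RFE` with step 1 implements exactly this
and is used directly. Grid ties resolve to the first grid point, so all
results are bit-reproducible from the seed.

## Cell-type enrichment

Spots failing QC are removed first: fewer than 200 detected features, or
mitochondrial fraction strictly above 10% (a spot at exactly 0.10 is
kept; a spot at exactly 200 features is kept). No upper feature cutoff
is applied — spatial spots are multi-cellular and high transcript
density is signal, not artifact. Surviving counts are library-size
normalized (counts per 10^4, log1p), each gene is z-scored across all
spots (population sd), and a gene is "expressed" in a cell type when its
mean z over that type's spots is strictly positive; zero-variance genes
are excluded. The enrichment of a query set (the DEGs) in cell type c is

    raw(c) = log2( (Obs_c / n_deg) / (Exp_c / n_genes) )

with Obs_c the expressed query genes, Exp_c all expressed genes, and a
half-count continuity correction when either count is zero. The literal
log2(Obs/Exp) is non-positive whenever the query set is a subset of the
universe, so the ratio-of-fractions form is the default and the literal
form is available behind a flag. Raw scores are normalized to [−1, 1]
by the maximum absolute raw score per patient (min-max onto [−1, 1] is
an alternative); patients are scored independently and reported side by
side. The order QC → normalization → z-scoring is a package choice the
alternatives (z-scoring raw counts) would confound with library depth.

## Synthetic data and what it does (not) show

The generator plants every quantity the pipeline is later asked to
recover, under one truth manifest:

* **Bulk cohorts.** Negative-binomial counts parameterized by mean and
  dispersion (default base mean 100, log-normal spread sigma = 1 across
  genes, dispersion 0.1), with log-normal library size factors
  (sigma = 0.25) so normalization genuinely matters. Planted up/down
  genes (40 + 40 of 2000 by default) carry case means of control × 2^±2;
  the planted |log2FC| = 2 clears the calling threshold of 1 by design.
* **Methylome.** One probe per gene plus 20 two-gene probes (joined with
  `;`, paired within a planted status so gene mapping is exercised
  without contaminating the truth sets). Replicate betas are Beta
  draws with concentration 150 around the group means, 7 case vs 5
  control replicates; planted hyper/hypo genes are shifted ±0.2, twice
  the ±0.1 cutoff. The hypo set contains exactly 4 planted up genes and
  the hyper set exactly 7 planted down genes, so the true integrated
  signature is a known 11-gene set.
* **Validation cohort.** Continuous log-intensity values, 4 cases (2
  dysplasia / 2 non-dysplasia) vs 2 controls, planted genes shifted by
  ±2 over Gaussian noise (sd 0.5) — directions preserved by
  construction.
* **Cell matrix.** Poisson counts over the gene universe plus 13
  `MT-`-prefixed mitochondrial genes targeted at a 4% count fraction.
  Each cell type's program genes run at 8× baseline in its spots; the
  designated program type carries the planted up-DEG set itself. A
  configurable 10% of spots is planted to violate QC (half under 200
  features, half above 10% mito), with violator ids recorded in the
  truth manifest.

One global seed expands into named, CRC-keyed substreams per component
and per iteration, so outputs are bit-identical across reruns and adding
a generator never shifts existing draws.

**Cohort sizing.** The real discovery cohorts are as small as 2 vs 2;
at that size no method recovers planted truth reliably, which is exactly
why the stability framework exists. The default *simulated* study
therefore uses n = 20 per group per cohort — the size at which recovery
properties (>= 90% recall, <= 1% null retention) are well-defined and
testable — while keeping the real cohorts' criteria pattern (FDR for
the first cohort, raw p for the two small ones). Table-style shapes
(8 vs 2, 2 vs 2) remain available through the cohort configuration.

**What passing tests do not show.** The generator has no batch effects,
no gene-gene correlation, no probe-chemistry artifacts, no spatial
autocorrelation, no doublets, and symmetric well-behaved noise. Perfect
recovery on synthetic data demonstrates that the pipeline's logic is
correct and its thresholds consistent with the planted effect sizes; it
does not certify performance on real GEO cohorts, where effect sizes are
smaller, noise is structured, and the methylome-transcriptome coupling
is far weaker.

## Problem sizes for the default end-to-end run

The scaled default run (`fibromark simulate-run`, and the acceptance
script) uses B = 100 bootstrap iterations and N = 200 permutations with
the linear-SVM family — sizes at which the run completes in about a
minute while every recovery property is already saturated. The library
defaults remain B = 500 and N = 1000 (`--full`).

## Numerical conventions

* BH adjustment via `statsmodels.multipletests`; verified against a
  brute-force step-up implementation to 1e−12.
* AUC via `scipy.stats.mannwhitneyu`; verified against exhaustive pair
  counting to 1e−12.
* Percentages round half-away-from-zero at one decimal (`decimal`
  module, not banker's rounding).
* Fold changes use +1 pseudocounts on group-mean CPM; beta-value tables
  enforce delta-beta = case mean − control mean to 1e−12.
* All stochastic components derive integer seeds below 2^31 from the
  global seed via named `SeedSequence` keys.

## Known limitations

Paired designs, covariate adjustment and dispersion shrinkage are out of
scope for the DE engine; deconvolution (CIBERSORTx/xCell), enrichment
databases, PPI networks, clustering/UMAP and reference-based cell-type
annotation are consumed as inputs or out of scope entirely. The
ambiguity between the literal and fraction-normalized Log2(Obs/Exp)
score is resolved by exposing both.
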