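# Methods

## Model overview

`gerclass` classifies bulk transcriptomic samples into the four
medulloblastoma molecular subtypes (Group3, Group4, SHH, WNT) using
within-sample log2 gene-expression ratios (GERs) as features. The core
assumptions are:

- expression is measured per gene on either a linear (FPKM-like) or log2
  (microarray-intensity) scale, complete (no missing values), with genes
  identified by symbol;
- subtype identity expresses itself through genes whose expression is
  systematically shifted in one subtype relative to the others, on the
  log2 scale;
- platform differences act, to first order, as per-sample global offsets
  plus per-gene offsets on the log scale. Within-sample ratios cancel the
  per-sample component exactly and are insensitive to the per-gene
  component whenever it is shared by numerator and denominator
  distributions rather than differential between subtypes.

A trained model is a set of directed gene pairs, each assigned to the one
subtype in which the ratio is significantly elevated. Classification is
the unweighted mean of each subtype's available ratio values followed by
argmax; ties (exact score equality) break deterministically in the order
Group3 < Group4 < SHH < WNT and raise a flag.

## Moderated differential expression

Feature selection rests on a two-group moderated *t*-statistic with
empirical-Bayes variance shrinkage. For feature *g* with pooled residual
variance s²_g on d degrees of freedom, and a scaled-inverse-chi-square
prior (d0, s0²) fitted across features,

    s²_post = (d0·s0² + d·s²_g) / (d0 + d)
    t_g     = logFC_g / (sqrt(1/n1 + 1/n2) · sqrt(s²_post))

on d0 + d degrees of freedom. d0 = 0 recovers the ordinary pooled t-test;
d0 = ∞ fixes every variance at s0². The prior is fitted by matching the
mean and excess dispersion of log s² to digamma/trigamma expressions
(scaled-F moment equations), the standard approach in the moderated-t
literature; the implementation agrees with the Bioconductor reference
implementation to ~1e-14 on shared fixtures (see
`tests/test_modstats.py`).

Two numerical choices deserve note:

- **Infinite-prior verdict.** The excess dispersion of log s² beyond
  trigamma(d/2) decides between a finite and an infinite d0. The raw
  "greater than zero" rule flips on sampling noise roughly half the time
  when variances are truly homogeneous, returning spuriously finite
  (enormous) d0. We therefore require the excess to exceed twice its null
  standard error before fitting a finite d0; otherwise d0 = ∞ and
  s0² = mean(s²). The guard only binds when d0 is effectively infinite,
  where the moderated statistics are insensitive to the distinction.
- **Residual variance for composite contrasts.** One-vs-rest contrasts
  compare one subtype's pooled mean against the pooled mean of the other
  three. Computing the residual from the two pooled sides would count
  genuine between-subtype signal inside the reference pool as noise,
  which systematically masks the moderate (≈ effect/3) negative fold
  changes that single-subtype markers show in the non-elevated groups.
  The residual is instead computed within each constituent subtype
  (cell-means model, df = n − #groups), matching what a linear model with
  a group factor does. For pairwise contrasts the two definitions
  coincide.
- Features with zero posterior variance are flagged; their p-value is 0
  when the group means differ and 1 when they are equal.
- When fewer than 10 features with positive variance are available the
  prior cannot be fitted and the engine degrades to the ordinary t-test
  with a warning.

BH adjustment is the standard step-up procedure (delegated to
statsmodels), checked in the tests against a literal brute-force
implementation.

## Feature selection

**Gene stage.** The preprocessing cascade for linear-scale input is:
max-expression filter (strictly > 20), log2(x + 1), standardized-CV filter
(CV of log2 values per gene, z-scored across genes, retained at z ≥ −1;
genes with non-positive log-scale mean get an infinite-CV sentinel and are
always retained), then family exclusion by anchored case-insensitive
symbol patterns (`^MT-`, `^MRPL`, `^MRPS`, `^RPL`, `^RPS`, `^RNU`,
`^SNOR`, `^RNA5S`, `^RN7S` by default; configuration, not code). Log2
input skips the first two steps. Boundary conventions: strict inequality
for the expression floor, inclusive for the CV threshold.

Signature genes are then selected in three steps: (1) per subtype, genes
significantly up (and separately down) versus *every* other subtype in
pairwise contrasts (adjusted p < 0.05, |log2FC| > 1); (2) the top 250
genes per pairwise comparison by adjusted p (ties broken by raw p, then
|logFC| descending, then symbol), union over comparisons; (3) from the
pooled set, genes significantly up in at least one subtype and
significantly down in another, using one-vs-rest contrasts. Step 3
applies the significance cutoff with the correct sign but no fold-change
floor: with four balanced groups, a clean single-subtype marker's
one-vs-rest fold change in the non-elevated subtypes is diluted to about
one third of the planted effect, and a full gene-stage floor there would
discard genuinely discriminating genes the earlier steps already vetted.

**Ratio stage.** All unordered pairs of signature genes are enumerated
(n(n−1)/2; numerator is the lexicographically smaller symbol — orientation
is resolved at selection time, which makes ordered enumeration redundant,
though it is retained as an option). A ratio is kept for subtype S when
its one-vs-rest contrast for S is significant with log2FC > 0.58 and no
other subtype's contrast is (in that orientation); features selected
"down" are stored flipped, so a stored feature is always the up direction
in its subtype. Each directed pair maps to at most one subtype.

The 0.58 (≈1.5-fold) ratio floor and the 1.0 (2-fold) gene floor are
defaults in `SelectionConfig`, both exposed; the adjusted-p gate carries
most of the selection pressure.

**Transfer training.** A second dataset (typically another platform) can
be trained after intersecting its genes with a given subset — usually the
gene set of an existing model — skipping the signature-selection stage.
Models are merged by set union on (numerator, denominator, subtype).

## Classification and confidence

Classification converts the matrix to log2 (pseudocount 1 if linear),
computes each model feature present in the data, averages per subtype,
and takes the argmax. Model features whose genes are missing are dropped
and counted: per-subtype coverage below 50% flags the sample; below 10%
(or zero computable features) the run errors unless `allow_partial` is
set. Because log-ratios are invariant to per-sample global offsets, no
further normalization is applied by default; an optional per-sample
z-scoring of the feature vector (`zscore=True`) makes scores comparable
across samples without changing any call.

The confidence value is the maximum of three one-sided Welch *t*-test
p-values comparing the winning subtype's ratio values against each other
subtype's values within the sample. One-sided ("winner greater") matches
the value's use as evidence the winner genuinely scores higher; two-sided
is available. The maximum is in practice attained by the runner-up
whenever variances are comparable. The value is not a calibrated
probability of correctness; calls with p > 0.05 carry a `high-p` flag and
deserve orthogonal confirmation.

## Evaluation statistics

Confusion matrices put predictions on rows and reference labels on
columns; samples with Unknown labels on either side are excluded with a
logged count. Overall statistics: accuracy; exact Clopper–Pearson 95% CI
(beta quantiles); no-information rate (largest reference-class
prevalence); one-sided exact binomial p-value for accuracy exceeding that
rate; Cohen's kappa from the marginal-product expected agreement; and the
McNemar–Bowker symmetry test, reported as NaN whenever a symmetric
off-diagonal pair is empty (the statistic is undefined there). Per-class
statistics are the one-vs-rest collapse; 0/0 rates (e.g. sensitivity of a
class absent from the reference) are NaN, never 0. Percentages in text
reports are printed to two decimals; all computations are on unrounded
values.

## Synthetic data

The generator emulates the structure the selection steps assume: per-gene
baselines b_g ~ Normal(baseline_log2_mean, baseline_log2_sd) on the log2
scale; per subtype, a disjoint set of planted marker genes shifted by
±effect_log2fc in that subtype only; i.i.d. Gaussian within-group noise.
Linear-scale output is 2^value − 1 clipped at zero, so log2(x + 1)
recovers the log-scale values. A platform pair is two independent sample
draws from one ground truth, the second with per-gene additive offsets
~ Normal(0, platform_shift_sd) and a subsampled gene set.

Defaults (all configurable): 25 samples per subtype (a 100-sample cohort,
the scale of a typical training study), 2,000 genes, 10 up + 10 down
markers per subtype, effect 3 log2 units (marker-grade, eight-fold),
noise SD 0.5, baseline 7 ± 1.5 log2 units (so most genes clear the
FPKM > 20 floor), platform shift SD 0.5, 96% gene retention on the second
platform. These constitute the study conditions for the round-trip and
cross-platform checks in the tests and acceptance script.

What the generator does **not** model: gene–gene correlation, within-cohort
batch effects, count noise at low expression, library-size artifacts, or
the real co-expression hierarchy of tumor transcriptomes. Passing the
synthetic round-trip therefore demonstrates pipeline correctness — the
selection steps find exactly the planted structure and the classifier
recovers labels across a simulated platform shift — not clinical-grade
accuracy on real cohorts.

## Other design choices and limitations

- Duplicate gene symbols at ingestion collapse to the row with the highest
  mean expression (standard microarray probe collapse); averaging is
  available. Rows are sorted by symbol, so results are independent of
  input row order. Missing values are rejected at ingestion, not imputed.
- Scale auto-detection: matrix maximum < 30 ⇒ log2; overridable.
- Label harmonization is table-driven and user-extensible; unrecognized
  labels degrade to Unknown with a warning and never abort a run. The
  shipped table is a best-effort superset of common annotation dialects
  (including the historical A/B/C/D group letters).
- Two-group contrasts only: no multi-factor designs, sample weights, or
  duplicate-correlation structure. No between-sample normalization
  (quantile/TMM) — upstream FPKM/RMA is assumed.
- The per-dataset evaluation tables that a real multi-cohort study
  produces require those cohorts' data; the package evaluates whatever
  prediction/reference pairs it is given and reports exclusion counts
  rather than reconciling label mismatches silently.
- Confidence p-values are not calibrated probabilities; calibration
  (e.g. histogram binning) is out of scope.
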