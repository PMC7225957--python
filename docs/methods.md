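# Methods

## Scope and data model

`latentsurv` implements an integrative prognosis-subtyping analysis for
paired bulk RNA and miRNA expression with overall-survival follow-up. The
in-memory containers are deliberately small: an `ExpressionMatrix`
(patients × features DataFrame plus a per-feature class tag, RNA or
miRNA), a clinical DataFrame (`time_days`, `event`, binary covariates),
and plain DataFrames for every derived table. Input/output is TSV for
matrices and clinical tables, GMT for gene sets, JSON for run summaries.

## Synthetic cohorts

The generator emulates the statistical structure of a TCGA-style lung
adenocarcinoma cohort rather than its sequencing mechanics. Log-scale
expression for feature *j* of patient *i* is

    log x_ij = b_j + s_j · 1[i high-risk] + coupling_ij + e_ij,

with per-feature baselines `b_j ~ N(2, 0.5)`, standardized subtype shifts
`s_j = ±effect_size` on a designated minority of differential features
(default effect size 1.5, random sign), unit Gaussian noise, and — for
each differential miRNA — a linear repression term
`coupling = mirna_coupling × centered log-miRNA` (default −0.3) applied
to a few randomly chosen target RNAs. Values are exponentiated and a
`zero_rate` fraction of entries (default 0.15) is zeroed completely at
random, emulating excess zeros. Survival is exponential with hazard
`baseline_hazard × hazard_ratio^{1[high-risk]}` (defaults 1/1200 per day
and 3), censored administratively at `Uniform(0, censor_time_max)`
(default 3650 days); binary covariates are Bernoulli with
subtype-conditional rates, defaulting to the new-tumor-event and sex
rates of the real subtype tables (83/198 vs 48/166 and 115/198 vs 84/166).
The full-scale default is 364 patients (198/166 split) with 2000 RNA and
300 miRNA features; the test-scale configuration
(`CohortConfig.scaled_down`) uses 200 patients, 400 RNA, 60 miRNA with
40/10 differential features, which keeps full-pipeline runs below ten
seconds.

What the generator does **not** model: count noise and library-size
variation (values are lognormal, not negative binomial), feature-feature
correlation beyond the planted miRNA coupling, informative censoring,
batch effects, and any sequence-level structure. Passing tests therefore
demonstrate that the pipeline recovers planted low-rank subtype structure
under lognormal noise — not that it would behave identically on real
count data.

## Preprocessing

Zero handling drops features whose zero fraction exceeds
`feature_zero_frac_max` (default 0.20), then recomputes patient zero
fractions over the surviving features and drops patients above
`sample_zero_frac_max` (default 0.20). Both thresholds are exposed because
no canonical value exists. Remaining zeros are kept as 0 — no imputation.
Standardization is per feature across patients (z-score, sample sd); the
per-feature reading of "standardized against patients" was chosen because
Cox screening and Euclidean K-means downstream require comparable feature
scales. Standardization happens once on the full matrix, before the
train/test split used for classification; the resulting mild leakage is a
property of the emulated design and is documented rather than repaired.
Assembly concatenates the two matrices on their common patients in
RNA-matrix order, prefixing feature ids with their class.

## Autoencoder

A symmetric fully connected autoencoder written directly in numpy: tanh
hidden layers (default 500–100–500; the middle layer is the bottleneck),
linear output, mean-squared reconstruction error with L1 and L2 penalties
on all dense weights, inverted dropout after each hidden layer except the
bottleneck (so encoding is deterministic), and plain SGD with the
`lr/(1 + decay·step)` schedule (defaults lr 0.01, decay 1e-6, batch
size 1, 150 epochs, dropout 0.5, L1 1e-3, L2 1e-4). tanh is the default
activation because rectifier variants are known to behave worse in this
architecture; the choice is exposed, and an identity activation turns the
model into a linear autoencoder whose latent code provably spans the top
principal-component score subspace — the test suite uses exactly that
identity as an oracle. The loss trace records reconstruction error only
(penalties excluded), one value per epoch; training is single-threaded
and bit-reproducible from the config seed.

**Scaled-down configuration.** The defaults above are sized for inputs
with >10k features. `AEConfig.scaled_down()` — used for the few-hundred-
feature test cohorts — changes four things, each forced by scale rather
than preference:

* architecture 64–2–64: the bottleneck tracks the input dimension (the
  full-size model's bottleneck is ~0.7% of its features);
* L1 2e-4 / L2 1e-4: per-element MSE gradients scale as 1/n_features, so
  penalties tuned for 13k features overwhelm the data gradient at 450.
  The retained L1 pressure still performs its structural role — it
  shrinks uninformative bottleneck dimensions toward zero variance so
  that the survival screen passes only prognosis-bearing dimensions;
* full-batch gradient descent with lr 0.5 for 2000 epochs: reaches the
  same optimum as per-sample SGD in a fraction of the wall-clock steps;
* dropout 0: multiplicative 0.5 noise adjacent to a 2-unit bottleneck
  destroys the signal a net this small is trying to compress.

In pre-build simulations over 15 cohort seeds this configuration chose
k = 2 and recovered planted subtypes at ARI ≥ 0.98 on every seed.

## Survival statistics

The univariate Cox partial likelihood is maximized by Newton–Raphson with
step-halving, Efron tie handling, an internally standardized covariate
for conditioning, and convergence at |Δβ| < 1e-8 (100-iteration cap);
monotone likelihoods (complete separation) are reported with
`converged=False`. The screening p-value is the score test at β = 0,
which reduces exactly to the two-group log-rank statistic for a binary
covariate **when event times are distinct**; under tied deaths the Efron
score and the hypergeometric-variance log-rank differ slightly (both are
standard; the package reports the Wald p alongside). Kaplan–Meier is the
product-limit estimator; the log-rank test is the k-group
observed-minus-expected statistic with hypergeometric covariance
(χ², df = k−1). Benjamini–Hochberg adjustment is the step-up procedure,
monotone and capped at 1.

## Subtyping

K-means (Lloyd, best of 50 restarts, tolerance 1e-12) and the Silhouette
and Calinski–Harabasz indices come from scikit-learn. The elbow curve
(WCSS vs k) is reported descriptively and never decides k. The consensus
rule is: k = Silhouette argmax over k ≥ 2; a differing Calinski–Harabasz
argmax is flagged as a conflict but does not override. Risk orientation
compares Kaplan–Meier survival of the two clusters at the median
follow-up time; the cluster with lower survival is named high-risk, an
exact tie is broken toward the smaller cluster (with a warning), and the
two-cluster log-rank test is reported. Orientation is defined only for
k = 2, matching the analysis this pipeline realizes.

## Classification

ANOVA ranking is the ordinary one-way F statistic between the two label
groups, computed on the training split only, with RNAs and miRNAs ranked
separately. The split is stratified 60/40 with a recorded seed. The
primary classifier is an RBF-kernel SVM with C = 1 and feature-count-
scaled bandwidth (`gamma="scale"`); the sweep covers miRNA counts
{5,10,15,20} × RNA counts {5,10,15,20,25,30} plus six showcased
combinations, and the comparison grids are KNN (k = 1..10 × Manhattan/
Euclidean), random forest (1..10 trees × entropy/Gini; "trees" is the
documented reading of an ambiguous grid axis) and logistic regression
(C ∈ {1,5,10,50,100,500,1000} × L1/L2). The confusion matrix takes the
high-risk subtype as the positive class.

## Differential expression and screens

The two-group test is deliberately simple and labeled as such: Welch t on
log2(x+1)-transformed normalized expression, log2 fold change = difference
of group means on that scale (high-risk − low-risk), BH adjustment over
all features. It replaces a negative-binomial shrinkage model by design —
the pipeline's interface accepts any external differential table with the
same columns, so the stage is swappable. `top_k` orders by adjusted p
with ties broken by |lfc| descending then feature id. The quartile
survival screen forms the top and bottom floor(q·n) patients by one
gene's expression (q = 0.25), excludes the middle, and log-rank-tests the
extremes; boundary ties are resolved by a stable sort on patient id.

## Enrichment

Preranked GSEA orders features by a signed statistic (default: the
differential t value). The enrichment score is the maximum deviation of a
running sum that rises by |stat|^weight (normalized over set members;
weight 1 by default) at hits and falls by 1/(N−|S|) at misses. The null
is gene-set permutation — random same-size sets from the universe
(default 1000 draws) — rather than phenotype permutation, matching
preranked practice; the p-value is the sign-matched tail frequency with
an add-one correction, NES = ES / mean(|null ES| of matching sign), BH
across sets. Over-representation is the one-sided hypergeometric upper
tail on the 2×2 overlap table, with a 0.5 continuity correction on the
odds ratio when a cell is zero. Gene-set collections are user-supplied
GMT files; tests use synthetic collections only.

## Association statistics

Fisher exact tests are two-sided throughout (probability-mass definition).
Mutation tables count *patients* with at least one mutation, not mutation
events — this is the reading consistent with the published per-subtype
rates. Mann–Whitney uses midrank ties, exact enumeration for untied
samples of ≤8 per group and the tie-corrected normal approximation
otherwise. Copy-number input is pre-summarized per patient per chromosome
(mean log2 value); one Mann–Whitney test per chromosome with BH across
chromosomes. Co-expression screens Pearson r of a seed gene against every
other feature, p from the t transform, BH FDR, sorted by |r|; the seed
and zero-variance targets are excluded.

## Pipeline and reproducibility

`run_pipeline` executes preprocess → autoencoder → Cox screen →
cluster-number selection → K-means → risk orientation → ANOVA ranking →
classifier sweep and grids → differential expression → (optional) GSEA →
covariate associations, writing every intermediate table plus a summary
JSON. Every random stage draws a child seed derived by SHA-256 from the
global seed and the stage name (kept below 2³¹), so runs are reproducible
from the config alone and stages are individually re-runnable. The
screening stage halts the pipeline with an explicit empty-selection error
when no latent feature is survival-associated.

## Known limitations

* The differential-expression stage is a two-group Welch test, not a
  count model; dispersion shrinkage and size-factor estimation are out of
  scope.
* The autoencoder is CPU-only numpy; the full 500–100–500 configuration
  at batch size 1 is faithful but slow on large matrices.
* Risk orientation and several characterization stages assume exactly two
  subtypes.
* Silhouette-based cluster-number selection on tanh-bounded latent spaces
  can prefer saturation-induced corner sub-clusters when weakly
  informative latent dimensions survive screening; the scaled-down
  configuration's L1 setting exists precisely to suppress those
  dimensions.
* Standardization precedes the classification split (see Preprocessing);
  reported test accuracies on real data would carry that mild optimism.
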