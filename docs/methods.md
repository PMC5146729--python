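# Methods

This note documents the statistical procedures implemented in `inflamscore`,
the assumptions behind them, the defaults of the synthetic cohort generator,
and the numerical choices that were genuinely open.

## Scores

**Quartile score.** For each panel gene the threshold is the empirical 75th
percentile across samples, computed with the linear-interpolation (type 7)
quantile; a sample scores 1 for that gene when its value is *strictly* above
the threshold. The per-sample score is the sum over panel genes, an integer
in [0, G]. The strict inequality makes the constant-gene case well defined
(a constant gene contributes 0 everywhere, logged rather than raised) and,
for tie-free data with n divisible by 4, fixes each gene's positive count at
exactly n/4, so the score mean sits at G/4 by construction. Sub-pathway
scores apply the same rule to each functional subset; when the sub-pathways
partition the scored panel the sub-scores sum to the total score exactly.

**PC1 score.** Genes are centred and scaled to unit variance before the
SVD, so the score is invariant to per-gene affine transformations.  The sign
of a principal axis is arbitrary; we fix it so the sum of gene loadings is
positive, which makes results reproducible but means the *direction* of PC1
relative to "more inflammation" is data-dependent — regression coefficients
on PC1 can legitimately have the opposite sign from the quartile score.

**Rank score.** For a given SEP indicator, each gene's direction is the
sign of its exposure coefficient from an ordinary least-squares fit
(covariates optional); samples are then ranked with average ranks on ties,
ascending for up-regulated genes and descending for down-regulated ones, so
that change in the low-SEP direction always earns a higher rank. A sample's
score aggregates its oriented ranks across genes. The published description
of this score ("the median sum of the rank scores … across all transcripts")
is ambiguous between a median and a sum over genes; both are implemented
(`aggregate="median"`, the default, and `aggregate="sum"`), and no further
guess is made about the original intent. Genes with an exactly zero
coefficient are excluded (logged); if *every* coefficient is zero the input
is fully degenerate and all samples receive the tied central rank (n+1)/2.
The score is exposure-specific and is recomputed per SEP indicator.

**Effective number of tests.** k is the smallest number of principal
components of the standardized panel whose cumulative variance share reaches
95%; the corrected per-gene significance level is 0.05/k.

## Technical de-noising

Each gene is fit by REML with crossed random intercepts for the three
technical batch factors (RNA isolation, hybridization, labeling) and the
per-gene fixed effects (SEP, age, gender, centre in three regions, phase,
and the two case-control indicators). De-noised expression subtracts only
the predicted random intercepts (BLUPs, u_f = σ̂²_f Z_f' V̂⁻¹(y − Xβ̂));
fixed effects remain in the data so downstream score models re-adjust for
covariates themselves. The fit uses the complete-covariate subset, but
BLUPs are per batch level and are subtracted for *all* samples (levels
unseen in the fit predict zero). ML-vs-REML is not dictated by the design;
REML is used as the standard choice for nuisance variance components.

Numerical choices: estimation via `statsmodels` `MixedLM` with variance
components; because near-boundary components defeat individual optimizers,
a short optimizer chain (BFGS, L-BFGS, Powell) is tried and the first
converged fit is accepted. A gene whose fit fails or does not converge
falls back to sequential batch-mean centering (per factor, subtract the
deviation of batch means of the current residual from its grand mean),
logged per gene in the fit log. `method="centering"` applies that fallback
everywhere, which is useful for quick runs and is nearly equivalent when
batch variance is genuinely zero. De-noising never changes matrix
dimensions or gene identities.

Quantile normalization (used on probe-level external data) maps every
column onto the across-sample mean of sorted values; tied values receive the
mean of the reference values their average rank spans, so output does not
depend on row order.

## Association models

The adjustment ladder is strictly nested: model A (age, gender, the two
case-control indicators, phase, centre, early-life SEP), B (+ education),
C (+ household occupation), D (+ BMI, smoking, alcohol), fully adjusted
(+ estimated neutrophil and monocyte proportions). One complete-case
analysis set — samples with all three SEP indicators and the behavioural
covariates observed — is fixed *before* fitting and shared by every rung, so
n never drifts within a ladder. Reference coding is fixed throughout
(high/non-manual SEP = 0, gender reference "woman", centre reference
"North", smoking reference "never"), so a positive coefficient always means
a higher outcome in the low SEP group; centre dummy coding is arbitrary and
does not affect the SEP contrast. Aliased design columns are dropped with a
warning. Per-gene SEP tests use the full mixed model on raw expression; the
Wald test of β₁ is flagged against the effective-tests level.

Descriptive group comparisons use the pooled-variance two-sample t test for
continuous variables and the chi-squared test for categorical ones, with
Yates continuity correction for 2×2 tables and none for larger tables —
the convention validated against published descriptive tables in the test
suite. Expected cells below 1 annotate a warning but the test is still
computed.

**Specificity null.** Gene sets of the panel's size are drawn without
replacement from the canonically sorted measured universe (so draws are
reproducible regardless of input row order); each set is scored and fitted
exactly like the observed panel, and k counts null p-values *strictly*
below the observed one. The panel's genes stay in the sampled universe by
default (an `exclude_observed` flag removes them) since the random sets are
meant to be exchangeable with the panel under the null. Both k/N and the
add-one form (k+1)/(N+1) are reported; the add-one form is the exact rank
statistic and is the one used in the uniformity calibration test. Default
`n_sets` is 1,000 for desk-scale runs; the original-scale 10,000 is a
parameter away.

**Power.** Only a simulation-based power estimate is provided (the
analytic inputs of a closed-form calculation — the score SD in particular —
are design-dependent): cohorts are simulated from a configuration template
across a grid of sample sizes and the rejection fraction of the chosen
score model is reported.

## Cell-type deconvolution

Per sample, expression over the shared signature genes is regressed on the
reference profiles by least squares on the linear intensity scale; while any
coefficient is negative the most negative cell type is removed and the
system re-solved; surviving coefficients are renormalized to proportions
(removed types get 0) and aggregated to Lymphocytes / Neutrophils /
Monocytes. Inputs that look log2-scaled (all values < 30) are exponentiated
first, logged — linear mixing is the model's assumption and log-scale input
is the common user error. Ties among equally negative coefficients drop the
lexicographically first type (logged); a rank-deficient reduced system
raises an error naming the offending types. The shipped 17-type signature
is synthetic (generated, full column rank by construction with bounded
resampling) and makes no claim of matching any laboratory reference; fully
adjusted results on real data depend on the signature supplied.

## Synthetic cohort generator

The generator emulates the data structure the pipeline assumes, with
defaults chosen as the study conditions: 250 samples, 15,000 annotated
genes, an 845-gene inflammatory panel split into 17 sub-pathways with the
canonical size profile (119 down to 13 genes, rescaled by largest remainder
for other panel sizes), Gaussian log2 intensities (no distributional detail
beyond that is assumed), ~1.5 probes per gene, and crossed batches of
roughly 10/8/12 samples (isolation/hybridization/labeling) with
random-intercept SDs (0.20, 0.15, 0.10) against a residual SD of 0.50.

The three SEP indicators form a Markov chain over life stages with
P(next low | current low) = p + c·(1−p) and the complementary transition
chosen to keep each stage's marginal at its target prevalence
(0.64 / 0.56 / 0.34 for the low class); c defaults to 0.45. Questionnaire
missingness (8% / 0.4% / 7% per indicator) yields a complete-case analysis
set near 85% of the cohort. Confounders get small direct effects on both
expression and SEP (age and BMI shift upward in the low early-life SEP
group; smoking prevalence differs by education), so adjustment genuinely
moves estimates. Latent cell composition is Dirichlet over 17 fine types
scaled to a 75/18/7 lymphocyte/neutrophil/monocyte mean, and contributes a
standardized signature-driven component to the signature genes' expression —
an additive emulation on the log2 scale, *not* linear-scale mixing, so
deconvolution accuracy on generated cohorts is not a planted truth (the
deconvolution oracle tests use exact linear mixtures instead).

The SEP effect is a per-gene log2 shift `effect_delta` applied to
inflammatory genes only; the default 0.05 yields an expected composite-score
contrast of ≈23 counts over the 845-gene panel under the default noise —
the magnitude the analysis is designed to detect. The expected contrast has
a closed form under the batch-, confounder- and cell-free configuration
(threshold = mixture upper-quartile, contrast = difference of exceedance
probabilities, summed over genes), implemented as
`expected_quartile_shift` / `calibrate_effect_delta` and validated against
large-sample simulation; parameter-recovery tests compare pooled model-A
estimates to this truth. Probe structure plants one strictly-most-variable
probe per gene by damping sibling-probe noise (factor 0.55), so collapsing
has a recorded ground truth and the collapsed matrix keeps a homogeneous
noise SD.

What the generator does **not** emulate: array-level artefacts beyond
additive batch intercepts, gene–gene correlation beyond the shared
confounder/batch/cell components, heavy-tailed intensity distributions,
and linear-scale cell mixing. Passing tests therefore demonstrate the
statistical machinery under the assumed model, not robustness to real
microarray pathology.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at reduced but statistically adequate sizes chosen as
package defaults: the null-calibration check uses 200 repetitions × 200
random sets on 80-sample / 600-gene cohorts; parameter recovery pools 100–
200 cohorts of 248 samples × 1,000 genes; permutation type-I error uses
1,000 permutations at 250 samples; de-noising checks use 25–60 genes (each
REML fit is a full mixed model). The specificity default of 1,000 sets (vs
the original-scale 10,000) is likewise a desk-scale default, not a changed
method.

## Known limitations

* The mixed model treats batch effects as additive random intercepts; scale
  or interaction batch effects are out of scope, as is unsupervised batch
  discovery (factors must be declared).
* The rank score's original aggregation rule is ambiguous (see above); both
  readings are provided rather than resolved.
* Replication on public data requires locally supplied series-matrix and
  platform-annotation files (no network access is attempted) plus an
  explicit mapping from a sample-characteristics field to the binary SEP
  indicator, which GEO encodes as free text.
* The quartile score weights all panel genes equally by design; effect-size
  weighting is intentionally not offered.
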