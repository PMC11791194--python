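# Methods

This note defines the statistical procedures implemented in `cetclock`, the
parameter choices they default to, and the numerical decisions behind them.

## Data model

A **sample panel** records, per sample: an identifier, species, tissue, age in
years, sex (`F`, `M`, or unknown), and whether the age is known. Labels are
trimmed and case-folded on construction. A **beta matrix** holds methylation
fractions in [0, 1] (values within 1e-9 outside the range are clamped; larger
excursions are rejected). A **CpG map** assigns each CpG a chromosome and a
1-based position; a CpG at position *p* corresponds to the half-open
0-based interval [*p* − 1, *p*), the convention used for all BED overlap.

## Age transforms

Clocks are trained on a transformed age scale and predictions are mapped
back:

- `log1p`: *f*(a) = log(a + c) − log(c), with offset c = 1 by default.
- `loglinear` (Horvath-style): logarithmic below a knot age *k*,
  *f*(a) = log(a + c) − log(k + c), and linear above it,
  *f*(a) = (a − k)/(k + c). Value and first derivative match at the knot, so
  the transform is C¹ and strictly increasing.

Both inverses are closed-form and total on the reals; predictions below the
transform's floor map to (possibly negative) years and are reported as-is
rather than clipped, so calibration problems stay visible.

## Elastic-net clocks

Transformed age is regressed on all CpGs with the elastic net
(mixing parameter alpha = 0.5, i.e. equal L1/L2 weighting). Features are
standardized internally; fitted coefficients are mapped back to the beta
scale and stored with an intercept, so the saved model applies directly to
raw beta values. Missing betas are imputed with the training means, and
prediction refuses samples missing more than 20 % of the model's CpGs.

The penalty strength lambda is selected on a 50-point logarithmic grid from
the data-derived maximum (the smallest lambda that zeroes all coefficients)
down by a factor of 1e-2 when *n* < *p* (1e-4 otherwise, the standard
glmnet convention), minimizing mean squared error on the transformed scale
over 10 internal folds. Folds are stratified by species when every species
has at least 10 samples.

**Leave-one-sample-out CV (LOOCV).** Each sample is predicted by a model
refit without it. For speed the penalty selected once on the full data is
reused for every refit (each fold still re-centers, re-scales, and refits
the coordinate-descent solution from a warm start). Reselecting lambda
inside every fold (`reselect_lambda=True`) is available but roughly three
orders of magnitude slower; on the recovery scenarios the two agree to
within the fold-to-fold noise, because removing one of hundreds of samples
barely moves the CV curve. Reported: Pearson *r* between age and predicted
age, and the median absolute error in years.

**Leave-one-species-out CV (LOSOCV).** Each species is predicted by a model
trained on all others, with the penalty reselected per fold (here the
training set genuinely changes). Reported: the repeated-measures correlation
between age and prediction, and the median over species of per-species
median absolute errors, so small species count equally.

**Repeated-measures correlation** is the Pearson correlation of age and
prediction after subtracting each species' mean from both — equivalently,
the partial correlation from the ANCOVA *y* ~ species + *x*, signed by the
common slope. Species with a single sample carry no within-species
information and are excluded.

## EWAS and meta-analysis

Analyses are run per **stratum** (species × tissue) with at least 15 samples.

- **Age:** Pearson correlation *r* of beta with age;
  *t* = *r*√(*n* − 2)/√(1 − *r*²) on *n* − 2 degrees of freedom.
- **Sex:** ordinary least squares of beta on a female indicator plus age;
  the statistic is the *t* of the female coefficient on *n* − 3 degrees of
  freedom. Samples of unknown sex are excluded; single-sex strata are
  skipped.

Each *t* is converted to a signed z-score through its two-sided p-value and
combined across strata by unweighted Stouffer's method,
*z*ₘ = Σ*zᵢ*/√*k*. Tissue-specific analyses (age-blood, age-skin) combine
strata in one step. Analyses spanning tissues (age-all, sex) combine in two
steps — tissues within species first, then species — so a species
contributing two tissues gets the same total weight as one contributing one.
Per CpG, *k* counts only the strata in which the CpG was actually testable.

All p-values are carried as natural-log values (`scipy.stats.t.logsf`,
`norm.logsf`) and z-scores are recovered with `scipy.special.ndtri_exp`, so
the pipeline is exact far past double-precision underflow. At extreme
*t* with large degrees of freedom, where even `t.logsf` saturates to −inf, a
moment-matched normal approximation to the t tail supplies the z-score.

Family-wise significance uses Bonferroni: alpha/*m* over the *m* CpGs tested
(0.05/20,150 ≈ 2.5e-6 for a typical mappable-probe background). Top-*N* CpG
lists (default *N* = 1000) are selected by |meta-z| within a sign direction,
with deterministic tie-breaking.

## Enrichment

Overlap of a CpG list with an interval set is computed by binary search
against the merged, sorted intervals per chromosome; an optional buffer
expands each CpG's interval symmetrically. Enrichment of a foreground of
size *n* with *k* hits against a background of size *N* containing *K* set
members is hypergeometric: p-enrichment = P(X ≥ k), p-depletion = P(X ≤ k),
both in log space. Fold change is *k*/(*nK*/*N*); the odds ratio uses the
Haldane 0.5 correction only when a contingency cell is zero.

Three annotation styles are built on this primitive:

- **Chromatin-state / region sets:** one test per set.
- **Transcription-factor binding:** per TF, tests run against each source
  dataset with a 200 bp buffer; datasets whose binding covers more than half
  the background are dropped (too unspecific), except for an always-keep
  list; the TF's representative result is the dataset with the median
  enrichment p (lower-middle for even counts). **Polycomb annotation** marks
  a CpG as PRC1/PRC2-bound when at least two distinct member TFs
  (RING1/RNF2/BMI1, resp. EED/SUZ12/EZH2) have a peak over it.
- **Gene-set (GREAT-style):** each gene gets a basal domain of TSS − 5 kb to
  TSS + 1 kb (strand-aware) extended up to 50 kb but clipped at neighboring
  genes' basal domains. CpGs are assigned to every domain containing them;
  gene sets are tested on the induced gene universe, reported when at least
  3 foreground genes overlap and p < 1e-3.

## Synthetic data

The generator draws, per stratum, ages uniform on [0, lifespan] (optionally
skewed toward young animals by a power), then sets each planted age-CpG's
mean to squash(b₀ + m·f(age)) where the squash clamps into [0.001, 0.999],
b₀ is a species-perturbed baseline, m a per-CpG slope (N(0.06, 0.02²),
random sign), and f the configured transform. Shared-effect fraction
controls how many planted CpGs use the same slope across species — the
knob that governs cross-species transfer and hence LOSOCV. Sex CpGs get
±delta on a designated sex chromosome. Gaussian noise (sd 0.03) is added and
clamped to [0, 1]; null CpGs are noise around their baseline, so type-I
error is measurable. Defaults mirror a realistic cetacean panel (13 species,
blood and skin, 37,000 CpGs); `standard_scenario()` is the compact recovery
benchmark used by the tests (6 species × 2 tissues × 40 samples, 2,000
CpGs, 200 planted, seed 42).

The annotation-fixture generator builds interval sets around actual CpG
positions so that one state set contains planted-age CpGs at
`enrichment_factor` times the background rate (0.08), alongside null state
sets, enriched and null TF datasets, and PRC2-member sets — enough to
exercise every enrichment code path with known truth.

## Determinism

Every stochastic routine takes an explicit seed. The pipeline derives
per-stage sub-seeds as (master × 1000003 + CRC32(stage name)) mod 2³¹,
records them in the run manifest together with input digests, and repeat
runs are byte-identical.

## Validation strategy

The test suite checks implementations against independent oracles rather
than against themselves: hypergeometric tails against exhaustive
binomial-coefficient enumeration (all backgrounds up to N = 30, relative
tolerance 1e-12), EWAS z-scores against `scipy.stats.pearsonr` and
`statsmodels` OLS (1e-8), repeated-measures correlation against both
`pingouin.rm_corr` and an explicit ANCOVA sum-of-squares decomposition,
near-unpenalized elastic nets against least squares, and Stouffer
combination against closed forms plus a Kolmogorov–Smirnov check of null
calibration. End-to-end recovery is validated on the standard scenario:
LOOCV *r* ≈ 0.997, LOSOCV repeated-measures *r* ≈ 0.995, all 200 planted
CpGs in the meta-EWAS top 200, stratum type-I error ≈ 0.05, and planted
annotation enrichment recovered while a factor-1 control stays null.

## Limitations

- The generator's noise is Gaussian and homoscedastic on the beta scale;
  real beta values are heteroscedastic (variance shrinks near 0 and 1).
- Strata are treated as independent in the meta-analysis; shared animals
  across tissues would violate that.
- Sex-EWAS uses a two-level sex coding plus age; no further covariates
  (batch, relatedness) are modeled.
- LOOCV's reuse of a single global penalty is an approximation; per-fold
  reselection is available when compute permits.
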