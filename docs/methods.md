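# Methods

`mirpanel` implements a two-phase urinary-miRNA biomarker workflow: a
sequencing *discovery* phase that nominates candidate miRNAs and
endogenous controls from a read-count matrix, and a qPCR *validation*
phase that tests the candidates with ΔΔCt statistics and asks whether the
panel improves a clinical risk model.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Count model and differential expression

Counts are modelled as negative binomial with mean–dispersion
parameterization,

    K_ij ~ NB(mu_ij, alpha_i),      Var(K_ij) = mu_ij + alpha_i mu_ij^2,
    log mu_ij = log s_j + x_j' beta_i,

where `s_j` is a median-of-ratios size factor (computed over miRNAs with
positive counts in every sample, rescaled to geometric mean 1) and `x_j`
contains an intercept, the subtype indicator, and any surrogate-variable
columns.  Each subtype is compared with controls separately, and
Benjamini–Hochberg adjustment is applied within each comparison,
mirroring the three separate discovery contrasts.

Dispersion is estimated in two steps: a per-miRNA method-of-moments
estimate `alpha~ = max(0, (Var - mean)/mean^2)` on normalized counts,
pooled across the design groups weighted by degrees of freedom, followed
by shrinkage towards a mean–dispersion trend `alpha(mu) = a0 + a1/mu`
fitted by least squares across miRNAs.  The final estimate is the equal-
weight average of the moment estimate and the trend value (`trend_weight
= 0.5`), clipped to `[1e-8, 10]`.  With fewer than 10 miRNAs the trend is
replaced by the global mean (with a warning).  This is deliberately
simpler than Cox–Reid/empirical-Bayes machinery: at the abundances the
selection rules keep (mean >= 300 reads) the moment estimator is already
stable, and the equal-weight trend shrinkage is what makes the null
p-value distribution uniform in the calibration studies (type-I error
0.05 at nominal 0.05, KS uniformity p > 0.1 at n = 50/50 with 2000
miRNAs).

The GLM is fitted by iteratively reweighted least squares, vectorized
across all miRNAs (batched p×p solves), with the linear predictor clipped
to ±30 and at most 100 iterations at tolerance 1e-8.  Non-converged or
all-zero miRNAs are flagged, their p-values set missing, and they are
excluded from the BH family (the family size shrinks accordingly).  The
Wald statistic uses the normal approximation of `beta/SE` with the Fisher
information at the fixed dispersion; fits are natural-log internally and
reported in log2.

## Surrogate variables (batch adjustment)

The number of latent components is chosen by parallel analysis on the
*residuals* of the class design: counts are transformed to
`log2(1 + normalized)`, rows are scaled by their delta-method precision
(`1/sd`, `sd = sqrt(1/mu + alpha0)/ln 2`, `alpha0` the median
within-class moment dispersion), columns are standardized, each miRNA is
regressed on the class indicators, and each residual singular value's
variance share is compared with its 95th-percentile null share under
independent within-row permutations (default 100 permutations).  Row
weighting matters: without it, low-count miRNAs dilute the factor
direction; without column standardization, per-sample depth differences
masquerade as a leading component (measured false-keep rate 15% instead
of the nominal ~5%).

The surrogate *scores* are then the leading right-singular vectors of the
row-weighted, row-centred **full** matrix, not of the residuals.  This is
a deliberate and load-bearing choice: residual-based scores are exactly
orthogonal to the class design, so a batch effect that is partially
confounded with the class cannot be absorbed by them — the class
coefficient silently retains the confounded bias (in our confounding
study the false-positive rate stayed above 0.6 despite a residual
direction correlating 0.9998 with the orthogonalized batch).  Scores
taken from the full matrix retain the confounded component and restore
the type-I error to ~0.01 under a 70/30 class–batch confounding.  The
assumption inherited from surrogate-variable analysis generally is that
the unwanted factor is *dense* (touches many features) while true signal
is sparse; a dense disease signature would partially leak into the
surrogate and attenuate effect estimates.  Scores are centred and
QR-orthonormalized, so columns are zero-mean and mutually orthogonal.

## Predictive power

PP is the leave-one-out cross-validated accuracy of a one-feature
logistic classifier on `log2(1 + normalized count)`; an "apparent"
(in-sample) scheme is available as a config option.  Two numerical
choices:

* The held-out sample is classified against the *training-fold case
  prevalence* rather than a fixed 0.5 probability.  With a 0.5 cutoff,
  removing the held-out sample tilts the training intercept against its
  own class; on balanced designs this drags null-feature accuracy to
  ~0.40 instead of 0.5.  The prevalence threshold cancels the artefact
  exactly and is indistinguishable from 0.5 whenever there is real
  signal.  A constant covariate degenerates to the training-majority
  rule, so its PP equals the majority-class proportion.
* Completely separated training folds (where the logistic MLE diverges)
  fall back to the midpoint-threshold rule the diverging fit induces.

Calibration: null features average PP 0.50–0.51; a feature whose exact
two-NB-class Bayes accuracy is 0.85 (effect size found by root-finding on
`0.5 * sum_k max(pmf0, pmf1)`, not a Gaussian approximation) scores
~0.81–0.86 at n = 100/100 — LOOCV sits slightly below the Bayes optimum,
as it must.

## Endogenous-control selection

Candidates must (1) have at least 2 raw reads in every sample, (2) have
log2 SD of normalized expression below 12, and (3) never deviate from
their own across-sample mean log2 expression by less than −4 or more
than +7 in any sample.  Criterion 1 reads as a raw-detection requirement
and uses raw counts; criteria 2–3 use depth-normalized counts.  The
reference point for criterion 3 is the miRNA's own mean — the "no
exceptional expression in any sample" logic of housekeeping screens.
Survivors are ranked by ascending log2 SD with lexicographic tie-breaks.
The default SD bound of 12 log2 units is intentionally permissive (it is
the screen's published form); the thresholds are all configurable and a
stricter SD bound is advisable for real cohorts.

## qPCR statistics

`ΔCt_ij = Ct_ij − mean(control-assay Ct in sample j)`; samples missing a
control Ct are excluded with a count.  `ΔΔCt` is the case-minus-control
difference of group mean ΔCt and the fold change is reported as
`log2FC = −ΔΔCt` (the standard `2^−ΔΔCt` convention in log2 units).
Association per assay is a logistic regression of class on `−ΔCt`
(log2-abundance scale) plus age and two smoking indicator contrasts
(former/current vs never), Wald p, BH-adjusted within the subtype's assay
panel.  Complete separation falls back to a Firth-penalized (Jeffreys
prior) fit, flagged in the output.  The trend test is a linear model of
`−ΔCt` on the ordinal class score control(0) < NMIBC G1+G2(1) <
NMIBC G3(2) < MIBC(3), with the same covariates; a cases-only mode drops
controls and rescores.  An ordinal-score linear model was chosen because
it admits covariate adjustment and reduces, for two groups without
covariates, to the equal-variance t-test exactly.  The spike-in assay is
used only as a QC flag (Ct SD above 1 cycle), never for normalization.

## ROC comparison

AUC is the tie-aware Mann–Whitney probability (ties count 1/2), computed
from midranks and exactly equal to exhaustive pair counting.  Variances
and the paired test follow DeLong: per-case and per-control placement
values, a 2×2 covariance for the two models' AUCs, normal-approximation
two-sided p for the difference; a zero-variance difference (e.g.
identical score vectors) returns p = 1 with a flag.  Confidence intervals
are normal-approximation on the raw AUC scale, truncated to [0, 1].
Model 0 is logistic on age + smoking; Model 1 adds one `−ΔCt` covariate
per panel miRNA; both are scored by in-sample fitted probabilities (an
honest stratified-CV AUC is a straightforward extension but in-sample
fits are the reference design here).  Assays missing in more than 20% of
samples are an error; otherwise missing values are list-wise deleted with
a count.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:

* NB counts with per-sample depth multipliers (uniform 0.5–1.5 by
  default), baseline log2 means uniform on (2, 13) (~4 to ~8000 reads,
  the post-filter dynamic range of urinary small RNA-seq), and a
  dispersion trend `alpha(mu) = 0.05 + 5/mu` (biological CV ~22% plus
  shot noise).
* Planted effects as (miRNA, class, log2FC) triples added to the latent
  log2 mean; planted housekeeping miRNAs with zero class effect and
  dispersion 1e-4, anchored mid-range.
* A two-level batch factor with per-miRNA Gaussian loadings (SD
  `batch_effect_sd`) on a centred ±1/2 batch score.  A shift common to
  *all* miRNAs equally would be exactly removed by size-factor
  normalization and could never confound anything, so the latent-factor
  form (which a single surrogate variable can recover) is used instead.
  `batch_confound` sets P(batch=1 | case); 0.5 is balanced.
* Age uniform on 42–75 years and smoking (12% never / 50% former / 38%
  current) drawn independently of class, so covariate-adjusted tests can
  be checked for type-I error; the generator does not model age- or
  smoking-associated expression.
* Ct values linearly linked to the same latent log2 expression
  (intercept 35, slope −1 cycle per doubling) plus Gaussian noise
  (default SD 0.5 cycles; the model-comparison studies use 0.8), with a
  constant spike-in at Ct 20.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: zero inflation and dropout,
miRNA–miRNA correlation beyond the single batch factor, depth–class
associations, qPCR efficiency differences between assays, hemolysis or
collection artefacts, and covariate–expression confounding.  Identical
(config, seed) pairs give bit-identical outputs.

## Validation-study problem sizes

The simulation studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` use: 2000 miRNAs × 50/50 samples for DE and batch
calibration; 2000 replicates at n = 100 for DeLong calibration; 200 null
features and 8 planted features at n = 100/100 for PP; 20 seeds × (5
stable + 95 variable) miRNAs for normalizer recovery; 1000 random
instances for the AUC and BH oracles; and 100 replicates at 112 cases /
65 controls (82/20/10 across subtypes) with a three-miRNA signature whose
combined Bayes AUC is 0.85 for the end-to-end model comparison.  The
signature's per-assay effect is derived in closed form from the target
Bayes AUC, accounting for the control-noise term shared across assays
within a sample.

## Known limitations

* The NB Wald test uses a plug-in dispersion; no Cox–Reid adjustment or
  LFC shrinkage, so very small groups (< ~10 per class) will be
  anti-conservative.
* Surrogate-variable scores from the full matrix assume unwanted factors
  dominate sparse signal; a dense signature would be partially absorbed.
* In-sample AUCs are optimistic by construction; cross-validated scoring
  should be preferred for honest assessment of real panels.
* The permissive default thresholds of the endogenous-control screen
  reflect its published form, not a recommendation.
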