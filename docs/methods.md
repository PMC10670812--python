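# Methods

## Endpoint and data model

A cohort is one row per patient with clinical variables (age, BMI, blood
glucose, TNM stage, histology, molecular subtype, ki-67), PET
semiquantitative primary-tumor (PT) features (volume, SUVmax, SUVmean, MTV,
TLG, margin, morphology), scanner identifier, and outcomes (death and
progression flags, OS, PFS, follow-up, all in months).  Clinical benefit
(CB) is *derived*, never stored authoritatively: CB = no death **and** no
progression up to last follow-up.  A `cb` column in a CSV is cross-checked
against the flags at load and any mismatch is a validation error.  Units
are fixed; there is no auto-conversion.  Serialization is plain CSV at 12
significant digits, which round-trips all analyses exactly.

## The penalized logistic GAM

logit P(CB=1|x) = β₀ + Σⱼ fⱼ(xⱼ) + Σₖ gₖ(cₖ).

**Smooths.** Each fⱼ is a cubic B-spline expansion with `n_splines` basis
functions.  Boundary knots sit at the training min/max; interior knots at
equally spaced quantiles of the training values (falling back to an even
grid if heavy ties collapse quantiles).  Basis columns are centered at
their training means, so each smooth has exactly zero mean over the
training sample and the intercept absorbs all level.

**Penalty.** Second-order differences of the spline coefficients, taken as
divided differences on the Greville abscissae (knot averages) with each row
scaled by the smaller adjacent site gap.  Two properties motivate this
form:

* the null space is exactly the coefficient vectors affine in the Greville
  sites, i.e. exactly the **linear** functions of x for any knot spacing
  (B-spline linear precision) — so λ → ∞ collapses every smooth to an
  ordinary linear logit term, verified to ~1e-8 in predicted probabilities;
* with the min-gap row scaling the penalty reduces to the classic
  (1, −2, 1) stencil for even spacing and keeps bounded row entries under
  the wildly uneven quantile spacing produced by heavy-tailed covariates
  (a mean-gap scaling was tried first and measurably oversmoothed the
  data-dense region).

**Categorical terms.** One coefficient per state under a frequency-weighted
sum-to-zero constraint, implemented by reparameterizing through an
orthonormal basis of the constraint null space.  Every state therefore has
a defined estimate (not only non-reference contrasts), and the weighted sum
of state estimates is 0 by construction.

**Fitting.** Penalized IRLS with step-halving; an accepted step never
increases the penalized deviance.  Convergence at relative penalized-
deviance change ≤ 1e-8 or 100 iterations.  A tiny ridge (1e-8) on all
non-intercept coefficients makes the penalized Hessian strictly positive
definite (the difference penalty and the centered basis have null
directions).  Complete separation is detected (non-convergence or
coefficients beyond 30 in standardized units) and answered by an automatic
refit with ridge 0.1 plus a warning.  Effective degrees of freedom per term
are tr of the corresponding block of (XᵀWX+P)⁻¹XᵀWX at convergence and are
non-increasing in λ.

## The five-step development protocol

1. **Correlation filter** (threshold 0.8): Pearson |r| for continuous
   pairs, Cramér's V for categorical pairs, max |r| against one-hot
   indicators for mixed pairs; from each over-threshold pair the variable
   later in the keep-priority list (volume > TLG > SUVmax > SUVmean > MTV)
   is removed greedily.  On default synthetic data this removes MTV
   (r > 0.99 with volume) and keeps volume and TLG (r ≈ 0.7).
2. **Standardization**: per-variable z-scores with full-cohort mean/sd
   (population sd), stored for exact inversion so cutoffs are reported in
   raw units.
3. **Grid search**: candidate `n_splines` ∈ {8, 12, 16, 20} × λ ∈
   10^{−2..3}, each cell scored by mean out-of-bag AUC over `B_tune` = 50
   stratified bootstrap splits (common random numbers across cells); ties
   break toward fewer splines, then larger λ.  The basis floor of 8 exists
   because a basis with no interior knots cannot represent a plateau at
   all, while AUC — a pure ranking measure — barely distinguishes smoothing
   regimes (differences ~0.001 across the grid); cells that cannot express
   the saturating hypothesis class the pipeline exists to detect are not
   allowed to win on ranking noise.
4. **Ensemble**: `B_estimate` stratified-bootstrap refits (default 10,000;
   tests and the acceptance script use 500–2000) with knots, basis centers,
   categorical levels and weights frozen from the full cohort, so all
   iterations share one coefficient space.  Per-fit ridge defaults to 0.2
   in the ensemble: bootstrap bags of a 70-patient cohort quasi-separate in
   roughly a quarter of iterations, and without regularization the
   heavy-tailed per-iteration coefficients make the averaged model's Monte
   Carlo error an order of magnitude larger; ridge 0.2 also improves
   out-of-bag AUC on study-scale data.  Failed iterations are skipped and
   logged (more than 5% is an error).
5. **Averaging**: the final model's coefficients are the arithmetic mean of
   the per-iteration coefficients.

The stratified bootstrap draws n_stratum records with replacement within
each CB stratum, so every bag has exactly the cohort's class balance;
records never drawn form the out-of-bag test set (expected OOB fraction
(1−1/n)ⁿ ≈ 0.368 per stratum).

**State estimates.** For T and M the variable is dichotomized *before*
fitting (T1 vs T>1; M0 vs M1) and the ensemble is re-run with the same
protocol; the reported values are the bootstrap-averaged per-state
coefficients under the frequency-weighted sum-to-zero coding.  This coding
is this package's definition — the convention behind published per-state
estimates of this kind is generally not recoverable, and obvious weightings
do not make such pairs sum to zero.

**Cutoff detection.** On a partial-effect curve f over a grid, the cutoff
is the smallest grid value x\* such that |f(x) − f(x_max)| ≤ ε·range(f)
for all x ≥ x\*, with ε = 0.05.  Two refinements make the rule meaningful:

* a detected plateau must cover at least 2ε of the grid span — any strictly
  monotone curve trivially sits inside the terminal ε-band over its last
  ε-fraction, and such a sliver is not a plateau ("no cutoff found");
* the search grid spans [min, 95th percentile] of the training covariate.
  Beyond the well-supported range the smooth is extrapolation-dominated
  (the difference penalty continues the incoming slope where there is no
  data to bend it), and a level comparison anchored at the observed maximum
  would be dominated by that artifact.  Full-range curves are still
  computed and exported; only the cutoff search is restricted.

## Synthetic-cohort generator

The generator emulates the study's data structure with known truth:

* **Bounded normals** (age, BMI, glucose, activity, DLP, ki-67): truncated
  normals whose underlying parameters are solved so the *truncated* mean
  and sd equal the configured targets (naive truncation would shift the
  ki-67 mean by ~3.5 points).
* **PT volume**: truncated log-normal (upper bound 400 cm³ — anatomically
  implausible beyond), moment-matched so mean/sd equal 12.8/30.4; a normal
  cannot produce sd > 2× mean with positivity, and the truncation tames the
  extreme kurtosis that otherwise makes sample correlations erratic.
  **MTV** is volume times a log-normal factor near 1 (r > 0.99), so the
  correlation filter is exercised realistically.
* **SUV pair**: SUVmax log-normal (8.1, 7.2); SUVmean = SUVmax × ratio with
  ratio ~ Beta, damped by (V/median V)^−0.15 and capped at 0.98.  The
  damping encodes lower mean uptake in bulky (partly necrotic) tumors and
  is required by the target moments themselves: E[TLG] = 47.4 <
  E[SUVmean]·E[MTV] = 62.2 implies negative SUVmean–MTV covariance.  The
  ratio level (0.591) is calibrated so E[SUVmean] = 4.9.
* **Outcome model** (log-odds of CB): intercept 3.4754 (calibrated once so
  default CB prevalence is 55/70), piecewise-linear saturating effects
  −0.09·min(volume, 30) and −0.015·min(TLG, 160), M1 shift −2.5, and ±0.1
  per-SD age/BMI terms.  CB is Bernoulli in this probability.
* **Survival**: CB patients are event-free to last follow-up (OS = PFS =
  follow-up; follow-up ~ U(12, 56) months).  No-CB patients progress at a
  truncated-exponential time (scale 60 months) within follow-up; one third
  of them (the study's death fraction among no-CB) additionally die at a
  uniform time between progression and follow-up.  Subtype is independent
  of survival, so cross-subtype comparisons are null by construction.

What the generator does **not** emulate: inter-feature correlations beyond
those above (none are published), informative censoring, scanner effects
(both scanners draw from one distribution, matching the published ANOVA
null), or any image-level structure.  Passing recovery tests therefore
demonstrates that the estimation machinery works under the assumed
structure, not that the model is correct for real patients.

## Evaluation and survival analysis

ROC curves enumerate all distinct score thresholds; AUC is trapezoidal and
equals tie-adjusted Mann–Whitney concordance to 1e-12; the Youden index is
max(TPR − FPR) with the smallest optimizing threshold on ties.  The "AUC ±
spread" of the ensemble is reported as mean ± sd of per-iteration
out-of-bag AUCs; the in-sample AUC of the averaged model is reported
separately and labeled (it is optimistic).  Per molecular subtype both the
AUC and the accuracy at the global Youden-optimal threshold are reported,
because "accuracy by subtype" is ambiguous; a subtype with only one
observed class is flagged undefined rather than silently scored.

Kaplan–Meier estimation and the pairwise log-rank tests are delegated to
lifelines.  OS events are deaths; PFS events are progression or death.
Cross-subtype comparison is pairwise log-rank (the statistic is χ²(1)) with
Bonferroni multiplication by the number of pairs, capped at 1.  A published
"chi-squared test" on survival differences is read as the log-rank test —
the standard interpretation; a binned chi-squared on survival status cannot
be excluded but is not implemented.

Descriptive tables report mean ± sd per CB group with Welch t-tests
(unequal variances — the equal-variance assumption is not stated anywhere
and Welch is the safer default), categorical counts with one-decimal
percentages (rounded half away from zero) and Pearson chi-squared tests
without continuity correction; small expected cells produce warnings, not
errors.  The packaged count fixture reproduces every printed percentage
that is arithmetically consistent with its printed count; a handful of
published cells (e.g. the M-row 82.3% where 58/70 = 82.9%) disagree with
exact arithmetic, and this package reports the exact rounded values.

## Numerical and testing notes

* All randomness flows through numpy Generators seeded from
  `SeedSequence`; identical (config, seed) reproduces every output
  bit-identically, including ensemble JSON.
* The PIRLS optimum is verified against a generic BFGS maximizer of the
  identical penalized likelihood (≤ 1e-5 in coefficients on toys up to 50
  records and 8 basis functions); the basis against an independent
  Cox–de Boor recursion (≤ 1e-10); AUC against pair counting; the KM
  estimator against hand product-limit values; chi-squared direction
  against hypergeometric enumeration.
* Degenerate inputs: constant variables are dropped by the filter with a
  warning; zero-variance standardization, empty CB strata, single-class
  labels, unseen categorical states, negative times, and zero-margin
  contingency tables all raise informative errors; a flat partial-effect
  curve yields "negligible everywhere" without division by zero.

## Known limitations

* **Cutoff extraction is the fragile step.**  Only ~5–10% of covariate
  mass lies beyond each plateau onset, the out-of-bag AUC used for
  hyperparameter selection is nearly flat across smoothing regimes (ranking
  is insensitive to saturation), and the correlated volume/TLG pair shares
  attribution.  At n = 2000 the detected cutoffs scatter roughly 24–45 cm³
  around the true 30 cm³ (volume) and 90–170 around the true 160 (TLG),
  and can be reported as "not found"; at the 70-patient study scale they
  are unstable and should be read as descriptive, not inferential.
* **Partial-effect recovery carries a systematic component** of ~0.2
  log-odds (about 7% of the 2.7-logit volume effect range) from shared
  attribution between correlated smooths; it does not vanish with n.
* Smoothing selection targets discrimination, not curve estimation; a
  criterion aimed at calibration or curvature recovery would select
  differently and is out of scope here.
* The ensemble averages coefficients in a frozen basis; it does not
  propagate knot or standardization uncertainty.
* Problem sizes in the test suite and acceptance script (n = 70 and 2000;
  B = 100–2000) are chosen as desk-scale analyses; the protocol's default
  B_estimate remains 10,000.
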