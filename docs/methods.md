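# Methods

## Scope and data model

`qolmap` converts EORTC QLQ-C30 or FACT-G responses into the EQ-5D-5L
utility index, and estimates such mapping algorithms on new data. The
unit of analysis is a respondent row: age (years), a female 0/1
indicator, the source measure's subscale scores, optionally the five
EQ-5D-5L item levels (1–5) and the observed index. The analysis
population for model fitting is complete-case: rows missing the index
or any required covariate are dropped at fit/predict time with the
count recorded in the dataset metadata.

## Instrument scoring

EORTC QLQ-C30 (version 3) items are averaged per subscale into a raw
score RS and transformed linearly to 0–100: functioning subscales as
(1 − (RS−1)/3)·100 (higher = better), symptom subscales as
((RS−1)/3)·100 (higher = worse), global health status as ((RS−1)/6)·100
since its two items run 1 (worst) to 7 (best). A subscale is scored when
at least half of its items were answered; otherwise it is reported as
unavailable (NaN), never as zero. FACT-G (version 4) items (Likert 0–4)
are reversed where negatively worded (all physical well-being items; all
emotional well-being items except GE2) and summed with proration,
sum·n_items/n_answered, requiring at least 50% of a domain answered.
Scores are kept at full floating precision internally; display rounding
to one decimal happens only at I/O.

## Value sets

A value set is represented as an additive tariff: a decrement per
(dimension, level) with zero level-1 decrements and levels non-decreasing,
so index(state) = 1 − Σ decrements. This representation is what the
indirect-mapping expectation requires; non-additive tariffs are out of
scope. The bundled file `tariff_japan_synthetic.csv` is a **synthetic**
stand-in for the Japanese EQ-5D-5L tariff, whose published per-level
decrements are not redistributable here. It is calibrated so the two
published extremes hold exactly: worst state (5,5,5,5,5) → −0.025 and
second-largest attainable index → 0.895 (equivalently, the smallest
level-2 decrement is 0.105). Level patterns within dimensions are
plausible but constructed; analyses needing the real tariff must load it
from a 25-row `dimension,level,decrement` CSV. Loaded tariffs are
validated (completeness, zero level-1, monotone levels) and summarized
by enumerating all 3125 states.

## Regression engines

Six direct methods model the index itself; responses at exactly 1
define full health (state 11111 under any tariff).

- **Linear**: OLS; expectation x'β (not clamped).
- **Beta**: the index is rescaled by u = (y + 0.025)/1.025 to [0,1];
  mean–precision beta regression with logit link on μ and constant
  precision φ (reported as the scale parameter). Expectation
  −0.025 + 1.025·μ(x).
- **Tweedie**: log-link GLM on the disutility d = 1 − y, which carries
  the full-health mass as exact zeros. Expectation 1 − exp(x'β).
- **Tobit**: two-sided censored normal MLE with fixed bounds −0.025 and
  1 (hand-written likelihood on a generic-MLE scaffold; statsmodels has
  no tobit). Expectation is the closed-form mean of the censored normal.
- **Two-part linear / two-part beta**: logistic regression for
  P(full health), then OLS on the non-full rows, or beta regression on
  u = (y + 0.025)/0.92 (denominator 0.895 − (−0.025), so the largest
  non-full index maps to 1). Expectation p(x) + (1 − p(x))·m(x).

Transformed responses landing exactly on 0 or 1 are squeezed inward by
0.005 before beta likelihood evaluation (both beta variants); interior
values are untouched. The seventh method is **ordinal logistic
regression** per EQ-5D item under the parameterization
logit P(level ≤ j | x) = αⱼ + x'β with αⱼ increasing, chosen so that a
positive coefficient on a better-health covariate raises the
probability of good (low) levels; this convention is stated explicitly
because ordinal software differs (statsmodels' OrderedModel uses the
opposite sign on β, converted at fit time). Levels unobserved at fit
time receive ±∞ thresholds, i.e. zero predicted probability. The
indirect prediction 1 − Σ_items Σ_levels P·decrement equals the exact
expectation over all 3125 states by linearity; a brute-force enumeration
oracle verifies this to 1e−12 in the tests.

Wald P values (not likelihood-ratio) drive variable selection
everywhere; with single-df covariates the distinction is minor. Tobit
standard errors come from the numerical Hessian.

### Tweedie power

The variance power p ∈ (1,2) is profiled over the grid 1.1–1.9 (step
0.1) by extended quasi-likelihood, with dispersion at each candidate
estimated by Pearson χ²/df. EQL is undefined at exact zeros (the
log V(y) term); zeros are floored at 0.005 inside that term only — the
same magnitude as the boundary squeeze — leaving deviances and fits
untouched. The chosen power is recorded in the fit report and can be
fixed via `tweedie_power=`. Predictions below the tariff minimum are
possible (log link is unbounded below) and are the analyst's signal of
extrapolation; they are not clamped.

### Predictive simulation

Each method with a full generative law can simulate indexes: linear and
two-part linear draw normal residuals at the fitted σ; beta and
two-part beta draw Beta(μφ, (1−μ)φ) rescaled to the index range (with a
Bernoulli full-health draw where two-part); tobit draws the latent
normal and clamps; the indirect model draws each item's level from its
predicted category distribution and scores the state under the tariff.
Tweedie deliberately raises — the quasi-likelihood fit does not commit
to a distribution. All draws take an explicit seed.

## Development pipeline

Direct-mapping candidates are fixed conceptually: the five functioning
subscales, global health status, fatigue and pain for EORTC QLQ-C30;
the four well-being subscales for FACT-G; age and sex always enter.
Indirect candidates per item are the subscales with |Spearman ρ| ≥ 0.4
(EORTC) or ≥ 0.3 (FACT-G) against that item, computed with average
ranks for ties (subscale scores are heavily tied); a 1e−12 guard admits
correlations exactly at the threshold despite floating-point
representation. Constant subscales are excluded with a warning.

Backward selection drops the covariate with the largest Wald P while it
exceeds 0.15, refitting after each drop; intercepts and thresholds are
never dropped. Ties on the largest P drop the covariate later in the
declared order (deterministic and logged). Two-part models select per
part and indirect models per item equation — the only reading
consistent with the published algorithms' differing covariate sets per
column. Face-validity pruning then removes, simultaneously and with one
refit, covariates whose sign opposes the anticipated direction
(functioning/well-being/global health positive, symptoms negative,
age/sex unconstrained) *and* whose P exceeds 0.05; significant
wrong-signed covariates are retained. No multiple-testing adjustment is
applied anywhere — the selection thresholds are used as published.

Cross-validation partitions the sample at random (unstratified; the
source describes only a random division) into 9 near-equal folds
(903 rows → folds of 100–101), reruns the **full** pipeline — screening,
selection and, by default, pruning (configurable) — on each training
set, and averages fold-level RMSE, MAE and Pearson correlation
unweighted. Fixed seeds make reports bit-reproducible. Folds that
cannot support a two-part fit (no full-health rows) are flagged and
excluded from the average rather than silently imputed. Calibration
summaries compare observed subgroup means (95% CI as mean ± 1.96·sd/√n)
with simulated means, and pool simulated draws into a global ECDF.

## Synthetic cohorts

The study data are restricted, so the generator emulates their
structure with known truth. A one-factor Gaussian copula (default
loading 0.75, sign-flipped for symptom scales) drives the subscales;
each marginal is a piecewise-linear quantile function through the study
population's printed quantiles (min/5%/25%/median/75%/95%/max), snapped
onto the subscale's attainable grid (multiples of 100/(3k) for EORTC,
integers for FACT-G). Age follows the printed median 68 / IQR 58–74
(bounded 25–90); sex is Bernoulli(0.46). Defaults use n = 903, the
EORTC analysis population size. EQ-5D outcomes come from the published
coefficients as generating truth: `ordinal_truth` draws item levels
from the proportional-odds equations and scores them under the tariff
(producing the ceiling atom at 1, support down to −0.025 and indexes
only at tariff-attainable values); `twopart_truth` draws a Bernoulli
full-health indicator and a rescaled beta index (continuous support, no
item levels). The generating coefficients, copula loading and seed ride
along in a tamper-checked truth record for parameter-recovery tests.

What the generator does **not** emulate: multi-factor dependence among
subscales (one latent factor gives roughly exchangeable inter-subscale
correlation ≈ 0.56), item-level response behaviour of the source
questionnaires (subscales are drawn directly), informative missingness,
or clinical covariates beyond age/sex. Passing recovery and pipeline
tests therefore demonstrates correctness of the estimation machinery
under the stated generating laws, not predictive accuracy on real
patients. Under defaults the simulated index quartiles fall within ±0.1
of the study population's printed quartiles — a realism check, not a
reproduction claim.

## Problem sizes and numerical choices

Parameter-recovery checks use cohorts of n = 5000 over 20 replicate
seeds, matching the estimator's Monte-Carlo error to a 3-SE tolerance;
pipeline behaviour checks use n = 903 (the study's size) or n = 2000
where a selection property needs power. Optimizers: BFGS with
Nelder–Mead fallback for the ordinal models, default statsmodels
settings elsewhere; non-convergence raises rather than returning a
silent partial fit. Logistic separation surfaces as a convergence error.
Full health is y = 1 exactly (tolerance 1e−12). Predictions are not
clamped to covariate ranges; the published algorithms instead reject
out-of-range inputs, because the models were fit on bounded scales.

## Known limitations

- The bundled tariff is synthetic (anchors only); real-tariff results
  require supplying the genuine value set file.
- Coefficient uncertainty of the published algorithms
  (variance–covariance matrices) is carried as a data slot only;
  standard errors of mapped indexes are not computed.
- Mixture models for utility data and item-level (rather than subscale)
  predictors are out of scope.
- A true-null covariate survives backward selection with probability
  equal to the retention level (≈ 0.15) per fit; selection is a
  screening device, not a guarantee.
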