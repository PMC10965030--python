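# Methods

## Scope and estimand

`mortalq` estimates marginal (population-averaged) conditional quantiles of
a Frailty Index (FI) trajectory in a cohort subject to death and
frailty-dependent intermittent missingness. The estimand is a *mortal-cohort*
quantity: the τ-quantile of the FI among individuals alive at each occasion,
as a linear function of age and covariates. This deliberately differs from
an immortal-cohort model that treats death as censoring; no imputation of
post-death frailty is attempted.

## Frailty Index construction

The FI is the deficit-accumulation index: each of K items (default 40) is
recoded to a deficit score in [0, 1] by a declarative rule (threshold on a
numeric value, category map, or identity), and

    FI = (sum of non-missing deficit scores) / (number of non-missing items),

reported only when at least `min_valid` items (default 35) are non-missing.
The denominator counts items actually considered — the standard
deficit-accumulation convention — so adding a missing item never changes the
FI, only the validity count. Fractional scores (e.g. 0.5 for an intermediate
category) are allowed. The battery is fully parameterized; the bundled
40-item YAML battery is synthetic (illustrative cutoffs spanning the usual
FI dimensions), not any survey's restricted coding.

## Quantile model

Two formulas for the trajectory of FI_ij on age A_ij (years, centered at
65):

* base: intercept, S (sex, 1 = female), E (education years, centered at the
  analysis-sample mean), BA (baseline age, centered at 65), A, A·S, A·E,
  A·BA;
* cohort: base plus Bo (born 1946 or later) and A·Bo.

Education centering is recomputed from whatever sample is being fit —
including inside every bootstrap replicate — so replicates are
self-contained. The centering constants travel inside each fitted model, so
reference-curve prediction on the raw age axis is unambiguous.

### Solver

The point estimator minimizes the weighted check loss
Σ_ij w_ij ρ_τ(FI_ij − x_ij'β), ρ_τ(u) = u(τ − 1{u<0}), pooling observations
under an independence working assumption. The default solver is exact: the
*dual* linear program (maximize Σ w_i y_i a_i subject to X'diag(w)a = 0,
a_i ∈ [τ−1, τ]) solved with HiGHS; the coefficient vector is read off the
equality-constraint marginals and the optimum equals the primal check loss.
The dual has p equality constraints instead of n, which makes the
bootstrap's hundreds of refits cheap without sacrificing exactness. A
smoothed IRLS fallback (|u| ≈ √(u²+ε), ε = 1e−8) exists for very large
dense problems.

Degeneracy: at an LP vertex the minimizer set can be an interval; the solver
returns one vertex deterministically, and exactness is asserted on the loss,
not the coefficients. Every fit records its subgradient bracket (weighted
fraction of negative residuals ≤ τ ≤ weighted fraction of non-positive
residuals), which is the optimality certificate the tests check. Rank
deficiency raises an error naming the collinear columns (QR with pivoting).
Quantile crossing across τ is possible (each τ is fit separately) and is a
reportable diagnostic, not an error.

## Stabilized observation weights

Under unconditional MAR — observation may depend on the recorded history
but not on survival time — each observed record of an alive individual at
occasion j ≥ 2 is weighted by

    w*_ij = p_MCAR / p_MAR,
    p_MCAR = P(R_ij=1 | Al_ij=1, sex, entry indicator),
    p_MAR  = P(R_ij=1 | Al_ij=1, sex, entry indicator, lag FI,
               observed-at-previous-visit, lag FI × sex),

both logistic regressions fit by ML on the pooled alive person-waves from
the second visit onward. Entry-wave records get weight 1 (everyone is
observed at entry by construction). A sensitivity variant adds education
and lag FI × education to the MAR model.

Choices the estimator has to make, and the defaults:

* **Lagged FI** = the most recent *observed* FI before occasion j (the
  history subscript 1 ≤ k < j), with a strict previous-wave-only variant as
  an option. When no earlier FI is observed the lag is imputed with the
  sample mean of baseline FI (each individual's first observed wave),
  computed once per sample and reused by that sample's bootstrap replicates.
* **Study-entry indicator** = occasion j−1 was the individual's entry wave
  (it distinguishes first re-interview opportunities).
* **Probability clipping** to [0.01, 0.99] before the ratio, disable-able;
  clipped rows are counted and reported. Small samples otherwise produce
  unstable extreme weights.
* Individuals alive but unobserved through later waves contribute
  observation rows as non-respondents; vital status is taken at face value
  (the generator makes it fully known — see limitations).
* A constant observation outcome or perfect separation raises an error
  suggesting the penalized (L1) fallback rather than silently producing
  degenerate weights.

## Inference

Within-person correlation is handled in the variance step: a bootstrap for
longitudinal data resamples n individuals with replacement, each carrying
all their waves (duplicates get distinct replicate-local ids), B = 200 by
default. Within a replicate the same resample is used for every τ, so the
per-replicate differences β̂_b(τ1) − β̂_b(τ2) carry the covariance needed for
cross-quantile equality tests; their SD is that test's SE. Single-coefficient
tests use z = estimate / bootstrap SD with normal p-values. Weights are
re-estimated inside every replicate by default — weight estimation is part
of the estimator, so its variability belongs in the SE — with a fixed-weights
mode for smoke tests. Failed replicates are dropped and counted (never
redrawn, keeping the draw sequence seed-stable); a failure rate above 20%
is an error. Reference-curve bands are percentile intervals of replicate
predictions, built from unclipped linear predictions; point curves are
clipped to [0, 1] only for display.

## Synthetic mortal-cohort generator

The generator produces the study conditions the estimator is designed for
and is the package's source of ground truth.

    FI_ij = x_ij'β + (σ0 + γ·A_ij) · ε_ij

* **Location coefficients β** (defaults): intercept 0.15, sex 0.004,
  educ −0.0008, baseline age −0.005, cohort 0.008, age 0.0067, age·sex
  0.0020, age·educ −0.0004, age·baseline-age 0.0004, age·cohort 0.0007 —
  magnitudes of weighted median estimates reported for European biennial
  ageing panels on the FI scale.
* **Scale** σ0 = 0.05 (FI units at 65), γ = 0.003 per year: positive γ makes
  the residual spread grow with age, so the true age slope at quantile τ is
  β_age + γ·q_ε(τ), strictly increasing in τ — upper-tail frailty progresses
  fastest.
* **Residual law** ε: standard normal, or a right-skewed option
  (Exp(1) − log 2, median zero). Because the median of ε is zero, the true
  τ = 0.5 coefficients equal β exactly; other quantiles shift only the
  intercept (by σ0·q_ε(τ)) and the age slope (by γ·q_ε(τ)). These
  closed-form truths drive the recovery tests.
* **Within-person correlation** `error_corr` = 0.6: exchangeable residual
  correlation from a shared per-person component, constructed so the
  marginal law — and hence the truth formulas — is exactly unchanged
  (normal: √ρ·b_i + √(1−ρ)·e_ij; skewed: Gamma(ρ) + Gamma(1−ρ) = Exp(1) by
  additivity). Persistence is what makes frailty-dependent missingness
  informative: with ρ = 0, selection on the lagged FI would be independent
  of the current residual given covariates and would bias nothing, leaving
  the weighting correction vacuous. 0.6 reflects the strong tracking of
  frailty within individuals.
* **Cohort**: n individuals enter at a uniform age in [65, 85], six waves
  two years apart; 53% female; education N(9.6, 4.5²) truncated at 0; 8%
  born 1946+.
* **Death**: per-wave logistic hazard on the current true FI and age,
  absorbing; defaults (−5.25, 4.0, 0.05) calibrated once by simulation to
  ≈ 21–22% deceased over follow-up, the mortality burden of the emulated
  cohorts. Death is evaluated before observation, so a wave-j death yields
  no wave-j interview.
* **Observation**: wave 1 always observed; later, alive individuals are
  interviewed with logistic probability on the previous wave's *true* FI
  and sex; defaults (0.75, −2.0, 0.1) give ≈ 60% of alive person-waves
  observed and ≈ 22–29% of individuals with only one or two interviews.
  Using the true lagged FI (which downstream weight models can only
  approximate from observed records plus imputation) intentionally
  preserves the estimator's real-world approximation gap.
* Latent FI values are clamped to [0, 1]; the clamp count is reported and
  defaults keep it below 1% so the truth formulas stay valid to tolerance.

What the generator does *not* emulate: country strata and survey weights,
unknown vital status (51% in real panels of this design; the simulator's
status is fully known), item-level FI measurement error in the analysis
panel (the FI enters directly; the item battery machinery is exercised
separately), non-linear age trajectories, and MNAR missingness. Passing
recovery tests therefore demonstrate correctness of the estimator under its
own assumptions, not robustness to their violation.

## Problem sizes used in validation

Recovery and correction checks run at n = 2000 individuals × 6 waves (the
desk-scale default, large enough for stable tail-quantile estimates);
Monte-Carlo SEs for recovery come from 50 repetitions at n = 400 scaled by
√(400/2000); the mortal-cohort correction is averaged over 20 repetitions;
cross-quantile test size uses 100 repetitions at n = 150 × 4 waves with
B = 50; the bootstrap SE calibration averages 5 datasets of n = 500 with
B = 200 (the bootstrap variance of a sample median fluctuates at the
O(n^−1/4) scale dataset-to-dataset, so a single dataset is an unreliable
judge of the ratio).

## Known limitations

* The unconditional-MAR weights correct the observation process among the
  alive, not mortality selection itself; both weighted and unweighted fits
  target the mortal cohort through the alive-pooling design.
* Visit-specific ratio weights (not cumulative products) follow the
  pooled-logistic design; they are approximate when observation depends on
  history older than the modeled lag.
* Percentile bands assume the replicate distribution approximates the
  sampling distribution; with B = 200 the band endpoints themselves carry
  Monte-Carlo noise of a few percent.
* The LP returns one vertex of a possibly non-unique solution set;
  coefficient-level comparisons across solvers are only meaningful up to
  degeneracy (loss-level comparisons are exact).
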