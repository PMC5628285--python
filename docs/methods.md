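# Methods

This note records the models, conventions and numerical choices behind
`cesdcat`, and what the synthetic-data checks do and do not establish.

## Measurement model

Responses are four ordered categories coded 0–3 internally regardless of
on-disk coding (`coding_offset`, default 1, handles 1–4 files).  The
graded response model is used throughout in the **logistic metric with no
scaling constant**: boundary curves
`P*_k(θ) = expit(a(θ − b_k))`, category probabilities by differencing.
The 1.702 constant appears only when slopes are converted to standardized
factor loadings, `λ = (a/1.702)/√((a/1.702)² + 1)`.  This is the only
convention under which the packaged bank's slopes and printed loadings
are mutually consistent (a = 3.70 ↔ λ = 0.91; a = 1.13 ↔ λ = 0.55).

Item information is Samejima's `Σ_k (P*'_k − P*'_{k+1})²/P_k`, which
equals the expected (Fisher) information; test information is additive
and `SE(θ) = 1/√I(θ)`.

## Calibration

`fit_grm` maximizes the marginal likelihood under a standard-normal
latent density by EM:

- quadrature: 41 equally spaced nodes on [−5, 5], weighted by the normal
  density (re-normalized);
- M-step: per-item maximization with thresholds kept strictly ordered via
  a log-gap parametrization (Nelder–Mead polish plus BFGS — same fixed
  point as per-item Newton);
- convergence: max absolute parameter change < 1e−4, cap 500 iterations;
  the log-likelihood trace is retained and is non-decreasing;
- standard errors: empirical cross-product of per-person marginal score
  vectors (scores by central finite differences, h = 1e−4);
- categories never observed for an item are collapsed into the nearest
  lower category before fitting (logged); anchored items (used in
  DIF-adjusted recalibration) are held fixed and keep all categories.

At n = 1000 the generating slopes of the packaged bank are recovered
within ±3 SE for ≥ 15/17 items; the whole fit takes ~10 s.

## Scoring

ML scoring maximizes the response log-likelihood on [−4, 4] (bounded
Brent, xatol 1e−6; the bounds are consistent with observed decile means
spanning ±1.7).  All-floor/all-ceiling patterns have no interior maximum:
the estimate is clamped to the bound with `converged=False`.  MAP scoring
adds a normal prior (default N(0, 1)); its SE is `1/√(I(θ̂) + 1/σ²)`.
With no responses MAP returns the prior mode with SE = σ.

Note the two SEs are evaluated at different points; the prior's
information advantage holds at a common θ, but a sparse extreme pattern
can place the ML estimate on a local information bump where the raw ML
SE is smaller than the MAP SE at the shrunken estimate.

## Diagnostics

**Yen's Q3** scores every person by MAP on the full vector (so extreme
responders stay finite), forms residuals `x − E[x|θ̂]` and correlates
them; |Q3| > 0.20 flags a pair.  Under the null the flag rate is
essentially zero at n = 2000 (residual correlations average slightly
negative, as expected when θ̂ is estimated from the same responses).

**Testlets**: locally dependent items are summed into one polytomous
super-item with `Σ(m_i − 1) + 1` categories; banks refit after testlet
formation legitimately mix category counts.

**Item fit** is a stratified Pearson χ² with two choices made for
calibration: persons are stratified (default 10 groups) by their
*rest-score* EAP — the posterior excluding the item under test, so an
item's own response cannot drive its stratum — and expected counts
average category probabilities over that posterior rather than plugging
in a point estimate.  Cells with expected count < 5 are pooled into a
neighbouring category; df = used cells − strata − item parameters,
floored at 1.  Under the null ≤ ~5–10% of items flag at p < 0.05; a
slope misfit of 3 vs 1 is flagged at p ≪ 0.01.

**DIF** fits three nested proportional-odds models per item (statsmodels
`OrderedModel`, BFGS): trait only; + group; + trait×group.  Uniform,
non-uniform and total DIF are likelihood-ratio tests (df 1/1/2).  The
operating flag is the relative change of the trait coefficient between
the first two models (> 1%); the McFadden pseudo-R² difference
(model 3 − model 1, against the intercepts-only null, which has a closed
form) grades severity with the conventional 0.13 bar.  Both thresholds
are parameters because published practice mixes several rules.  The
matching variable is the MAP score from the pooled calibration; no
iterative purification is attempted.  DIF-adjusted rescoring refits the
GRM within each group with non-flagged items anchored at pooled values
(a shared metric) and flagged items free, then rescores each person with
their group's parameters; the report is the Pearson correlation between
original and adjusted scores plus a Welch t comparison.

## CFA

The one-factor CFA treats Likert scores as continuous and fits the
correlation matrix by maximum likelihood (analytic-gradient L-BFGS-B,
uniqueness floor 0.005 against Heywood cases, flagged when active).
χ² = (n−1)·F_ML; CFI/TLI against the independence baseline, truncated to
[0, 1]; RMSEA with a 90% CI by noncentral-χ² inversion.  Polychoric CFA
is out of scope.  Loadings are unidentified item-by-item under exact
independence (any split of λ² + ψ = 1); only the implied covariances are
testable there.

## Mokken scalability

`H_ij = σ_ij / σ_ij^max`, where the maximum covariance given both
marginals is attained by the comonotone coupling (independently sorted
columns paired); item and scale H are ratios of sums.  Item standard
errors use a first-order delta-method approximation: the variance of the
numerator sum via per-person influence values with the denominator fixed.
Item selection removes the single lowest-H item while it falls below
h_min = 0.30, recomputing after each removal (sequential removal is the
conservative reading of repeat-until-clean strategies); pairwise H values
of surviving items are unchanged by removals, only the aggregates move.

## Adaptive-testing engine

Selection is maximum Fisher information at the current estimate, ties to
the lower bank index; the first item is chosen at the prior mean (0).
Interim scoring is **Bayesian modal** by default, and the stopping check
(after each response) uses its prior-inclusive SE; the final estimate is
recomputed by ML (MAP fallback for patterns that are still all-floor or
all-ceiling).  With the 0.32 rule this leaves final ML SEs at ~0.33–0.34,
matching the study's reported decile SEs; an `interim="ML_mixed"` policy
(ML as soon as the pattern is mixed) is available and yields tests about
one item longer.  "Mixed" is operationalized as the exact finiteness
condition for GRM ML: not all responses at the floor category and not all
at the ceiling.  SEs use expected (Fisher) information.

## Simulation studies

Study 1 draws n true severities from N(0, 1) (default n = 1042), runs a
fully stochastic CAT per simulee (each on an independent RNG substream
spawned from the master seed, so results are order-independent), and
summarizes by deciles of true θ: mean θ, RMSE, mean bias, mean length,
mean SE.  Decile sizes are ⌊n/10⌋ with the remainder going to the extreme
deciles first (n = 1042 → 105 in D1 and D10).  Study 2 replays fixed full
response vectors post hoc; the reference score is the full-bank ML
estimate of the same vector and the headline is the CAT-vs-full-bank
Pearson r (≥ 0.95 on bank-simulated data; 1.0 exactly when the stopping
threshold is 0).  Per-decile RMSE ≥ |mean bias| always (Jensen).

## Synthetic-data generator

The generator emulates the study conditions the pipeline assumes:
~1000 respondents per cohort (defaults 1018 evaluation / 1042
validation), θ ~ N(0, 1), responses from the packaged bank, and a
0.66/0.34 gender split.  Generation uses the ordinal-regression
representation (propensity `a(θ − b_k) + e`, e standard logistic), which
makes three injections exact and keeps the null design bit-identical to
plain GRM sampling:

- **second dimension**: all off-dimension items share one independent
  trait θ₂, entering as `√(1−λ₂²)·θ + λ₂·θ₂` so total latent variance
  stays 1;
- **local dependence**: a shared N(0, 1) shock scaled by
  `√(ρ/(1−ρ))·π/√3` is added to both propensities, putting the latent
  residual correlation exactly at ρ (the observed Q3 is attenuated by
  categorization but comfortably exceeds 0.20 at ρ = 0.5);
- **DIF**: the named group answers with thresholds b + δ (uniform) and
  slope a·κ (non-uniform).

What passing tests show — and do not.  The generator produces clean
logistic-GRM data plus the stated violations; real questionnaire data
additionally carry response styles, skewed trait distributions,
demographic structure and item content effects none of which are
emulated.  Detection-power results (Mokken removal, Q3 flags, DIF power
at δ = 0.5 and n = 2000) therefore characterize the methods under the
model, not field performance.

## Problem sizes and determinism

Test and simulation sizes are chosen to match the study where stated
(n = 1042 for the simulation studies; n = 1000–2000 for recovery and
power checks, the smallest sizes at which the checked effects are
decisively separated from noise).  Every stochastic routine takes an
explicit seed; master seeds expand to substreams via `SeedSequence`, and
`SimulationDesign.child_seeds()` exposes the derivation so any dataset
can be reproduced piecewise.

## Known limitations

- The published test-information maximum (18.71) is not derivable from
  the published item parameters, which yield a maximum of 14.07 at
  θ = 0.43 under the same convention that reproduces all printed
  loadings; the information functions here report the latter.
- The limited-information M2 fit statistic is out of scope; model
  adequacy is covered by the Q3 / testlet / item-fit battery.
- The CAT engine implements no exposure control or content balancing.
- CFA is linear-ML on Pearson correlations; with 4-category items its
  absolute fit indices are approximations (polychoric input would be the
  stricter choice).
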