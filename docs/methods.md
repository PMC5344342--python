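# Methods

## Model

The package models a population of non-optimistic agents judging their own
chance of a future life event relative to the average person's. Each event
has a true base rate *p* ∈ (0,1) — the average person's risk. An agent may
hold a *subjective* base rate p̂ and private binary diagnostic evidence
from a cue with sensitivity *s* and false-positive rate *f* (positive
likelihood ratio s/f; the default cue (0.8, 0.2) has LR+ = 4 and
LR− = 0.25). Posterior personal risk follows Bayes' theorem; the frequency
of positive results in the population follows the *true* base rate
(w+ = p·s + (1−p)·f). Two exact properties anchor everything:

* **Conservation.** When p̂ = p, the result-weighted mean of the two
  posteriors equals p exactly (law of total probability). This is the
  premise that makes a non-zero group mean look like bias — and the
  property the artifact mechanisms break.
* **Uninformative cue.** With s = f the posterior equals the prior, so no
  agent can differentiate themselves and every comparative rating is zero.

Base-rate regression is modelled as linear shrinkage toward the midpoint,
p̂ = (1−λ)p + λ/2 with λ ∈ [0,1]. The functional form of the regressive
distortion is not uniquely determined by the phenomenon (any contraction
toward ½ produces over-estimation of rare and under-estimation of common
events); linear shrinkage is the simplest such map, is exactly invertible,
and makes the λ = 0 and λ = 1 limits transparent. Default levels for curve
families are λ ∈ {0.2, 0.4, 0.6}; the study generator uses the middle
value 0.4.

## Response scales and policies

Comparative ratings live on a bounded integer scale [−U, +U]. Two response
policies are implemented:

* **perfect_predictor** — fixed responses for the at-risk minority and the
  majority (e.g. +3 / −1 in the classic worked example);
* **proportional** — a linear map of the comparison Δ = posterior − p̂,
  normalized by the largest possible deviation max(p̂, 1−p̂), so the extreme
  comparison reaches the scale endpoint:
  response = clip(gain · Δ/max(p̂, 1−p̂) · U, −U, +U).

Rounding to scale integers is a policy flag, **off** for population
mechanism curves and **on** when generating discrete Likert data. The
reason: with the continuous map, unbiased agents with truthful base rates
average to exactly zero (conservation survives any linear transform), so
the λ = 0 regression curve is identically zero — the correct no-artifact
baseline. Rounding is itself a (small) scale artifact and belongs in the
simulated response process, not in the definition of the population curve.

A consequence worth noting: with the *continuous* proportional policy, the
mean score scales linearly in U, so scale width is irrelevant after
normalization. The claim that wider scales attenuate less is therefore
checked on rounded integer responses, comparing the midpoint-normalized
mean |score|/U across widths, where it holds (0.060 at ±4 vs 0.0036 at
±100 for a 6% base rate).

## Mechanism curves

`mechanism_curve` evaluates the mean comparative score over a base-rate
grid (default 0.01..0.99 step 0.01):

* *attenuation*: the perfect-predictor population mean;
* *undersampling*: the same averaged over Monte-Carlo binomial samples of
  size n (default 10⁵ replicates — large-scale published simulations use
  10⁶, but the Monte-Carlo standard error at 10⁵ is already an order of
  magnitude below the effects displayed, and the exact binomial computation
  is available as `undersampling_excess_analytic` in any case);
* *regression*: Bayesian agents with shrunk subjective base rates, scored
  by the proportional policy.

Tie handling in the undersampling excess: when n·p is an integer, samples
that represent the minority exactly are excluded from both the "under" and
"over" counts. This makes the excess exactly zero at p = ½ and matches the
under/over-sampling semantics. The excess is reported as a *proportion* of
samples; an absolute count over the replicate budget would carry the same
information scaled by reps.

All three curves are negative below p = ½, zero at ½ and positive above
(undersampling within Monte-Carlo error), and antisymmetric about ½ under
symmetric policies with the symmetric default cue (s + f = 1).

## Synthetic study generator

`generate_study1` emulates a 102-participant × 40-event rating study. The
packaged event list carries the published group-mean perceived frequencies
(divided by 100) as base rates; its per-event desirability and
controllability columns are **synthetic** hand-assigned plausible values,
since only qualitative descriptions of them are published. Per
participant×event:

1. subjective base rate = clip₀₁((1−λ)p + λ/2 + ε), ε ~ N(0, σ_f/100),
   with σ_f = 15 on the 0–100 scale — a typical magnitude for lay frequency
   estimation error;
2. frequency estimate = round(100 · subjective);
3. outcome drawn from the true base rate, diagnostic result from (s, f)
   given the outcome, posterior by Bayes' rule on the *subjective* base rate;
4. comparative rating = proportional policy on (posterior − subjective)
   + β_des·(desirability/5) + N(0, σ_r), rounded and clipped to −5..+5,
   with σ_r = 1.0 rating units and β_des = 0 by default (the null world);
5. desirability/controllability ratings = event values plus N(0,1)/N(0,1.5)
   noise, rounded and clipped to their scales.

Randomness uses one master seed with per-participant substreams
(`SeedSequence.spawn`), so participant *i*'s data are invariant to the
total number of participants generated.

What the generator does **not** model: question-order and block effects,
participant-level response styles (acquiescence, scale-end avoidance),
correlated evidence across events, and any real covariance between
desirability and base rate beyond the fixture's fixed values. Passing
tests therefore show that the *pipeline* is calibrated and sensitive under
the stated response model, not that real raters behave this way.

Calibration facts computed by the acceptance script at these defaults: the
type-I rate of the by-item desirability coefficient over 500 seeds is 0.05
(band 0.03–0.07), and a β_des = 1 effect is recovered with correct sign and
p < .05 in ≥ 90% of 100 seeds.

`generate_experiment` produces balanced 2 (severity) × 2 (target: self vs
other) between-subject designs, estimates = cell mean + N(0, σ) clipped to
[0,100], default 50 per cell and σ = 24, with an optional within-subject
scenario factor realized as additive scenario offsets. Mixed
(within×between) partitions are deliberately out of scope; within-subject
scenarios are analyzed per scenario or after participant-mean collapsing,
since the optimism and severity contrasts of interest are between-subjects.

## Analysis battery

* **Median-split cells**: events are classed positive/negative by the sign
  of their mean desirability rating and split rare/common at the
  within-valence median of mean perceived frequency; with an odd count the
  single median event is excluded (it belongs to neither half). Cell
  means/SEs aggregate per-participant cell means.
* **By-item regressions**: predictors are z-scored *across events* (the
  regression operates on the 40 event means); interactions are products of
  z-scored mains, re-standardized, so all coefficients are standardized
  betas. Forward selection is strictly staged — main effects exhaust stage
  1 before two-way interactions are candidates, then the three-way — with
  an F-to-enter criterion at p < .05 (the entry statistics published for
  this design are consistent with a .05 rule). The simultaneous variant
  fits all seven terms. Condition numbers above 10⁸ raise a collinearity
  error.
* **By-subject partials**: per participant, ratings are regressed on
  frequency estimates and the residuals correlated with desirability; a
  participant whose ratings are numerically fully explained by frequency
  contributes r = 0 (nothing left for desirability) rather than an
  undefined correlation from degenerate residuals; participants with
  constant predictors are excluded and counted.
* **Sign test**: exact two-sided binomial p as the doubled smaller tail,
  capped at 1 — the convention that reproduces the printed marginal p for
  14 of 40 events (.08); the minimum-likelihood summation convention gives
  a different value and is not used.
* **Factorial ANOVA**: statsmodels OLS with sum-to-zero contrasts and Type
  III sums of squares (meaningful for the unbalanced retained cells of
  filtered experiments); partial η² = SS_effect/(SS_effect+SS_error);
  simple effects of target within each severity level use the pooled error
  term.
* **Partial correlation**: the first-order formula
  r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), cross-checked against
  pingouin in the tests. The published existence proof — a comparative
  score computed literally as the self/average estimate ratio yields
  opposite-signed partials with the larger magnitude for the self estimate,
  mimicking "egocentric weighting" — is reproduced on a synthetic
  self/average table; the original supplementary table of per-event
  estimates is distributed as a separate document and is not re-published
  here, so the exact published partials (.65 / −.81) cannot be recomputed
  self-contained. The corresponding test states how to supply the table.

## Bayes factors

`jzs_bf_ttest` computes BF01 = f(t|δ=0)/∫f(t|δ)π(δ)dδ with f the
noncentral-t density (noncentrality δ√(n₁n₂/(n₁+n₂))) and π a Cauchy with
default scale √2/2, optionally truncated to one sign and renormalized (×2
on the half-line). The one-dimensional noncentral-t marginal is equivalent
to the two-parameter (δ, g) JZS formulation for a Cauchy prior on δ and
avoids a second quadrature dimension. Numerics: the substitution
δ = scale·tan(θ) maps the prior to the uniform density 1/π on
(−π/2, π/2), so the Cauchy tails are integrated exactly; adaptive
quadrature is anchored at the likelihood peak θ = atan(t/(scale·√n)), with
relative error of order 10⁻⁸ (well inside the 10⁻⁴ requirement).
scipy's noncentral-t evaluator overflows at large df × noncentrality — a
region where the true density has underflowed — so evaluations are masked
to the 25σ neighbourhood of the mode and non-finite results treated as
zero; the discarded mass is Gaussian-small in the noncentrality.

Identities used as correctness checks: bf10(two-sided) is the exact
average of the two half-prior bf10s; both truncations coincide at t = 0;
BF01 → 1 as the prior scale → 0; and an independent Monte-Carlo
prior-predictive estimator (rejection sampling for truncation) agrees with
quadrature within 3 MC standard errors over a (t, n) grid.

`anova_model_bf` compares factorial models via the single-g Zellner–Siow
marginal, BF10 = ∫(1+g)^((n−1−k)/2) (1+g(1−R²))^(−(n−1)/2) π(g) dg with
π(g) = InverseGamma(½, n·scale²/2) and scale 0.5 on standardized effects.
This is an approximation relative to implementations that integrate one g
per factor (and it treats within-subject scenario rows as exchangeable);
it is used for model *ordering*, at which it is reliable for these design
sizes, not for reproducing any published BF value — those depend on
unreleased raw data.

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: 10⁵ Monte-Carlo
replicates for undersampling (agreement with the exact binomial within 3 MC
SE), 500 null seeds / 100 effect seeds for pipeline calibration, 5×5 (t,n)
grids with 5–6·10⁴ prior draws for the Bayes-factor oracle, conservation
checked to 10⁻¹². These sizes put every Monte-Carlo standard error at least
an order of magnitude below the quantity being checked while keeping a full
run in the minutes range.

## Known limitations

* The regression-level λ values behind published curve figures are not
  recoverable; curves are reproduced qualitatively (sign, ordering,
  antisymmetry), not point-for-point.
* Event desirability/controllability fixture values are synthetic; analyses
  that depend on their real covariance with frequency are exercised only
  structurally.
* The single-g ANOVA Bayes factor and the simplified handling of
  within-subject scenarios are approximations, as noted above.
* Published real-data statistics (group means −0.32/−0.46, the 58.4%
  by-item variance share, printed F and BF values) require the unreleased
  participant data and are treated as qualitative patterns the null-world
  generator should (and does) reproduce in kind, not as numeric targets.
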