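"""The three statistical-artifact mechanisms of the comparative method.

Comparative risk studies elicit "my chance vs. the average person's" on a
bounded bipolar scale and read a non-zero group mean as bias.  Three purely
statistical mechanisms push that mean away from zero for rare events even
when every respondent is unbiased:

* **scale attenuation** — the bounded scale cannot let a small at-risk
  minority balance the majority (a 6% minority would need a response 15.67
  times further from zero than the majority's);
* **minority undersampling** — in finite random samples the minority
  outcome class is more often under- than over-represented, dragging
  sample means further toward the majority response;
* **base-rate regression** — estimation noise on the bounded probability
  scale pulls subjective base rates toward 0.5, and Bayesian posteriors
  built on those regressive base rates inherit the distortion.

This module reproduces each mechanism as a simulation over a grid of event
base rates, yielding the signature "rarer events look more optimistic"
curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import DiagnosticTest, EventSpec, population_posteriors, regress_toward_midpoint

__all__ = [
    "ResponseScale",
    "ResponsePolicy",
    "SimulationCurve",
    "perfect_predictor_mean",
    "perfect_predictor_sample_mean",
    "required_balance_multiplier",
    "undersampling_excess_analytic",
    "simulate_undersampling",
    "mechanism_curve",
]

Mechanism = Literal["attenuation", "undersampling", "regression"]


@dataclass(frozen=True)
class ResponseScale:
    """Bounded integer comparative scale, e.g. -3..+3 or -5..+5."""

    lower: int = -3
    upper: int = 3

    def __post_init__(self) -> None:
        if not self.lower < 0 < self.upper:
            raise ValueError(f"scale must straddle zero, got [{self.lower}, {self.upper}]")

    @property
    def is_symmetric(self) -> bool:
        return self.upper == -self.lower

    def clip(self, x):
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class ResponsePolicy:
    """Rule mapping risk comparisons onto the bounded response scale.

    ``perfect_predictor`` mode: respondents know their own outcome; those
    who will experience the event answer ``minority_response`` and the rest
    ``majority_response`` (the names reflect the rare-event case the
    mechanism targets).

    ``proportional`` mode: a continuous comparison ``delta`` (own risk minus
    the reference/average risk) is mapped linearly so the largest possible
    deviation ``max(ref, 1 - ref)`` reaches the scale endpoint::

        response = clip(gain * delta / max(ref, 1 - ref) * upper, lower, upper)

    ``round_responses`` additionally rounds to scale integers — appropriate
    when generating discrete Likert ratings; population mechanism curves
    keep the linear map so that unbiased agents average to exactly zero
    when no artifact operates.
    """

    mode: Literal["perfect_predictor", "proportional"] = "perfect_predictor"
    minority_response: int = 3
    majority_response: int = -3
    gain: float = 1.0
    round_responses: bool = False

    def validate(self, scale: ResponseScale) -> None:
        if self.mode == "perfect_predictor":
            for r in (self.minority_response, self.majority_response):
                if not scale.lower <= r <= scale.upper:
                    raise ValueError(f"response {r} outside scale [{scale.lower}, {scale.upper}]")
        elif self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")

    def respond(self, delta, reference, scale: ResponseScale):
        """Proportional-mode response to comparison ``delta`` at base rate ``reference``."""
        if self.mode != "proportional":
            raise ValueError("respond() applies to proportional policies")
        norm = np.maximum(np.asarray(reference, dtype=float), 1.0 - np.asarray(reference, dtype=float))
        raw = self.gain * np.asarray(delta, dtype=float) / norm * scale.upper
        if self.round_responses:
            raw = np.round(raw)
        return scale.clip(raw)


@dataclass
class SimulationCurve:
    """Mean comparative difference score as a function of event base rate."""

    base_rates: np.ndarray
    mean_scores: np.ndarray
    mechanism: Mechanism
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"base_rate": self.base_rates, "mean_score": self.mean_scores})


def perfect_predictor_mean(
    base_rate: float,
    policy: ResponsePolicy | None = None,
    scale: ResponseScale = ResponseScale(),
) -> float:
    """Population mean response of perfect predictors at a given base rate.

    ``base_rate * minority_response + (1 - base_rate) * majority_response``:
    a fraction ``base_rate`` of omniscient respondents know they will
    experience the event and give ``minority_response``; the rest give
    ``majority_response``.  With the classic +3 / -1 policy at a 6% base
    rate this is the -0.76 "optimism" of a perfectly calibrated population.
    """
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base_rate must lie in [0, 1]")
    policy = policy or ResponsePolicy()
    policy.validate(scale)
    return base_rate * policy.minority_response + (1.0 - base_rate) * policy.majority_response


def perfect_predictor_sample_mean(
    n_experiencers: int,
    n: int,
    policy: ResponsePolicy | None = None,
    scale: ResponseScale = ResponseScale(),
) -> float:
    """Finite-sample analogue using observed counts (e.g. 5 of 100 -> -0.8)."""
    if not 0 <= n_experiencers <= n:
        raise ValueError("need 0 <= n_experiencers <= n")
    return perfect_predictor_mean(n_experiencers / n, policy, scale)


def required_balance_multiplier(base_rate: float) -> float:
    """Factor by which the minority's response magnitude must exceed the majority's.

    For the group mean to sit at zero the at-risk minority must respond
    ``(1 - base_rate) / base_rate`` times further from zero than the
    majority — 15.67 at a 6% base rate, far beyond any  bounded scale.
    """
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie strictly inside (0, 1)")
    return (1.0 - base_rate) / base_rate


def undersampling_excess_analytic(base_rate: float, n: int) -> float:
    """Exact excess probability that the minority is under- vs. over-sampled.

    ``P(X < n*base_rate) - P(X > n*base_rate)`` for ``X ~ Binomial(n, p)``.
    When ``n*base_rate`` is an integer, samples representing the minority
    exactly count as neither under- nor over-sampled, which makes the
    excess exactly zero at p = 0.5.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base_rate must lie in [0, 1]")
    m = n * base_rate
    dist = stats.binom(n, base_rate)
    if abs(m - round(m)) < 1e-9:
        k = int(round(m))
        under = dist.cdf(k - 1)
        over = dist.sf(k)
    else:
        k = math.floor(m)
        under = dist.cdf(k)
        over = dist.sf(k)
    return float(under - over)


def simulate_undersampling(
    base_rate: float,
    n: int,
    reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Monte-Carlo counterpart of :func:`undersampling_excess_analytic`.

    Draws ``reps`` binomial samples of size ``n`` and reports the
    proportions in which the minority class is under- / over-represented,
    their difference, and the Monte-Carlo standard error of that difference.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.binomial(n, base_rate, size=reps)
    m = n * base_rate
    under = k < m - 1e-9
    over = k > m + 1e-9
    prop_under = under.mean()
    prop_over = over.mean()
    excess = prop_under - prop_over
    # var of (I_under - I_over), a {-1, 0, +1} variable
    var = prop_under + prop_over - excess**2
    return {
        "prop_under": float(prop_under),
        "prop_over": float(prop_over),
        "excess": float(excess),
        "mc_se": float(np.sqrt(max(var, 0.0) / reps)),
    }


def _regression_mean_score(
    base_rate: float,
    lam: float,
    test: DiagnosticTest,
    policy: ResponsePolicy,
    scale: ResponseScale,
) -> float:
    """Population mean comparative score under base-rate regression."""
    subjective = regress_toward_midpoint(base_rate, lam)
    event = EventSpec(label="", base_rate=base_rate, desirability=0.0)
    values, weights = population_posteriors(event, test, subjective)
    responses = policy.respond(values - subjective, subjective, scale)
    return float(np.dot(weights, responses))


def mechanism_curve(
    mechanism: Mechanism,
    base_rate_grid=None,
    scale: ResponseScale = ResponseScale(),
    policy: ResponsePolicy | None = None,
    lam: float = 0.4,
    test: DiagnosticTest = DiagnosticTest(),
    n: int = 100,
    reps: int = 100_000,
    seed: int = 0,
) -> SimulationCurve:
    """Mean comparative difference score across a base-rate grid.

    Parameters
    ----------
    mechanism
        ``attenuation`` — population of perfect predictors on the bounded
        scale; ``undersampling`` — the same averaged over ``reps`` random
        samples of size ``n``; ``regression`` — Bayesian agents whose
        subjective base rate is shrunk toward 0.5 by ``lam`` before
        updating on a diagnostic result.
    base_rate_grid
        Probabilities strictly inside (0, 1); defaults to 0.01..0.99
        in steps of 0.01.
    policy
        Defaults to the symmetric perfect-predictor policy (scale
        endpoints) for attenuation/undersampling and the proportional
        policy for regression.

    With symmetric defaults every mechanism yields scores < 0 below a base
    rate of 0.5, 0 at 0.5 and > 0 above — seeming optimism for rare events
    from unbiased respondents.
    """
    if base_rate_grid is None:
        base_rate_grid = np.arange(0.01, 1.0, 0.01)
    grid = np.asarray(base_rate_grid, dtype=float)
    if np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise ValueError("base rate grid must lie strictly inside (0, 1)")
    if np.any(np.diff(grid) < 0):
        raise ValueError("base rate grid must be sorted ascending")

    if mechanism in ("attenuation", "undersampling"):
        policy = policy or ResponsePolicy(
            mode="perfect_predictor",
            minority_response=scale.upper,
            majority_response=scale.lower,
        )
        policy.validate(scale)
    elif mechanism == "regression":
        policy = policy or ResponsePolicy(mode="proportional")
        policy.validate(scale)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    params: dict = {"scale": (scale.lower, scale.upper), "policy_mode": policy.mode}
    if mechanism == "attenuation":
        scores = np.array([perfect_predictor_mean(p, policy, scale) for p in grid])
    elif mechanism == "undersampling":
        rng = np.random.default_rng(seed)
        scores = np.empty_like(grid)
        for i, p in enumerate(grid):
            k = rng.binomial(n, p, size=reps)
            sample_means = (
                k * policy.minority_response + (n - k) * policy.majority_response
            ) / n
            scores[i] = sample_means.mean()
        params.update(n=n, reps=reps, seed=seed)
    else:
        scores = np.array(
            [_regression_mean_score(p, lam, test, policy, scale) for p in grid]
        )
        params.update(
            lam=lam,
            sensitivity=test.sensitivity,
            false_positive_rate=test.false_positive_rate,
        )

    return SimulationCurve(base_rates=grid, mean_scores=scores, mechanism=mechanism, params=params)
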