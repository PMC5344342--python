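"""Bayesian agent machinery for comparative risk judgments.

The comparative method asks each member of a population to rate their own
chance of experiencing a life event against "the average person's" chance.
The logic of the method rests on a conservation property: if every agent
holds the correct base rate and updates on private diagnostic evidence via
Bayes' theorem, the population mean of their posterior personal risks equals
the base rate exactly.  This module provides that machinery: events with a
population base rate, diagnostic evidence sources parameterized by a
likelihood ratio, exact posterior updating, linear regression of subjective
base rates toward the probability-scale midpoint, and the induced population
distribution of posteriors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "EventSpec",
    "DiagnosticTest",
    "RegressionLevel",
    "posterior_risk",
    "regress_toward_midpoint",
    "population_posteriors",
    "load_life_events",
    "DEFAULT_REGRESSION_LEVELS",
]

TestResult = Literal["positive", "negative"]

#: Default shrinkage levels for base-rate regression curves.
DEFAULT_REGRESSION_LEVELS = (0.2, 0.4, 0.6)


@dataclass(frozen=True)
class EventSpec:
    """A future life event with population-level attributes.

    Parameters
    ----------
    label
        Human-readable event description.
    base_rate
        Population probability of experiencing the event ("the average
        person's risk"), strictly inside (0, 1).
    desirability
        Event-level mean desirability on a -5..+5 scale.
    controllability
        Event-level mean perceived controllability on a 0..10 scale.
    """

    label: str
    base_rate: float
    desirability: float = 0.0
    controllability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError(f"base_rate must be in (0, 1), got {self.base_rate}")
        if not -5.0 <= self.desirability <= 5.0:
            raise ValueError(
                f"desirability must be on the -5..+5 scale, got {self.desirability}"
            )
        if not 0.0 <= self.controllability <= 10.0:
            raise ValueError(
                f"controllability must be on the 0..10 scale, got {self.controllability}"
            )

    @property
    def valence(self) -> str:
        """'positive' or 'negative', by the sign of mean desirability."""
        return "positive" if self.desirability >= 0 else "negative"


@dataclass(frozen=True)
class DiagnosticTest:
    """An agent's private evidence source.

    A binary cue (family history, lifestyle, a screening result ...) with a
    true-positive rate ``sensitivity`` and a ``false_positive_rate``.  The
    positive likelihood ratio sensitivity/false_positive_rate measures how
    diagnostic the cue is; the default (0.8, 0.2) gives the 4:1 ratio used
    in standard worked examples, with negative-result likelihood ratio
    (1-0.8)/(1-0.2) = 0.25.
    """

    sensitivity: float = 0.8
    false_positive_rate: float = 0.2

    def __post_init__(self) -> None:
        s, f = self.sensitivity, self.false_positive_rate
        if not (0.0 < f <= s < 1.0):
            raise ValueError(
                "need 0 < false_positive_rate <= sensitivity < 1 for a "
                f"diagnostic test, got s={s}, f={f}"
            )

    @property
    def positive_lr(self) -> float:
        return self.sensitivity / self.false_positive_rate

    @property
    def negative_lr(self) -> float:
        return (1.0 - self.sensitivity) / (1.0 - self.false_positive_rate)

    def is_informative(self) -> bool:
        return self.sensitivity != self.false_positive_rate


@dataclass(frozen=True)
class RegressionLevel:
    """Linear shrinkage of probability estimates toward the midpoint 0.5.

    ``lam`` = 0 leaves estimates untouched; ``lam`` = 1 collapses every
    estimate to 0.5.  Models the regressiveness that unbiased estimation
    error induces on a bounded probability scale.
    """

    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")


def posterior_risk(base_rate, test: DiagnosticTest, result: TestResult):
    """Posterior probability of the event given a diagnostic result.

    Bayes' theorem with likelihoods taken from ``test``::

        P(E | r) = BR * L(r) / (BR * L(r) + (1 - BR) * Lbar(r))

    where ``L`` is sensitivity (positive result) or 1 - sensitivity
    (negative), and ``Lbar`` the corresponding false-positive terms.
    Accepts scalars or arrays; base rates of exactly 0 or 1 are absorbing.
    """
    br = np.asarray(base_rate, dtype=float)
    if np.any(br < 0.0) or np.any(br > 1.0):
        raise ValueError("base_rate must lie in [0, 1]")
    if result == "positive":
        like, unlike = test.sensitivity, test.false_positive_rate
    elif result == "negative":
        like, unlike = 1.0 - test.sensitivity, 1.0 - test.false_positive_rate
    else:
        raise ValueError(f"result must be 'positive' or 'negative', got {result!r}")
    num = br * like
    denom = num + (1.0 - br) * unlike
    with np.errstate(invalid="ignore"):
        post = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), br)
    return float(post) if np.isscalar(base_rate) else post


def regress_toward_midpoint(p, level: RegressionLevel | float):
    """Shrink probability ``p`` toward 0.5 by factor ``lambda``.

    Returns ``(1 - lambda) * p + lambda * 0.5``; a contraction toward the
    scale midpoint that overestimates rare events and underestimates common
    ones, as unbiased error on a bounded scale does to mean estimates.
    """
    lam = level.lam if isinstance(level, RegressionLevel) else float(level)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("p must lie in [0, 1]")
    out = (1.0 - lam) * arr + lam * 0.5
    return float(out) if np.isscalar(p) else out


def population_posteriors(
    event: EventSpec,
    test: DiagnosticTest,
    subjective_base_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of posterior personal risks across the population.

    Each agent observes one diagnostic result and updates the (possibly
    mis-estimated) ``subjective_base_rate``; the frequency of positive and
    negative results in the population is governed by the TRUE base rate.

    Returns
    -------
    values, weights
        ``values[0]``/``values[1]`` are the posteriors after a positive /
        negative result; ``weights`` are the marginal result probabilities
        under the true base rate and sum to 1.

    Notes
    -----
    With ``subjective_base_rate`` equal to the true base rate the weighted
    mean of the posteriors equals the true base rate exactly (law of total
    probability) — the conservation property underpinning the comparative
    method.
    """
    if subjective_base_rate is None:
        subjective_base_rate = event.base_rate
    if not 0.0 <= subjective_base_rate <= 1.0:
        raise ValueError("subjective_base_rate must lie in [0, 1]")
    br = event.base_rate
    w_pos = br * test.sensitivity + (1.0 - br) * test.false_positive_rate
    values = np.array(
        [
            posterior_risk(subjective_base_rate, test, "positive"),
            posterior_risk(subjective_base_rate, test, "negative"),
        ]
    )
    weights = np.array([w_pos, 1.0 - w_pos])
    return values, weights


def load_life_events(path=None) -> list[EventSpec]:
    """Load an event list from CSV (label, base_rate, desirability, controllability).

    With no argument, loads the packaged 40-event fixture whose base rates
    are group mean perceived frequencies (out of 100) from a standard
    comparative-optimism study; its desirability and controllability columns
    are synthetic plausible values.
    """
    if path is None:
        ref = importlib.resources.files("riskartifacts") / "data" / "life_events.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    required = {"label", "base_rate", "desirability", "controllability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    return [
        EventSpec(
            label=row.label,
            base_rate=float(row.base_rate),
            desirability=float(row.desirability),
            controllability=float(row.controllability),
        )
        for row in df.itertuples(index=False)
    ]


def events_to_frame(events: list[EventSpec]) -> pd.DataFrame:
    """Tabulate a list of events (inverse of :func:`load_life_events`)."""
    return pd.DataFrame(
        {
            "label": [e.label for e in events],
            "base_rate": [e.base_rate for e in events],
            "desirability": [e.desirability for e in events],
            "controllability": [e.controllability for e in events],
        }
    )
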