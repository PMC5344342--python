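"""Synthetic rating-study and factorial-experiment generators.

Two designs are emulated, with injectable true effects so every stage of
the analysis pipeline can be exercised and calibrated without human data.

**Event-rating study** (``generate_study1``): N participants rate ~40 life
events on a bounded comparative scale (-5..+5), and also estimate each
event's frequency ("out of 100"), desirability (-5..+5) and controllability
(0..10).  The response process is the unbiased-agent model: each
participant's subjective base rate is the true base rate shrunk toward 0.5
(base-rate regression) plus estimation noise; they observe one diagnostic
result whose frequency follows the *true* base rate, update by Bayes'
theorem, and map the posterior-vs-subjective-base-rate comparison onto the
bounded scale.  A ``beta_desirability`` parameter injects a genuine
"wishful thinking" effect (zero by default — the null world in which any
apparent optimism is pure artifact).

**Factorial probability-estimate experiment** (``generate_experiment``): a
2 (severity) x 2 (target: self vs. other) between-subjects design with
estimates on 0-100, Gaussian cell noise, and optional within-subject
scenarios — the structure used to test for optimism free of the
comparative-scale artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .artifact_sim import ResponsePolicy, ResponseScale
from .core_model import (
    DiagnosticTest,
    EventSpec,
    load_life_events,
    posterior_risk,
    regress_toward_midpoint,
)

__all__ = [
    "StudyConfig",
    "ExperimentConfig",
    "generate_study1",
    "generate_experiment",
]


@dataclass
class StudyConfig:
    """Configuration of a synthetic event-rating study.

    Defaults follow a typical comparative-optimism study: 102 participants,
    the packaged 40-event list, an 11-point -5..+5 comparative scale, a
    4:1-likelihood-ratio diagnostic cue, moderate base-rate regression
    (lambda = 0.4) and realistic estimation noise (SD 15 on the 0-100
    frequency scale, SD 1.0 on the rating scale).
    """

    n_participants: int = 102
    events: list[EventSpec] = field(default_factory=load_life_events)
    scale: ResponseScale = field(default_factory=lambda: ResponseScale(-5, 5))
    test: DiagnosticTest = field(default_factory=DiagnosticTest)
    frequency_noise_sd: float = 15.0  # on the 0-100 estimate scale
    lam: float = 0.4  # base-rate regression toward 0.5
    beta_desirability: float = 0.0  # injected true desirability effect (rating units per des/5)
    rating_noise_sd: float = 1.0  # on the comparative rating scale
    desirability_noise_sd: float = 1.0
    controllability_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not self.events:
            raise ValueError("event list must not be empty")
        for sd in (
            self.frequency_noise_sd,
            self.rating_noise_sd,
            self.desirability_noise_sd,
            self.controllability_noise_sd,
        ):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")


def generate_study1(config: StudyConfig) -> pd.DataFrame:
    """Generate a long-format participant x event rating table.

    Returns a DataFrame with one row per participant x event and columns
    ``participant``, ``event``, ``comparative_rating`` (integer on the
    study scale), ``frequency_estimate`` (0-100), ``desirability`` (-5..+5)
    and ``controllability`` (0-10).

    Per-participant random substreams are spawned deterministically from
    the master seed, so datasets are reproducible and participant i's data
    do not depend on how many other participants are generated after them.
    """
    cfg = config
    events = cfg.events
    n_e = len(events)
    base_rates = np.array([e.base_rate for e in events])
    event_des = np.array([e.desirability for e in events])
    event_ctrl = np.array([e.controllability for e in events])
    policy = ResponsePolicy(mode="proportional", round_responses=False)

    regressed = regress_toward_midpoint(base_rates, cfg.lam)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)

    rows = []
    for pid, child in enumerate(children):
        rng = np.random.default_rng(child)
        subjective = np.clip(
            regressed + rng.normal(0.0, cfg.frequency_noise_sd / 100.0, n_e), 0.0, 1.0
        )
        frequency_estimate = np.round(100.0 * subjective)
        # diagnostic result: outcome drawn from the TRUE base rate, result
        # from the test's operating characteristics given the outcome
        will_experience = rng.random(n_e) < base_rates
        p_positive = np.where(
            will_experience, cfg.test.sensitivity, cfg.test.false_positive_rate
        )
        positive = rng.random(n_e) < p_positive
        post_pos = posterior_risk(subjective, cfg.test, "positive")
        post_neg = posterior_risk(subjective, cfg.test, "negative")
        posterior = np.where(positive, post_pos, post_neg)

        latent = policy.respond(posterior - subjective, subjective, cfg.scale)
        latent = (
            latent
            + cfg.beta_desirability * (event_des / 5.0)
            + rng.normal(0.0, cfg.rating_noise_sd, n_e)
        )
        comparative = cfg.scale.clip(np.round(latent)).astype(int)

        des = np.clip(np.round(event_des + rng.normal(0.0, cfg.desirability_noise_sd, n_e)), -5, 5)
        ctrl = np.clip(np.round(event_ctrl + rng.normal(0.0, cfg.controllability_noise_sd, n_e)), 0, 10)

        rows.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "event": [e.label for e in events],
                    "comparative_rating": comparative,
                    "frequency_estimate": frequency_estimate.astype(int),
                    "desirability": des.astype(int),
                    "controllability": ctrl.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class ExperimentConfig:
    """Configuration of a synthetic 2 x 2 probability-estimate experiment.

    Cell means on the 0-100 scale are parameterized as::

        mean(severity, target) = baseline + d_severity * [severe]
                               + d_target * [other] + d_interaction * [severe & other]

    so ``d_severity > 0`` is a severity effect (negative outcomes judged
    more probable) and ``d_target > 0`` the pattern unrealistic optimism
    predicts (higher estimates for the other than for the self).
    Alternatively pass explicit ``cell_means`` keyed by (severity, target).
    """

    n_per_cell: int = 50
    baseline: float = 40.0
    d_severity: float = 0.0
    d_target: float = 0.0
    d_interaction: float = 0.0
    sd: float = 24.0
    cell_means: dict | None = None
    scenarios: tuple[str, ...] | None = None
    scenario_offsets: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("need at least 2 participants per cell")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def mean(self, severity: str, target: str) -> float:
        if self.cell_means is not None:
            return float(self.cell_means[(severity, target)])
        m = self.baseline
        if severity == "severe":
            m += self.d_severity
        if target == "other":
            m += self.d_target
        if severity == "severe" and target == "other":
            m += self.d_interaction
        return m


def generate_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Generate a balanced factorial probability-estimate dataset.

    Returns a DataFrame with columns ``participant``, ``severity``
    (severe/neutral), ``target`` (self/other), ``estimate`` (0-100, clipped)
    and, when ``config.scenarios`` is set, one row per participant x
    scenario with a ``scenario`` column (within-subject factor).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scenarios = cfg.scenarios or (None,)
    rows = []
    pid = 0
    for severity in ("neutral", "severe"):
        for target in ("self", "other"):
            mu = cfg.mean(severity, target)
            for _ in range(cfg.n_per_cell):
                for scen in scenarios:
                    offset = 0.0
                    if scen is not None and cfg.scenario_offsets:
                        offset = cfg.scenario_offsets.get(scen, 0.0)
                    est = np.clip(rng.normal(mu + offset, cfg.sd), 0.0, 100.0)
                    row = {
                        "participant": pid,
                        "severity": severity,
                        "target": target,
                        "estimate": float(est),
                    }
                    if scen is not None:
                        row["scenario"] = scen
                    rows.append(row)
                pid += 1
    return pd.DataFrame(rows)
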