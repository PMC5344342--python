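"""Statistical battery for comparative-optimism rating studies and experiments.

Covers the analyses such studies report: group-level one-sample t tests of
mean comparative ratings, an exact binomial sign test over events, a
median-split 2x2 (frequency x valence) cell analysis, by-item forward and
simultaneous multiple regressions on z-scored event-level predictors,
by-subject partial correlations of desirability with comparative ratings
controlling perceived frequency, first-order partial correlations, and
between-subjects factorial ANOVA (Type III) with simple effects for the
2 x 2 probability-estimate experiments.

Standard fits go through scipy / statsmodels; this module adds the study
specific plumbing (median splits with median-event exclusion, strictly
staged forward selection, residual-based per-subject partials).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "one_sample_t",
    "binomial_sign_test",
    "median_split_cells",
    "CellSummary",
    "event_summary",
    "forward_regression",
    "simultaneous_regression",
    "RegressionStep",
    "by_subject_partial",
    "partial_correlation",
    "two_way_anova",
]


# --------------------------------------------------------------------------
# group-level tests


def one_sample_t(values, mu0: float = 0.0) -> dict:
    """One-sample t test of the mean of ``values`` against ``mu0``.

    Raises ``ValueError`` on fewer than 2 observations or zero variance
    (degenerate data for which the t statistic is undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: zero variance")
    res = stats.ttest_1samp(x, mu0)
    return {
        "t": float(res.statistic),
        "df": int(x.size - 1),
        "p": float(res.pvalue),
        "mean": float(x.mean()),
    }


def binomial_sign_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (doubled smaller tail, capped at 1).

    The convention used when a study reports e.g. "optimistic direction for
    14 of 40 events, p = .08 by the binomial test".
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


# --------------------------------------------------------------------------
# median-split cell analysis


@dataclass
class CellSummary:
    """2x2 (frequency: rare/common x valence) cell means with SEs."""

    means: dict = field(default_factory=dict)  # {(freq_class, valence): mean}
    ses: dict = field(default_factory=dict)
    excluded_events: list = field(default_factory=list)
    cell_table: pd.DataFrame | None = None  # per-participant cell means


def event_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """By-event means of ratings and predictors from a long rating table.

    Returns one row per event with columns ``mean_rating``, ``frequency``,
    ``desirability``, ``controllability`` and the derived ``valence``
    (sign of the mean desirability rating).
    """
    g = dataset.groupby("event")
    out = pd.DataFrame(
        {
            "mean_rating": g["comparative_rating"].mean(),
            "frequency": g["frequency_estimate"].mean(),
            "desirability": g["desirability"].mean(),
            "controllability": g["controllability"].mean(),
        }
    )
    out["valence"] = np.where(out["desirability"] >= 0, "positive", "negative")
    return out


def median_split_cells(dataset: pd.DataFrame) -> CellSummary:
    """Median-split events into rare/common within each valence.

    Events are classified by the sign of their mean desirability rating;
    within each valence they are split at the median of the group mean
    perceived frequency.  With an odd number of events in a valence, the
    single median event is excluded (it belongs to neither half).  Cell
    values are per-participant mean comparative ratings, averaged to group
    means with standard errors.
    """
    items = event_summary(dataset)
    classes: dict[str, str] = {}
    excluded: list[str] = []
    for valence, sub in items.groupby("valence"):
        if len(sub) < 3:
            raise ValueError(f"need >= 3 events of valence {valence!r} for a median split")
        order = sub.sort_values("frequency")
        n = len(order)
        half = n // 2
        labels = list(order.index)
        if n % 2 == 1:
            excluded.append(labels[half])
            rare, common = labels[:half], labels[half + 1 :]
        else:
            rare, common = labels[:half], labels[half:]
        for ev in rare:
            classes[ev] = "rare"
        for ev in common:
            classes[ev] = "common"

    df = dataset[~dataset["event"].isin(excluded)].copy()
    ev_val = items["valence"]
    df["valence"] = df["event"].map(ev_val)
    df["freq_class"] = df["event"].map(classes)
    cell_table = (
        df.groupby(["participant", "freq_class", "valence"])["comparative_rating"]
        .mean()
        .reset_index()
    )
    summary = CellSummary(excluded_events=excluded, cell_table=cell_table)
    for (fc, val), sub in cell_table.groupby(["freq_class", "valence"]):
        x = sub["comparative_rating"].to_numpy()
        summary.means[(fc, val)] = float(x.mean())
        summary.ses[(fc, val)] = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    return summary


# --------------------------------------------------------------------------
# by-item regressions

MAIN_TERMS = ("frequency", "desirability", "controllability")


@dataclass
class RegressionStep:
    """One entry of a staged forward regression."""

    step: int  # 1 = main effects, 2 = two-way, 3 = three-way
    term: str
    beta: float
    delta_r2: float
    r2: float
    f_to_enter: float
    p_to_enter: float


def _design_matrix(items: pd.DataFrame) -> pd.DataFrame:
    """z-scored mains and their (re-standardized) interaction products."""
    z = pd.DataFrame(index=items.index)
    for t in MAIN_TERMS:
        col = items[t].astype(float)
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {t!r} has zero variance over events")
        z[t] = (col - col.mean()) / sd

    def standardize(c):
        return (c - c.mean()) / c.std(ddof=1)

    for a, b in combinations(MAIN_TERMS, 2):
        z[f"{a}:{b}"] = standardize(z[a] * z[b])
    z["frequency:desirability:controllability"] = standardize(
        z["frequency"] * z["desirability"] * z["controllability"]
    )
    cond = np.linalg.cond(z.to_numpy())
    if cond > 1e8:
        raise ValueError(f"collinear predictors (condition number {cond:.3g})")
    return z


def _staged_terms() -> list[list[str]]:
    two_way = [f"{a}:{b}" for a, b in combinations(MAIN_TERMS, 2)]
    return [list(MAIN_TERMS), two_way, ["frequency:desirability:controllability"]]


def forward_regression(items: pd.DataFrame, entry_alpha: float = 0.05) -> list[RegressionStep]:
    """Staged forward selection on by-event means.

    ``items`` holds one row per event with ``mean_rating`` and the three
    predictors (see :func:`event_summary`).  Predictors are z-scored over
    events; the response is z-scored so coefficients are standardized
    betas.  Main effects compete at step 1, two-way interactions of the
    z-scored mains at step 2, the three-way at step 3 (strictly staged:
    a later-stage term is never considered before the earlier stage is
    exhausted).  A term enters when its F-to-enter p-value is below
    ``entry_alpha``; each entry records the increment to R².
    """
    if len(items) < 8:
        raise ValueError("need at least 8 events for the by-item regression")
    z = _design_matrix(items)
    y = items["mean_rating"].astype(float)
    y = ((y - y.mean()) / y.std(ddof=1)).to_numpy()
    n = len(y)

    included: list[str] = []
    steps: list[RegressionStep] = []
    r2_current = 0.0

    def fit_r2(terms: list[str]) -> tuple[float, sm.regression.linear_model.RegressionResultsWrapper]:
        X = sm.add_constant(z[terms].to_numpy()) if terms else np.ones((n, 1))
        res = sm.OLS(y, X).fit()
        return float(res.rsquared), res

    for stage_idx, stage_terms in enumerate(_staged_terms(), start=1):
        candidates = [t for t in stage_terms if t not in included]
        while candidates:
            best = None
            for term in candidates:
                r2_new, _ = fit_r2(included + [term])
                df_resid = n - len(included) - 2  # constant + new term
                if df_resid <= 0:
                    continue
                delta = r2_new - r2_current
                resid_frac = 1.0 - r2_new
                if resid_frac <= 0:
                    # perfect fit: entering term explains all remaining variance
                    # (or none of it, if the model was already saturated)
                    f, p = (np.inf, 0.0) if delta > 1e-12 else (0.0, 1.0)
                else:
                    f = delta / (resid_frac / df_resid)
                    p = float(stats.f.sf(f, 1, df_resid))
                if best is None or p < best[0]:
                    best = (p, f, term, r2_new)
            if best is None or best[0] >= entry_alpha:
                break
            p, f, term, r2_new = best
            included.append(term)
            _, res = fit_r2(included)
            beta = float(res.params[len(included)])  # last-entered term
            steps.append(
                RegressionStep(
                    step=stage_idx,
                    term=term,
                    beta=beta,
                    delta_r2=r2_new - r2_current,
                    r2=r2_new,
                    f_to_enter=f,
                    p_to_enter=p,
                )
            )
            r2_current = r2_new
            candidates.remove(term)
    return steps


def simultaneous_regression(items: pd.DataFrame) -> dict:
    """All-terms multiple regression (3 mains, 3 two-ways, 1 three-way).

    Returns the full standardized coefficient table plus model R² and F —
    the simultaneous counterpart of :func:`forward_regression`.
    """
    z = _design_matrix(items)
    y = items["mean_rating"].astype(float)
    y = ((y - y.mean()) / y.std(ddof=1)).to_numpy()
    terms = list(z.columns)
    X = sm.add_constant(z[terms].to_numpy())
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "term": ["(Constant)"] + terms,
            "beta": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return {
        "coefficients": table,
        "r2": float(res.rsquared),
        "f": float(res.fvalue),
        "p": float(res.f_pvalue),
        "df_model": int(res.df_model),
        "df_resid": int(res.df_resid),
    }


# --------------------------------------------------------------------------
# by-subject analysis and partial correlations


def by_subject_partial(dataset: pd.DataFrame, min_events: int = 4) -> dict:
    """Per-participant partialling of frequency out of the desirability/rating link.

    For each participant: regress comparative ratings on their frequency
    estimates (across events), then correlate the residuals with their
    desirability ratings.  Participants with too few events or no variance
    in any variable are excluded (their count is reported).  The returned
    group-level one-sample t tests the mean of the per-subject correlations
    against zero; ``frequency_coefs`` holds the per-subject standardized
    frequency slopes.
    """
    r_values = []
    freq_coefs = []
    n_excluded = 0
    for _, sub in dataset.groupby("participant"):
        y = sub["comparative_rating"].to_numpy(dtype=float)
        f = sub["frequency_estimate"].to_numpy(dtype=float)
        d = sub["desirability"].to_numpy(dtype=float)
        if len(y) < min_events or np.ptp(f) == 0 or np.ptp(d) == 0 or np.ptp(y) == 0:
            n_excluded += 1
            continue
        slope, intercept = np.polyfit(f, y, 1)
        resid = y - (slope * f + intercept)
        if resid.std() <= 1e-10 * max(y.std(), 1.0):
            # rating fully explained by frequency: nothing left for desirability
            r_values.append(0.0)
            freq_coefs.append(float(slope * f.std(ddof=1) / y.std(ddof=1)))
            continue
        r_values.append(float(stats.pearsonr(resid, d).statistic))
        freq_coefs.append(float(slope * f.std(ddof=1) / y.std(ddof=1)))
    r = np.asarray(r_values)
    out = {
        "r_values": r,
        "frequency_coefs": np.asarray(freq_coefs),
        "n_excluded": n_excluded,
        "mean_r": float(r.mean()) if r.size else np.nan,
    }
    if r.size >= 2 and np.ptp(r) > 0:
        t = one_sample_t(r, 0.0)
        out.update(t=t["t"], df=t["df"], p=t["p"])
    return out


def partial_correlation(x, y, control) -> float:
    """First-order partial correlation of x and y controlling one variable.

    ``r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))`` —
    equivalently the correlation of the residuals of x and y after
    regressing each on the control.  Undefined (raises) when the control
    is perfectly correlated with x or y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y and control must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    r_xy = stats.pearsonr(x, y).statistic
    r_xz = stats.pearsonr(x, z).statistic
    r_yz = stats.pearsonr(y, z).statistic
    if np.isclose(abs(r_xz), 1.0) or np.isclose(abs(r_yz), 1.0):
        raise ValueError("partial correlation undefined: control collinear with x or y")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2)))


# --------------------------------------------------------------------------
# factorial ANOVA


def _simple_effect(df: pd.DataFrame, dv: str, within: str, level: str, factor: str, mse: float, df_resid: int) -> dict:
    sub = df[df[within] == level]
    groups = [g[dv].to_numpy(dtype=float) for _, g in sub.groupby(factor)]
    if len(groups) != 2:
        raise ValueError(f"simple effect expects 2 levels of {factor!r}")
    n1, n2 = len(groups[0]), len(groups[1])
    m1, m2 = groups[0].mean(), groups[1].mean()
    ss = (m1 - m2) ** 2 * n1 * n2 / (n1 + n2)
    f = ss / mse
    return {"F": float(f), "df": (1, df_resid), "p": float(stats.f.sf(f, 1, df_resid))}


def two_way_anova(
    dataset: pd.DataFrame,
    dv: str = "estimate",
    factor_a: str = "severity",
    factor_b: str = "target",
    simple_effects: bool = False,
) -> dict:
    """Between-subjects 2-way ANOVA with Type III sums of squares.

    Uses sum-to-zero contrasts so Type III tests are meaningful for
    unbalanced cells; reports F, df, p and partial eta² for both main
    effects and the interaction.  With ``simple_effects=True`` adds F tests
    of ``factor_b`` within each level of ``factor_a`` using the pooled
    error term.
    """
    counts = dataset.groupby([factor_a, factor_b]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("every cell of the 2x2 design needs at least 2 observations")
    formula = f"{dv} ~ C({factor_a}, Sum) * C({factor_b}, Sum)"
    model = smf.ols(formula, data=dataset).fit()
    table = sm.stats.anova_lm(model, typ=3)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = int(table.loc["Residual", "df"])
    mse = ss_resid / df_resid

    def row(label):
        ss = float(table.loc[label, "sum_sq"])
        return {
            "F": float(table.loc[label, "F"]),
            "df": (int(table.loc[label, "df"]), df_resid),
            "p": float(table.loc[label, "PR(>F)"]),
            "partial_eta_sq": ss / (ss + ss_resid),
        }

    out = {
        factor_a: row(f"C({factor_a}, Sum)"),
        factor_b: row(f"C({factor_b}, Sum)"),
        "interaction": row(f"C({factor_a}, Sum):C({factor_b}, Sum)"),
        "mse": mse,
        "df_resid": df_resid,
    }
    if simple_effects:
        out["simple_effects"] = {
            level: _simple_effect(dataset, dv, factor_a, level, factor_b, mse, df_resid)
            for level in dataset[factor_a].unique()
        }
    return out
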