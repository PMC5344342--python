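"""Statistical battery: t tests, sign test, median splits, regressions, partials, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskartifacts import (
    StudyConfig,
    binomial_sign_test,
    by_subject_partial,
    event_summary,
    forward_regression,
    generate_study1,
    median_split_cells,
    one_sample_t,
    partial_correlation,
    simultaneous_regression,
    two_way_anova,
)


class TestOneSampleT:
    def test_mean_equal_to_mu0_gives_zero_t(self):
        assert one_sample_t([1, 2, 3, 4, 5], 3.0)["t"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_oracle(self):
        # textbook formula on {2,4,4,4,5,5,7,9} vs mu0=3: t = 2.6458, p = .0331
        res = one_sample_t([2, 4, 4, 4, 5, 5, 7, 9], 3.0)
        assert res["t"] == pytest.approx(2.6457513, abs=1e-6)
        assert res["p"] == pytest.approx(0.0331455, abs=1e-6)
        assert res["df"] == 7

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([3.0, 3.0, 3.0], 0.0)
        with pytest.raises(ValueError):
            one_sample_t([1.0], 0.0)


class TestBinomialSignTest:
    def test_fourteen_of_forty(self):
        """14 events optimistic out of 40 is marginal: p rounds to .08."""
        assert round(binomial_sign_test(14, 40), 2) == 0.08

    def test_even_split_is_one(self):
        assert binomial_sign_test(20, 40) == 1.0

    def test_extreme_tail_doubles(self):
        assert binomial_sign_test(0, 5) == pytest.approx(0.0625, abs=1e-12)

    @settings(deadline=None)
    @given(k=st.integers(min_value=0, max_value=60), n=st.integers(min_value=1, max_value=60))
    def test_symmetry_at_half(self, k, n):
        if k > n:
            k = n
        assert binomial_sign_test(k, n) == pytest.approx(binomial_sign_test(n - k, n), abs=1e-12)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_sign_test(5, 4)


class TestMedianSplit:
    def test_fixture_excludes_one_median_event_per_valence(self, study_df, events):
        """21 negative and 19 positive events: one median exclusion in each valence."""
        cells = median_split_cells(study_df)
        assert len(cells.excluded_events) == 2
        valence = {e.label: e.valence for e in events}
        assert sorted(valence[e] for e in cells.excluded_events) == ["negative", "positive"]

    def test_rare_cells_below_common_cells(self, study_df):
        """Rating means track frequency within both valences (the artifact signature)."""
        cells = median_split_cells(study_df)
        assert cells.means[("rare", "negative")] < cells.means[("common", "negative")]
        assert cells.means[("rare", "positive")] < cells.means[("common", "positive")]

    def test_minimal_three_event_valence(self):
        # three negative events with frequencies 10 < 20 < 30: median (20) excluded
        rows = []
        for pid in range(4):
            for ev, f, d in [("a", 10, -3), ("b", 20, -3), ("c", 30, -3),
                             ("x", 15, 3), ("y", 25, 3), ("z", 35, 3)]:
                rows.append(
                    dict(participant=pid, event=ev, comparative_rating=f // 10,
                         frequency_estimate=f, desirability=d, controllability=5)
                )
        cells = median_split_cells(pd.DataFrame(rows))
        assert set(cells.excluded_events) == {"b", "y"}

    def test_too_few_events_rejected(self):
        rows = [
            dict(participant=p, event=e, comparative_rating=0,
                 frequency_estimate=f, desirability=d, controllability=5)
            for p in range(3)
            for e, f, d in [("a", 10, -3), ("b", 20, -3), ("x", 15, 3), ("y", 25, 3)]
        ]
        with pytest.raises(ValueError):
            median_split_cells(pd.DataFrame(rows))


class TestByItemRegressions:
    @staticmethod
    def _items(n=24, seed=0):
        rng = np.random.default_rng(seed)
        items = pd.DataFrame(
            {
                "frequency": rng.uniform(0, 100, n),
                "desirability": rng.uniform(-5, 5, n),
                "controllability": rng.uniform(0, 10, n),
            }
        )
        return items

    def test_pure_frequency_response_enters_frequency_alone(self):
        items = self._items()
        items["mean_rating"] = 0.04 * items["frequency"] - 1.5
        steps = forward_regression(items)
        assert [s.term for s in steps] == ["frequency"]
        assert steps[0].r2 == pytest.approx(1.0, abs=1e-9)
        assert steps[0].step == 1

    def test_interaction_only_signal_enters_at_stage_two(self):
        items = self._items(seed=3)
        zf = (items["frequency"] - items["frequency"].mean()) / items["frequency"].std(ddof=1)
        zd = (items["desirability"] - items["desirability"].mean()) / items["desirability"].std(ddof=1)
        items["mean_rating"] = (zf * zd).to_numpy()
        steps = forward_regression(items)
        assert any(s.term == "frequency:desirability" and s.step == 2 for s in steps)

    def test_r2_nondecreasing_across_entries(self, study_df):
        steps = forward_regression(event_summary(study_df))
        r2s = [s.r2 for s in steps]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
        assert all(0 <= s.r2 <= 1 for s in steps)

    def test_simultaneous_reports_full_seven_term_model(self, study_df):
        res = simultaneous_regression(event_summary(study_df))
        terms = list(res["coefficients"]["term"])
        assert terms == [
            "(Constant)",
            "frequency",
            "desirability",
            "controllability",
            "frequency:desirability",
            "frequency:controllability",
            "desirability:controllability",
            "frequency:desirability:controllability",
        ]
        assert res["df_model"] == 7
        assert 0 <= res["r2"] <= 1

    def test_forward_and_simultaneous_agree_when_all_terms_forced(self):
        """With entry_alpha = 1 every term enters and the final fit is the full model."""
        items = self._items(seed=5)
        rng = np.random.default_rng(6)
        items["mean_rating"] = 0.03 * items["frequency"] + rng.normal(0, 1, len(items))
        steps = forward_regression(items, entry_alpha=1.0)
        assert len(steps) == 7
        assert steps[-1].r2 == pytest.approx(simultaneous_regression(items)["r2"], abs=1e-9)

    def test_frequency_dominates_in_generated_data(self, study_df):
        """The null-world generator reproduces the headline pattern: frequency
        predicts by-item comparative ratings, desirability does not."""
        steps = forward_regression(event_summary(study_df))
        assert steps[0].term == "frequency"
        assert all(s.term != "desirability" for s in steps)

    def test_too_few_events_rejected(self):
        items = self._items(n=5)
        items["mean_rating"] = 1.0 * items["frequency"]
        with pytest.raises(ValueError):
            forward_regression(items)


class TestBySubjectPartial:
    def test_pure_frequency_ratings_give_zero_partials(self, events):
        cfg = StudyConfig(events=events, n_participants=6, rating_noise_sd=0.0,
                          desirability_noise_sd=0.0, seed=2)
        df = generate_study1(cfg)
        # overwrite ratings with an exact linear function of frequency
        df["comparative_rating"] = 0.1 * df["frequency_estimate"]
        res = by_subject_partial(df)
        assert np.allclose(res["r_values"], 0.0, atol=1e-8)

    def test_injected_desirability_effect_detected(self, events):
        cfg = StudyConfig(events=events, beta_desirability=1.5, seed=3)
        res = by_subject_partial(generate_study1(cfg))
        assert res["mean_r"] > 0
        assert res["p"] < 0.05

    def test_returns_one_r_per_retained_participant(self, study_df):
        res = by_subject_partial(study_df)
        assert len(res["r_values"]) + res["n_excluded"] == study_df["participant"].nunique()
        assert len(res["frequency_coefs"]) == len(res["r_values"])

    def test_null_world_mean_r_near_zero(self, study_df):
        res = by_subject_partial(study_df)
        assert abs(res["mean_r"]) < 0.1


class TestPartialCorrelation:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x, z = rng.normal(size=(2, 60))
        y = 0.5 * x + 0.3 * z + rng.normal(size=60)
        mine = partial_correlation(x, y, z)
        theirs = float(
            pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z")["r"].iloc[0]
        )
        assert mine == pytest.approx(theirs, abs=1e-10)

    def test_uncorrelated_control_reduces_to_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=2000)
        y = 0.6 * x + rng.normal(size=2000)
        z = rng.normal(size=2000)  # independent of both
        from scipy.stats import pearsonr

        assert partial_correlation(x, y, z) == pytest.approx(pearsonr(x, y).statistic, abs=0.01)

    @settings(deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_symmetric_and_affine_invariant(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 30))
        y = y + 0.4 * x
        r = partial_correlation(x, y, z)
        assert partial_correlation(y, x, z) == pytest.approx(r, abs=1e-12)
        assert partial_correlation(a * x + b, y, z) == pytest.approx(r, abs=1e-9)

    def test_ratio_score_mimics_egocentrism_pattern(self):
        """A comparative score that is literally self/average produces the
        asymmetric partial-correlation pattern read as 'egocentric weighting':
        opposite-signed partials, larger in magnitude for the self estimate."""
        rng = np.random.default_rng(11)
        average = rng.uniform(2, 60, 40)
        self_est = average * rng.lognormal(0.0, 0.5, 40)
        ratio = self_est / average
        r_avg = partial_correlation(average, ratio, self_est)
        r_self = partial_correlation(self_est, ratio, average)
        assert np.sign(r_avg) == -np.sign(r_self)
        assert abs(r_self) > abs(r_avg)

    def test_collinear_control_rejected(self):
        x = np.arange(10.0)
        y = np.arange(10.0)[::-1]
        with pytest.raises(ValueError):
            partial_correlation(x, y, 2 * x + 1)


class TestTwoWayAnova:
    @staticmethod
    def _balanced_2x2():
        return pd.DataFrame(
            {
                "severity": ["neutral"] * 4 + ["severe"] * 4,
                "target": (["self"] * 2 + ["other"] * 2) * 2,
                "estimate": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            }
        )

    def test_hand_computed_balanced_design(self):
        """Cell means 1.5/3.5/5.5/7.5 with within-cell variance 0.5: F = 64, 16, 0."""
        res = two_way_anova(self._balanced_2x2())
        assert res["severity"]["F"] == pytest.approx(64.0, rel=1e-9)
        assert res["target"]["F"] == pytest.approx(16.0, rel=1e-9)
        assert res["interaction"]["F"] == pytest.approx(0.0, abs=1e-9)
        assert res["severity"]["df"] == (1, 4)

    def test_additive_means_give_small_interaction(self, experiment_df):
        res = two_way_anova(experiment_df)
        assert res["interaction"]["p"] > 0.01  # no interaction was injected

    def test_simple_effects_use_pooled_error(self):
        res = two_way_anova(self._balanced_2x2(), simple_effects=True)
        se = res["simple_effects"]
        # within each severity level the target means differ by 2 with n=2
        # per cell -> SS = 2^2 * (2*2/4) = 4, F = 4 / MSE(0.5) = 8
        assert se["neutral"]["F"] == pytest.approx(8.0, rel=1e-9)
        assert se["severe"]["F"] == pytest.approx(8.0, rel=1e-9)
        assert se["neutral"]["df"] == (1, 4)

    def test_partial_eta_squared_range(self, experiment_df):
        res = two_way_anova(experiment_df)
        for key in ("severity", "target", "interaction"):
            assert 0.0 <= res[key]["partial_eta_sq"] <= 1.0

    def test_empty_cell_rejected(self):
        df = self._balanced_2x2()
        df = df[~((df["severity"] == "severe") & (df["target"] == "other"))]
        with pytest.raises(ValueError):
            two_way_anova(df)

    def test_null_pvalues_roughly_uniform(self):
        """Type-I calibration: under equal cell means, p < .05 about 5% of the time."""
        from riskartifacts import ExperimentConfig, generate_experiment

        rejections = 0
        n_seeds = 120
        for seed in range(n_seeds):
            df = generate_experiment(ExperimentConfig(n_per_cell=10, sd=20.0, seed=seed))
            rejections += two_way_anova(df)["target"]["p"] < 0.05
        # binomial(120, .05): 3 sigma band around 6
        assert rejections <= 14
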