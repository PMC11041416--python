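"""Bland-Altman statistics and model-family fitting."""

import numpy as np
import pandas as pd
import pytest

from hragree import agreement as agr


class TestBlandAltman:
    def test_constant_difference_degenerate_sd(self):
        ref = np.array([100.0, 120.0, 140.0])
        ba = agr.bland_altman(ref + 5.0, ref)
        assert ba.mean_diff == 5.0
        assert ba.sd_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (5.0, 5.0)

    def test_hand_computed_two_pairs(self):
        ba = agr.bland_altman(np.array([100.0, 110.0]), np.array([100.0, 100.0]))
        assert ba.mean_diff == pytest.approx(5.0)
        assert ba.sd_diff == pytest.approx(7.0711, abs=1e-4)
        assert ba.loa_low == pytest.approx(-8.859, abs=1e-3)
        assert ba.loa_high == pytest.approx(18.859, abs=1e-3)

    def test_swap_antisymmetry(self, rng):
        t = rng.uniform(80, 160, 30)
        r = rng.uniform(80, 160, 30)
        fwd, rev = agr.bland_altman(t, r), agr.bland_altman(r, t)
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff)
        assert fwd.loa_low == pytest.approx(-rev.loa_high)

    def test_loa_symmetric_about_bias(self, rng):
        ba = agr.bland_altman(rng.normal(100, 10, 50), rng.normal(100, 10, 50))
        assert ba.loa_high - ba.mean_diff == pytest.approx(ba.mean_diff - ba.loa_low)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            agr.bland_altman(np.array([100.0]), np.array([90.0]))


class TestPerParticipant:
    @staticmethod
    def summaries(rng, bias_by_pid, n=20):
        rows = []
        for pid, bias in bias_by_pid.items():
            ref = rng.uniform(120, 150, n)
            for i, r in enumerate(ref):
                rows.append(
                    {
                        "session_id": f"{pid}_{i}",
                        "participant_id": pid,
                        "age": 60.0,
                        "baseline_test": np.nan,
                        "baseline_ref": np.nan,
                        "peak20_test": r + bias + rng.normal(0, 1),
                        "peak20_ref": r,
                        "hr_th_max": 160.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_partition_bookkeeping(self, rng):
        df = self.summaries(rng, {"A": 2.0, "B": -3.0})
        table = agr.per_participant_agreement(df, "high_intensity")
        assert table["n"].sum() == len(df)

    def test_single_participant_reduces_to_cohort(self, rng):
        df = self.summaries(rng, {"A": 4.0})
        table = agr.per_participant_agreement(df, "high_intensity")
        cohort = agr.cohort_bland_altman(df, "high_intensity")
        assert table.loc[0, "mean_diff"] == pytest.approx(cohort.mean_diff)
        assert table.loc[0, "loa_high"] == pytest.approx(cohort.loa_high)

    def test_recovers_injected_participant_bias(self, rng):
        biases = {"A": 1.5, "B": -4.0, "C": 7.0}
        df = self.summaries(rng, biases, n=60)
        table = agr.per_participant_agreement(df, "high_intensity").set_index(
            "participant_id"
        )
        for pid, b in biases.items():
            se = table.loc[pid, "sd_diff"] / np.sqrt(table.loc[pid, "n"])
            assert abs(table.loc[pid, "mean_diff"] - b) < 2 * se + 1e-9

    def test_underpowered_participant_reported_without_stats(self, rng):
        df = self.summaries(rng, {"A": 2.0}, n=1)
        table = agr.per_participant_agreement(df, "high_intensity")
        assert table.loc[0, "n"] == 1
        assert np.isnan(table.loc[0, "mean_diff"])


class TestOverallBias:
    def test_matches_reported_condition_average(self):
        assert agr.overall_bias(1.68, 6.29) == pytest.approx(3.985)

    def test_idempotent_and_symmetric(self):
        assert agr.overall_bias(4.2, 4.2) == 4.2
        assert agr.overall_bias(-2.0, 2.0) == 0.0


class TestAIC:
    def test_unit_mean_square(self):
        assert agr.aic(rss=100.0, n=100, k=2) == pytest.approx(4.0)

    def test_direct_evaluation(self):
        assert agr.aic(rss=596 * np.e, n=596, k=4) == pytest.approx(604.0)

    def test_monotone_in_rss(self):
        assert agr.aic(50.0, 100, 2) < agr.aic(100.0, 100, 2)


class TestLinearFit:
    def test_collinear_perfect_r2(self):
        x = np.array([60.0, 100.0, 140.0, 180.0])
        fit = agr.linear_fit(x, 0.9 * x + 12.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params[1] == pytest.approx(0.9)

    def test_closed_form_three_points(self):
        fit = agr.linear_fit(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert fit.params[1] == pytest.approx(1.5)
        assert fit.params[0] == pytest.approx(-2.0 / 3.0)
        assert fit.r_squared == pytest.approx(27.0 / 28.0)

    def test_independent_data_r2_near_zero(self, rng):
        n = 4000
        fit = agr.linear_fit(rng.uniform(60, 160, n), rng.uniform(60, 160, n))
        assert fit.r_squared < 10.0 / (n - 1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            agr.linear_fit(np.full(10, 100.0), np.arange(10.0))


class TestFamilies:
    def test_noiseless_sigmoid_recovery(self):
        x = np.linspace(50, 180, 120)
        true = (30.0, 170.0, 110.0, 25.0)
        y = agr._sigmoid(x, *true)
        fit = agr.fit_family(x, y, "sigmoid")
        assert fit.rss < 1e-6
        assert np.allclose(fit.params, true, rtol=1e-3)

    def test_linear_family_matches_closed_form(self, rng):
        x = rng.uniform(60, 160, 50)
        y = 0.8 * x + 10 + rng.normal(0, 2, 50)
        fit = agr.fit_family(x, y, "linear")
        beta, alpha = np.polyfit(x, y, 1)
        assert fit.params == pytest.approx([alpha, beta], abs=1e-8)

    def test_logarithmic_domain_guard(self):
        with pytest.raises(ValueError, match="> 0"):
            agr.fit_family(np.array([0.0, 1, 2, 3]), np.arange(4.0), "logarithmic")

    def test_noiseless_negative_exponential_recovery(self):
        x = np.linspace(60, 160, 80)
        y = agr._neg_exponential(x, 160.0, 400.0, 0.03)
        fit = agr.fit_family(x, y, "negative_exponential")
        assert fit.rss < 1e-4

    def test_sigmoid_approximates_linear_data(self):
        # nested-dominance within tolerance: a wide sigmoid can track a line
        x = np.linspace(60, 160, 101)
        y = 0.8 * x + 10.0
        fit = agr.fit_family(x, y, "sigmoid")
        rmse = np.sqrt(fit.rss / fit.n)
        assert rmse < 2.0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            agr.fit_family(np.arange(10.0), np.arange(10.0), "cubic")


class TestSelection:
    @staticmethod
    def fake_fit(family, aic_value, k):
        return agr.ModelFit(
            family=family, params=np.array([]), param_names=(), rss=1.0,
            n=10, k=k, aic=aic_value,
        )

    def test_argmin(self):
        fits = [
            self.fake_fit("linear", 10.0, 2),
            self.fake_fit("sigmoid", 8.0, 4),
            self.fake_fit("logarithmic", 12.0, 2),
        ]
        assert agr.select_model(fits) == "sigmoid"

    def test_tie_prefers_fewer_parameters(self):
        fits = [self.fake_fit("sigmoid", 8.0, 4), self.fake_fit("linear", 8.0, 2)]
        assert agr.select_model(fits) == "linear"

    def test_all_failed_rejected(self):
        bad = self.fake_fit("linear", np.inf, 2)
        bad.success = False
        with pytest.raises(ValueError, match="no successful"):
            agr.select_model([bad])

    def test_predict_flags_extrapolation(self):
        x = np.linspace(60, 160, 50)
        fit = agr.fit_family(x, 0.9 * x + 5, "linear")
        yhat, extra = agr.predict(fit, np.array([50.0, 100.0, 170.0]))
        assert list(extra) == [True, False, True]
        assert yhat[1] == pytest.approx(95.0)
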