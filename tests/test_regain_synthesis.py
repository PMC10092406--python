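import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weightregain.errors import EstimationError
from weightregain.regain_synthesis import (
    CrossingRecord,
    crossing_times,
    fit_metareg,
    fit_mixed,
    followup_bias_check,
    km_estimate,
    qol_weight_slope,
    smd_to_sf36,
    standardize_qol,
)
from weightregain.study_corpus import (
    DifferenceSeries,
    build_difference_series,
    corpus_from_frame,
    filter_regain_eligible,
)
from conftest import linear_series, make_rows


def _noisy_series(rng, n_studies=12, slope=0.03, tau=0.8, noise=0.5,
                  ts=(0.0, 6.0, 12.0, 24.0)):
    out = []
    for j in range(n_studies):
        a = rng.normal(-2.8, tau)
        pts = tuple(
            (float(t), float(a + slope * t + rng.normal(0, noise)), 0.1, 100) for t in ts
        )
        out.append(DifferenceSeries(f"s{j}", "weight_kg", pts, 6.0 + max(ts)))
    return out


class TestMixedModel:
    def test_noiseless_random_intercepts_recover_slope_exactly(self):
        rng = np.random.default_rng(4)
        a = rng.normal(-2.8, 0.8, size=10)
        series = [linear_series(f"s{j}", a[j], 0.03, [0, 6, 12, 36]) for j in range(10)]
        fit = fit_mixed(series, weights_policy="none")
        assert fit.slope == pytest.approx(0.03, abs=1e-9)
        # at the degenerate zero-noise REML boundary the intercept is a
        # precision-weighted mean of the a_j; close to, not exactly, mean(a)
        assert fit.intercept == pytest.approx(a.mean(), abs=0.05)

    def test_near_noiseless_tau2_approaches_intercept_variance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(-2.8, 0.8, size=12)
        series = [
            DifferenceSeries(
                f"s{j}",
                "weight_kg",
                tuple(
                    (t, float(a[j] + 0.03 * t + rng.normal(0, 1e-3)), 0.1, 100)
                    for t in (0.0, 6.0, 12.0, 36.0)
                ),
                42.0,
            )
            for j in range(12)
        ]
        fit = fit_mixed(series, weights_policy="none")
        assert fit.tau2 == pytest.approx(np.var(a, ddof=1), rel=0.05)

    def test_single_study_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(8)
        ts = np.array([0.0, 6.0, 12.0, 24.0, 36.0])
        ys = -3.0 + 0.02 * ts + rng.normal(0, 0.4, ts.size)
        series = [
            DifferenceSeries(
                "only", "weight_kg", tuple((float(t), float(y), None, 50) for t, y in zip(ts, ys)), 42.0
            )
        ]
        fit = fit_mixed(series, weights_policy="none")
        slope_ols, intercept_ols = np.polyfit(ts, ys, 1)
        assert fit.slope == pytest.approx(slope_ols, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept_ols, abs=1e-10)

    def test_matches_statsmodels_mixedlm_reml(self):
        import pandas as pd
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        series = _noisy_series(rng)
        fit = fit_mixed(series, weights_policy="none")
        rows = [
            {"g": s.study_id, "t": t, "y": d}
            for s in series
            for t, d, _, _ in s.points
        ]
        df = pd.DataFrame(rows)
        sm_fit = smf.mixedlm("y ~ t", df, groups=df["g"]).fit(reml=True)
        assert fit.slope == pytest.approx(sm_fit.params["t"], abs=1e-6)
        assert fit.intercept == pytest.approx(sm_fit.params["Intercept"], abs=1e-6)
        assert fit.tau2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.se_slope == pytest.approx(sm_fit.bse["t"], rel=1e-3)

    def test_ci_covers_truth_on_reference_synthetic_corpus(self, corpus_seed7):
        series = filter_regain_eligible(build_difference_series(corpus_seed7))
        fit = fit_mixed(series)
        lo, hi = fit.ci95_slope
        assert lo < 0.027 < hi
        assert fit.tau2 > 0

    def test_all_points_at_programme_end_is_inestimable(self):
        series = [linear_series(f"s{j}", -2.0, 0.0, [0]) for j in range(5)]
        with pytest.raises(EstimationError):
            fit_mixed(series)


class TestMetaRegression:
    def test_noiseless_common_slope_recovered_with_zero_tau2(self):
        series = [
            linear_series(f"s{j}", -2.8, 0.01, [0, t_final])
            for j, t_final in enumerate([12, 24, 36, 48, 60])
        ]
        fit = fit_metareg(series)
        assert fit.slope == pytest.approx(0.01, abs=1e-8)
        assert fit.tau2 == pytest.approx(0.0, abs=1e-8)

    def test_matches_metafor_reml_on_frozen_fixture(self):
        # oracle: R metafor rma(yi, vi, mods=~t, method="REML") on this table
        y = [-2.0, -1.5, -2.5, -1.0, -0.5, -1.8]
        v = [0.04, 0.09, 0.02, 0.16, 0.08, 0.05]
        t = [12.0, 24.0, 18.0, 36.0, 48.0, 30.0]
        series = [
            DifferenceSeries(f"s{i}", "weight_kg",
                             ((0.0, -3.0, 0.04, 100), (t[i], y[i], v[i], 100)), 60.0)
            for i in range(6)
        ]
        fit = fit_metareg(series)
        assert fit.intercept == pytest.approx(-2.9612055288, abs=1e-6)
        assert fit.slope == pytest.approx(0.0490877369, abs=1e-7)
        assert fit.tau2 == pytest.approx(0.1136225169, abs=1e-5)
        assert fit.se_slope == pytest.approx(0.0145374013, abs=1e-6)

    def test_shared_final_time_is_inestimable(self):
        series = [linear_series(f"s{j}", -2.0 - j, 0.02, [0, 24]) for j in range(5)]
        with pytest.raises(EstimationError):
            fit_metareg(series)

    def test_fewer_than_three_studies_is_an_error(self):
        series = [linear_series("a", -2, 0.02, [0, 12]), linear_series("b", -3, 0.02, [0, 24])]
        with pytest.raises(EstimationError):
            fit_metareg(series)

    def test_agrees_with_mixed_model_on_two_point_noiseless_studies(self):
        series = [
            linear_series(f"s{j}", -2.8, 0.015, [0, t_final])
            for j, t_final in enumerate([12, 18, 24, 36, 60])
        ]
        m1 = fit_mixed(series, weights_policy="none")
        m2 = fit_metareg(series)
        assert m1.slope == pytest.approx(m2.slope, abs=1e-8)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-7)


class TestTimeToEvent:
    def test_crossing_interpolated_between_visits(self):
        s = DifferenceSeries("s", "weight_kg", ((0.0, -2.0, None, 50), (10.0, 2.0, None, 50)), 16.0)
        (rec,) = crossing_times([s])
        assert rec.event and rec.time_months == pytest.approx(5.0)

    def test_never_crossing_censors_at_last_visit(self):
        s = linear_series("s", -4.0, 0.01, [0, 12, 36])
        (rec,) = crossing_times([s])
        assert not rec.event and rec.time_months == 36.0

    @given(
        d0=st.floats(-8.0, -0.5),
        rate=st.floats(0.01, 0.4),
    )
    @settings(max_examples=50, deadline=None)
    def test_crossing_exact_for_linear_series(self, d0, rate):
        t_cross = -d0 / rate
        ts = [0.0, t_cross * 0.4, t_cross * 1.6]
        s = DifferenceSeries(
            "s", "weight_kg", tuple((t, d0 + rate * t, None, 50) for t in ts), 99.0
        )
        (rec,) = crossing_times([s])
        assert rec.event
        assert rec.time_months == pytest.approx(t_cross, rel=1e-9)

    def test_km_median_with_three_events(self):
        recs = [CrossingRecord(f"s{i}", t, True) for i, t in enumerate([10, 20, 30])]
        km = km_estimate(recs)
        assert km.median_months == pytest.approx(20.0)

    def test_km_median_undefined_when_all_censored(self):
        recs = [CrossingRecord(f"s{i}", t, False) for i, t in enumerate([12, 24, 36])]
        assert km_estimate(recs).median_months is None

    def test_km_single_event_steps_to_zero(self):
        km = km_estimate([CrossingRecord("s", 5.0, True)])
        assert km.median_months == pytest.approx(5.0)
        assert km.survival[-1] == pytest.approx(0.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        # exhaustive over event-time multisets of up to 6 studies
        grid = [6.0, 12.0, 24.0]
        for k in range(1, 7):
            for times in itertools.combinations_with_replacement(grid, k):
                recs = [CrossingRecord(f"s{i}", t, True) for i, t in enumerate(times)]
                km = km_estimate(recs)
                arr = np.asarray(times)
                for t, s in zip(km.times, km.survival):
                    assert s == pytest.approx(np.mean(arr > t), abs=1e-12)


class TestQualityOfLife:
    def test_smd_from_pooled_sd(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 50),
            ("s1", "i", "intervention", 6, 6, -4.0, 3.0, 50),
        )
        df.loc[:, "qol_scale"] = "SF-36"
        df.loc[:, "qol_direction"] = "higher_better"
        df.loc[df.arm_role == "control", "qol_mean_change"] = 0.0
        df.loc[df.arm_role == "intervention", "qol_mean_change"] = 5.0
        df.loc[:, "qol_sd"] = 25.0
        (series,) = standardize_qol(corpus_from_frame(df))
        assert series.at_programme_end() == pytest.approx(0.2)

    def test_zero_difference_gives_zero_smd(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 50),
            ("s1", "i", "intervention", 6, 6, -4.0, 3.0, 50),
        )
        df.loc[:, ["qol_scale", "qol_direction"]] = ["SF-36", "higher_better"]
        df.loc[:, "qol_mean_change"] = 3.0
        df.loc[:, "qol_sd"] = 25.0
        (series,) = standardize_qol(corpus_from_frame(df))
        assert series.at_programme_end() == 0.0

    def test_lower_is_better_scale_flips_sign(self):
        df = make_rows(
            ("s1", "c", "control", 6, 6, -2.0, 3.0, 50),
            ("s1", "i", "intervention", 6, 6, -4.0, 3.0, 50),
        )
        df.loc[:, ["qol_scale", "qol_direction"]] = ["IWQOL", "lower_better"]
        df.loc[df.arm_role == "control", "qol_mean_change"] = 0.0
        df.loc[df.arm_role == "intervention", "qol_mean_change"] = -5.0
        df.loc[:, "qol_sd"] = 25.0
        (series,) = standardize_qol(corpus_from_frame(df))
        assert series.at_programme_end() == pytest.approx(+0.2)

    def test_smd_back_conversion_to_sf36_points(self):
        assert smd_to_sf36(0.2, [30.0])["median"] == pytest.approx(6.0)
        assert smd_to_sf36(0.0, [30.0])["median"] == 0.0
        res = smd_to_sf36(0.2, [10.0, 30.0, 50.0])
        assert res["median"] == pytest.approx(6.0)
        assert res["iqr"] == (pytest.approx(4.0), pytest.approx(8.0))
        with pytest.raises(EstimationError):
            smd_to_sf36(0.2, [])

    def test_qol_weight_slope_exact_on_noiseless_pairing(self):
        weight = [linear_series(f"s{j}", -2.8 - 0.2 * j, 0.03, [0, 6, 12, 24]) for j in range(6)]
        qol = []
        for s in weight:
            pts = tuple((t, 0.15 - 0.02 * d, 0.01, n) for t, d, _, n in s.points)
            qol.append(DifferenceSeries(s.study_id, "qol_smd", pts, s.max_followup_months))
        fit = qol_weight_slope(qol, weight)
        assert fit.slope == pytest.approx(-0.02, abs=1e-9)

    def test_qol_weight_slope_needs_varying_weight(self):
        weight = [linear_series(f"s{j}", -2.8, 0.0, [0, 6]) for j in range(4)]
        qol = [
            DifferenceSeries(s.study_id, "qol_smd",
                             tuple((t, 0.2, 0.01, n) for t, _, _, n in s.points), 12.0)
            for s in weight
        ]
        with pytest.raises(EstimationError):
            qol_weight_slope(qol, weight)


class TestFollowupBiasCheck:
    def test_constant_followup_is_inestimable(self):
        series = [linear_series(f"s{j}", -2 - j, 0.02, [0, 12], max_fu=24.0) for j in range(5)]
        with pytest.raises(EstimationError):
            followup_bias_check(series)

    def test_recovers_built_in_association(self):
        rng = np.random.default_rng(13)
        slopes = []
        for _ in range(30):
            series = []
            for j in range(40):
                fu = rng.uniform(12, 120)
                d0 = -4.0 + 0.02 * fu + rng.normal(0, 0.3)
                series.append(
                    DifferenceSeries(
                        f"s{j}", "weight_kg",
                        ((0.0, d0, 0.05, 100), (fu / 2, d0 + 0.2, 0.05, 100)),
                        max_followup_months=fu,
                    )
                )
            slopes.append(followup_bias_check(series).slope)
        assert np.mean(slopes) == pytest.approx(0.02, rel=0.1)

    def test_null_association_ci_covers_zero_on_reference_corpus(self, corpus_seed7):
        series = filter_regain_eligible(build_difference_series(corpus_seed7))
        fit = followup_bias_check(series)
        lo, hi = fit.ci95_slope
        assert lo < 0.0 < hi
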