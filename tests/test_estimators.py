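"""The five growth-rate estimators, the reference fit, and method selection."""

import numpy as np
import pytest
from conftest import exact_traj, grid_search_lsf1, grid_search_lsf2, make_traj
from hypothesis import given, settings
from hypothesis import strategies as st

from pkdgrowth import (
    DegenerateDesignError,
    InsufficientDataError,
    blend_mic_lsf2,
    fit_ground_truth,
    fit_lsf1,
    fit_lsf2,
    fit_mic_average,
    fit_mic_latest,
    mic_rate,
    recommend_rate,
)


class TestMicLatest:
    def test_single_scan(self):
        traj = make_traj([40.0], [600.0])
        fit = fit_mic_latest(traj, 1)
        assert fit.rate_r == pytest.approx(0.0352649, abs=1e-6)
        assert fit.httkv0 == 150.0 and fit.n_points == 1

    def test_on_curve_uses_scan_k(self):
        traj = exact_traj(150.0, 0.03, [40.0, 45.0])
        assert fit_mic_latest(traj, 2).rate_r == pytest.approx(0.03, rel=1e-12)

    def test_k_out_of_range(self):
        traj = make_traj([40.0], [600.0])
        with pytest.raises(IndexError):
            fit_mic_latest(traj, 0)
        with pytest.raises(IndexError):
            fit_mic_latest(traj, 2)


class TestMicAverage:
    def test_mean_of_equal_rates(self):
        traj = exact_traj(150.0, 0.04, [30.0, 35.0])
        assert fit_mic_average(traj, 2).rate_r == pytest.approx(0.04, rel=1e-12)

    def test_arithmetic_mean_of_per_scan_rates(self):
        # volumes chosen so per-scan MIC rates are exactly 0.02 and 0.04
        ages = [30.0, 40.0]
        vols = [150 * 1.02**30, 150 * 1.04**40]
        assert fit_mic_average(make_traj(ages, vols), 2).rate_r == pytest.approx(
            0.03, rel=1e-12
        )

    def test_needs_two_scans(self):
        with pytest.raises(InsufficientDataError):
            fit_mic_average(make_traj([40.0, 42.0], [400.0, 430.0]), 1)


class TestLsf1:
    def test_consistent_data_recovered_with_zero_rss(self):
        traj = exact_traj(150.0, 0.03, [30.0, 35.0, 41.0, 44.0])
        fit = fit_lsf1(traj, 4)
        assert fit.rate_r == pytest.approx(0.03, rel=1e-12)
        assert fit.rss_log == pytest.approx(0.0, abs=1e-20)

    def test_two_point_closed_form(self, two_point_traj):
        fit = fit_lsf1(two_point_traj, 2)
        assert fit.rate_r == pytest.approx(0.0261037, abs=1e-6)
        assert fit.httkv0 == 150.0

    def test_matches_grid_search(self, two_point_traj):
        fit = fit_lsf1(two_point_traj, 2)
        b = grid_search_lsf1([40.0, 45.0], [400.0, 500.0])
        assert np.log1p(fit.rate_r) == pytest.approx(b, abs=2e-5)

    def test_duplicate_points_weight_like_repeats(self):
        ages = [40.0, 40.0 + 1e-9, 45.0]
        t1 = make_traj(ages, [400.0, 400.0, 500.0])
        # a duplicated point pulls the fit toward itself relative to 2 points
        t2 = make_traj([40.0, 45.0], [400.0, 500.0])
        assert fit_lsf1(t1, 3).rate_r != pytest.approx(fit_lsf1(t2, 2).rate_r, abs=1e-8)


class TestLsf2:
    def test_two_point_interpolation(self, two_point_traj):
        fit = fit_lsf2(two_point_traj, 2)
        r = (500 / 400) ** (1 / 5) - 1
        assert fit.rate_r == pytest.approx(r, rel=1e-12)
        assert fit.httkv0 == pytest.approx(400 / (1 + r) ** 40, rel=1e-10)
        assert fit.httkv0 == pytest.approx(67.1089, abs=1e-3)

    def test_noiseless_recovery(self):
        traj = exact_traj(200.0, 0.05, [20.0, 25.0, 31.0, 36.0, 40.0])
        fit = fit_lsf2(traj, 5)
        assert fit.rate_r == pytest.approx(0.05, rel=1e-10)
        assert fit.httkv0 == pytest.approx(200.0, rel=1e-10)

    def test_two_distinct_ages_suffice(self):
        traj = make_traj([40.0, 40.0 + 1e-9, 45.0], [400.0, 410.0, 500.0])
        fit = fit_lsf2(traj, 3)
        assert fit.rate_r > 0

    def test_identical_ages_degenerate(self):
        traj = make_traj([40.0, 40.0 + 1e-12], [400.0, 410.0])
        with pytest.raises((DegenerateDesignError, InsufficientDataError)):
            fit_lsf2(traj, 2)

    def test_matches_nested_grid_search(self, rng):
        for _ in range(5):
            n = rng.integers(3, 9)
            ages = np.sort(rng.uniform(20, 60, n))
            ages += np.arange(n) * 1e-3
            vols = 150 * np.exp(rng.uniform(-0.5, 1.5, n))
            fit = fit_lsf2(make_traj(ages, vols), int(n))
            a, b = grid_search_lsf2(ages, vols)
            assert np.log(fit.httkv0) == pytest.approx(a, abs=1e-4)
            assert np.log1p(fit.rate_r) == pytest.approx(b, abs=1e-5)

    @given(
        httkv0=st.floats(min_value=30.0, max_value=600.0),
        r=st.floats(min_value=-0.09, max_value=0.19),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_recovery_property(self, httkv0, r):
        ages = [22.0, 28.0, 35.0, 41.0, 50.0]
        fit = fit_lsf2(exact_traj(httkv0, r, ages), 5)
        assert fit.rate_r == pytest.approx(r, rel=1e-9, abs=1e-12)
        assert fit.httkv0 == pytest.approx(httkv0, rel=1e-9)


class TestLinearFitSpace:
    def test_matches_log_space_on_noiseless_data(self):
        traj = exact_traj(180.0, 0.04, [25.0, 30.0, 38.0, 45.0])
        log_fit = fit_lsf2(traj, 4)
        lin_fit = fit_lsf2(traj, 4, fit_space="linear")
        assert lin_fit.rate_r == pytest.approx(log_fit.rate_r, rel=1e-8)
        assert lin_fit.httkv0 == pytest.approx(log_fit.httkv0, rel=1e-8)

    def test_minimises_volume_space_rss(self, rng):
        ages = np.array([25.0, 30.0, 38.0, 45.0])
        vols = 150 * 1.05**ages * np.exp(rng.normal(0, 0.1, 4))
        traj = make_traj(ages, vols)
        fit = fit_lsf2(traj, 4, fit_space="linear")

        def rss_lin(r, v0):
            return ((v0 * (1 + r) ** ages - vols) ** 2).sum()

        base = rss_lin(fit.rate_r, fit.httkv0)
        for dr in (-1e-4, 1e-4):
            assert rss_lin(fit.rate_r + dr, fit.httkv0) >= base
        log_fit = fit_lsf2(traj, 4)
        assert base <= rss_lin(log_fit.rate_r, log_fit.httkv0)

    def test_lsf1_linear_keeps_intercept_pinned(self):
        traj = exact_traj(150.0, 0.035, [30.0, 36.0, 44.0])
        fit = fit_lsf1(traj, 3, fit_space="linear")
        assert fit.httkv0 == 150.0
        assert fit.rate_r == pytest.approx(0.035, rel=1e-8)


class TestGroundTruthAndBlend:
    def test_ground_truth_is_full_lsf2(self):
        traj = exact_traj(120.0, 0.036, [20.0, 23.0, 27.0, 30.0, 34.0, 38.0])
        gt = fit_ground_truth(traj)
        full = fit_lsf2(traj, 6)
        assert gt.rate_r == full.rate_r and gt.httkv0 == full.httkv0
        assert gt.method == "ground_truth"
        assert gt.rate_r == pytest.approx(0.036, rel=1e-10)
        assert gt.httkv0 == pytest.approx(120.0, rel=1e-10)

    def test_ground_truth_single_scan_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_ground_truth(make_traj([40.0], [400.0]))

    def test_blend_is_mean_of_component_rates(self, two_point_traj):
        fit = blend_mic_lsf2(two_point_traj, 2)
        mic = fit_mic_latest(two_point_traj, 2)
        ls = fit_lsf2(two_point_traj, 2)
        assert fit.rate_r == pytest.approx(0.5 * (mic.rate_r + ls.rate_r), rel=1e-12)
        assert fit.httkv0 == pytest.approx(np.sqrt(mic.httkv0 * ls.httkv0), rel=1e-12)

    def test_blend_on_mic_curve_equals_components(self):
        traj = exact_traj(150.0, 0.03, [30.0, 36.0, 42.0])
        assert blend_mic_lsf2(traj, 3).rate_r == pytest.approx(0.03, rel=1e-10)

    def test_blend_needs_two_scans(self):
        with pytest.raises(InsufficientDataError):
            blend_mic_lsf2(make_traj([40.0, 44.0], [400.0, 480.0]), 1)


class TestRecommendRate:
    @pytest.mark.parametrize(
        "k, method", [(1, "mic_latest"), (2, "mic_latest"), (3, "blend_mic_lsf2"),
                      (4, "lsf2"), (5, "lsf2")]
    )
    def test_scan_count_rule(self, k, method):
        traj = exact_traj(170.0, 0.04, [30.0, 32.0, 34.5, 37.0, 39.0])
        assert recommend_rate(traj, k).method == method

    def test_degenerate_design_falls_back_to_mic(self, caplog):
        ages = [40.0, 40.0 + 1e-12, 40.0 + 2e-12]
        traj = make_traj(ages, [400.0, 405.0, 410.0])
        with caplog.at_level("WARNING"):
            fit = recommend_rate(traj, 3)
        assert fit.method == "mic_latest"
        assert "degenerate_design_fallback" in fit.warnings


class TestInvariants:
    def test_all_estimators_agree_on_mic_curve(self):
        """Noiseless data with true birth volume 150 make all five coincide."""
        traj = exact_traj(150.0, 0.027, [25.0, 29.0, 34.0, 40.0])
        rates = [
            fit_mic_latest(traj, 4).rate_r,
            fit_mic_average(traj, 4).rate_r,
            fit_lsf1(traj, 4).rate_r,
            fit_lsf2(traj, 4).rate_r,
            blend_mic_lsf2(traj, 4).rate_r,
        ]
        assert all(r == pytest.approx(0.027, rel=1e-9) for r in rates)

    def test_mic_bias_closed_form(self):
        """Noiseless data off the 150 assumption bias MIC by a known factor."""
        httkv0, r = 220.0, 0.03
        traj = exact_traj(httkv0, r, [35.0, 42.0, 50.0])
        for obs in traj.observations:
            expected = (1 + r) * (httkv0 / 150.0) ** (1 / obs.age_years) - 1
            assert mic_rate(obs.age_years, obs.httkv) == pytest.approx(
                expected, rel=1e-12
            )

    def test_order_invariance(self, rng):
        ages = rng.uniform(20, 60, 6)
        ages.sort()
        vols = 150 * np.exp(rng.normal(0.5, 0.3, 6))
        perm = rng.permutation(6)
        t1 = make_traj(ages, vols)
        t2 = make_traj(ages[perm], vols[perm])
        assert fit_lsf2(t1, 6).rate_r == fit_lsf2(t2, 6).rate_r
        assert fit_lsf1(t1, 6).rate_r == fit_lsf1(t2, 6).rate_r
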