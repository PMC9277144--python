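"""Analytic plug-flow forms, rate-point assembly and (k, n) estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from srbkin import (
    DegenerateFitError,
    InsufficientDataError,
    KineticModel,
    MissingFeedError,
    RatePoint,
    SteadyStateObservation,
    build_rate_points,
    confidence_band,
    filter_rate_points,
    fit_kinetics,
    goodness_of_fit,
    grid_search_sse,
    mean_rate,
    pfr_outlet_concentration,
)


def numeric_outlet(C0: float, k: float, n: float, tau: float) -> float:
    """Independent oracle: adaptive integration of dC/dτ = −k·Cⁿ."""
    sol = solve_ivp(
        lambda _, c: [-k * max(c[0], 0.0) ** n],
        (0.0, tau),
        [C0],
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    return max(float(sol.y[0, -1]), 0.0)


def ladder_points(model: KineticModel, C0: float = 1000.0) -> list[RatePoint]:
    """Noiseless rate points over the 9-step dilution ladder × 3 volumes."""
    ladder = (0.010, 0.014, 0.016, 0.018, 0.021, 0.024, 0.028, 0.032, 0.042)
    points = []
    for d in ladder:
        for v in (0.33, 0.66, 1.0):
            fv = d / v
            ca = pfr_outlet_concentration(C0, model, 1.0 / fv)
            points.append(RatePoint(fv, C0, ca, fv * (C0 - ca), v))
    return points


class TestOutletConcentration:
    @pytest.mark.parametrize("n", [0.5, 0.8, 1.5, 2.0, 2.9, 5.0])
    @pytest.mark.parametrize("extent", [0.01, 0.5, 2.0, 20.0])
    def test_matches_numeric_integration(self, n, extent):
        """Closed form agrees with the adaptive ODE oracle to <= 1e-6 relative."""
        C0, tau = 1000.0, 24.0
        k = extent / (tau * C0 ** (n - 1.0))  # so k·τ·C0^(n−1) = extent
        model = KineticModel(k=k, n=n)
        analytic = pfr_outlet_concentration(C0, model, tau)
        numeric = numeric_outlet(C0, k, n, tau)
        assert analytic == pytest.approx(numeric, rel=1e-6, abs=1e-6)

    def test_printed_truth_first_order(self):
        model = KineticModel(k=0.06955, n=1.0)
        assert pfr_outlet_concentration(1000.0, model, 24.0) == pytest.approx(
            188.4, abs=0.05
        )

    def test_printed_truth_high_order(self):
        model = KineticModel(k=1.5e-7, n=2.9)
        assert pfr_outlet_concentration(1000.0, model, 24.0) == pytest.approx(
            457.0, abs=0.5
        )

    def test_zero_rate_constant_returns_inlet(self):
        assert pfr_outlet_concentration(1000.0, KineticModel(k=0.0, n=2.0), 24.0) == 1000.0

    def test_sub_first_order_clamps_at_complete_conversion(self):
        # n < 1 exhausts substrate in finite time; outlet clamps to zero
        model = KineticModel(k=50.0, n=0.5)
        assert pfr_outlet_concentration(100.0, model, 10.0) == 0.0

    def test_first_order_limit_is_continuous(self):
        C0, tau, k = 1000.0, 24.0, 0.06955
        exact = C0 * math.exp(-k * tau)
        for n in (1.0 - 1e-6, 1.0 + 1e-6):
            near = pfr_outlet_concentration(C0, KineticModel(k=k, n=n), tau)
            assert near == pytest.approx(exact, rel=1e-3)

    @given(
        n=st.floats(0.5, 5.0),
        k=st.floats(1e-9, 1e-1),
        tau1=st.floats(0.0, 50.0),
        dtau=st.floats(0.0, 50.0),
    )
    def test_monotone_non_increasing_in_residence_time(self, n, k, tau1, dtau):
        model = KineticModel(k=k, n=n)
        c1 = pfr_outlet_concentration(1000.0, model, tau1)
        c2 = pfr_outlet_concentration(1000.0, model, tau1 + dtau)
        assert c2 <= c1 + 1e-9


class TestMeanRate:
    def test_zero_k_gives_zero_rate(self):
        assert mean_rate(1000.0, KineticModel(k=0.0, n=1.0), 1.0 / 24.0) == 0.0

    def test_printed_first_order_example(self):
        assert mean_rate(1000.0, KineticModel(k=0.06955, n=1.0), 1.0 / 24.0) == pytest.approx(
            33.8, abs=0.05
        )

    def test_large_k_approaches_complete_conversion_bound(self):
        rate = mean_rate(1000.0, KineticModel(k=1e3, n=1.0), 1.0 / 24.0)
        assert rate == pytest.approx(1000.0 / 24.0, rel=1e-6)

    @given(
        k1=st.floats(1e-6, 1e-1),
        factor=st.floats(1.0, 100.0),
        fv=st.floats(1e-3, 1.0),
        n=st.floats(0.5, 4.0),
    )
    def test_nonnegative_increasing_in_k_and_bounded(self, k1, factor, fv, n):
        C0 = 1000.0
        r1 = mean_rate(C0, KineticModel(k=k1, n=n), fv)
        r2 = mean_rate(C0, KineticModel(k=k1 * factor, n=n), fv)
        assert 0.0 <= r1 <= r2 + 1e-9
        assert r2 <= fv * C0 + 1e-9


class TestRatePoints:
    def _obs(self, d, boundary, conc, excluded=False):
        return SteadyStateObservation(d, boundary, "sulfate", conc, excluded=excluded)

    def test_three_cumulative_points_per_steady_state(self, lactate_config):
        obs = [
            self._obs(0.010, "feed", 1000.0),
            self._obs(0.010, "inlet", 580.0),
            self._obs(0.010, "middle", 300.0),
            self._obs(0.010, "effluent", 100.0),
        ]
        points = build_rate_points(obs, lactate_config)
        assert len(points) == 3
        inlet = points[0]
        assert inlet.flow_per_volume == pytest.approx(0.010 / 0.33)
        assert inlet.y == pytest.approx((1000.0 - 580.0) * 0.010 / 0.33)
        assert inlet.y == pytest.approx(12.73, abs=0.01)
        assert [p.segment_volume for p in points] == [0.33, 0.66, 1.0]

    def test_excluded_rows_contribute_no_points(self, lactate_config):
        obs = [
            self._obs(0.014, "feed", 1000.0),
            self._obs(0.014, "inlet", 600.0, excluded=True),
            self._obs(0.014, "middle", 400.0),
        ]
        points = build_rate_points(obs, lactate_config)
        assert [p.label for p in points] == ["inlet+middle 0.66 L"]

    def test_missing_feed_is_an_error(self, lactate_config):
        with pytest.raises(MissingFeedError, match="0.021"):
            build_rate_points([self._obs(0.021, "inlet", 500.0)], lactate_config)

    def test_dataset_filter(self, lactate_config):
        obs = [
            self._obs(0.010, "feed", 1000.0),
            self._obs(0.010, "inlet", 580.0),
            self._obs(0.010, "effluent", 100.0),
        ]
        points = build_rate_points(obs, lactate_config)
        assert len(filter_rate_points(points, "inlet")) == 1
        assert len(filter_rate_points(points, "whole")) == 1
        assert len(filter_rate_points(points, "composite")) == 0
        assert len(filter_rate_points(points, "joint")) == 2

    def test_inconsistent_rate_point_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            RatePoint(0.042, 1000.0, 500.0, 99.0, 1.0)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        sse, r2, se, dof = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 2)
        assert (sse, r2, dof) == (0.0, 1.0, 1)
        assert se == 0.0

    def test_mean_predictor_has_zero_r2(self):
        y = [1.0, 2.0, 3.0]
        _, r2, _, _ = goodness_of_fit(y, [2.0, 2.0, 2.0], 1)
        assert r2 == pytest.approx(0.0)

    def test_hand_worked_example(self):
        sse, r2, se, dof = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], 1)
        assert sse == pytest.approx(1.0)
        assert dof == 2
        assert se == pytest.approx(math.sqrt(0.5), abs=1e-4)

    def test_zero_variance_with_misfit_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            goodness_of_fit([2.0, 2.0], [1.0, 3.0], 1)


class TestFit:
    def test_single_point_fixed_order_interpolates_exactly(self):
        fv, C0 = 1.0 / 24.0, 1000.0
        truth = KineticModel(k=0.05, n=1.0)
        y = mean_rate(C0, truth, fv)
        result = fit_kinetics([RatePoint(fv, C0, C0 - y / fv, y, 1.0)], order_fixed=1.0)
        assert result.sse == pytest.approx(0.0, abs=1e-18)
        assert result.model.k == pytest.approx(0.05, rel=1e-9)

    def test_recovers_first_order_truth_from_noiseless_ladder(self):
        points = ladder_points(KineticModel(k=0.06955, n=1.0))
        result = fit_kinetics(points, order_fixed=1.0)
        assert result.model.k == pytest.approx(0.06955, rel=1e-3)
        assert result.r2 > 0.999

    def test_recovers_free_order_truth_from_noiseless_ladder(self):
        points = ladder_points(KineticModel(k=1.5e-7, n=2.9))
        result = fit_kinetics(points)
        assert result.model.n == pytest.approx(2.9, abs=0.05)
        assert result.model.k == pytest.approx(1.5e-7, rel=0.05)

    def test_sse_beats_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        truth = KineticModel(k=0.06955, n=1.0)
        noisy = []
        for p in ladder_points(truth):
            y = max(p.y * (1.0 + 0.05 * rng.standard_normal()), 0.0)
            noisy.append(RatePoint(p.flow_per_volume, p.C0, p.C0 - y / p.flow_per_volume,
                                   y, p.segment_volume))
        fit = fit_kinetics(noisy)
        oracle = grid_search_sse(noisy, n_grid=40)
        assert fit.sse <= oracle * (1.0 + 1e-9)

    def test_repeated_fits_are_deterministic(self):
        points = ladder_points(KineticModel(k=7e-5, n=2.0))
        sses = {fit_kinetics(points).sse for _ in range(3)}
        assert max(sses) - min(sses) <= 1e-8 * max(max(sses), 1e-30)

    def test_all_zero_rates_is_degenerate(self):
        points = [RatePoint(0.042, 1000.0, 1000.0, 0.0, 1.0) for _ in range(3)]
        with pytest.raises(DegenerateFitError) as err:
            fit_kinetics(points, order_fixed=1.0)
        assert err.value.result.model.k == 0.0

    def test_underdetermined_free_fit_is_an_error(self):
        points = ladder_points(KineticModel(k=0.06955, n=1.0))[:2]
        with pytest.raises(InsufficientDataError):
            fit_kinetics(points)


class TestConfidenceBand:
    def _result(self, se, dof):
        points = ladder_points(KineticModel(k=0.06955, n=1.0))
        result = fit_kinetics(points, order_fixed=1.0)
        result.se = se
        result.dof = dof
        from scipy import stats

        result.t_crit = float(stats.t.ppf(0.975, dof))
        return result

    def test_zero_se_collapses_to_fit(self):
        result = self._result(0.0, 10)
        band = confidence_band(result, 1000.0, [0.01, 0.042])
        assert (band["lo"] == band["fit"]).all()
        assert (band["hi"] == band["fit"]).all()

    def test_t_critical_small_and_large_dof(self):
        assert self._result(1.0, 5).t_crit == pytest.approx(2.571, abs=1e-3)
        band = confidence_band(self._result(1.0, 10_000), 1000.0, [0.042])
        half = float(band["hi"][0] - band["fit"][0])
        assert half == pytest.approx(1.96, abs=0.01)
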