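"""Solver correctness against closed forms and internal consistency checks.

The adder variant admits full closed forms (the added size is Erlang with
shape M and rate k/mu), which serve as the analytic oracle; the degradation
variant is cross-checked against an independent scipy LSODA integration.
"""
import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from divstages import DivisionModel, GrowthLaw
from divstages.master_equation import (
    ConsistencyError,
    ExtrapolationError,
    division_size_density,
    division_time_density,
    noise_summary,
    size_at_division_density,
    solve_stages,
    strategy_curves,
)

MU = math.log(2.0)


def _models_matrix():
    return [
        DivisionModel.adder(k=4 * MU, M=4),
        DivisionModel.degradation(k=4 * MU, M=8, gamma=MU),
        DivisionModel.power_law(k=2.0, M=8, lam=2.0),
        DivisionModel.commitment(k=4.0, M=8, s0=1.5, beta=6.0),
    ]


class TestSolveStages:
    @pytest.mark.parametrize("model", _models_matrix(), ids=lambda m: m.variant)
    def test_initial_condition_and_conservation(self, model, growth):
        st = solve_stages(model, growth, 1.0)
        assert st.P[0, 0] == pytest.approx(1.0)
        assert np.all(st.P[0, 1:] == 0.0)
        assert np.abs(st.P.sum(axis=1) - 1.0).max() < 1e-6

    @pytest.mark.parametrize("model", _models_matrix(), ids=lambda m: m.variant)
    def test_division_cdf_monotone_and_complete(self, model, growth):
        st = solve_stages(model, growth, 1.0)
        PM = st.P[:, -1]
        assert np.all(np.diff(PM) >= -1e-10)
        assert st.completion >= 1.0 - 1e-6

    def test_single_stage_adder_survival_closed_form(self, growth):
        # one inhomogeneous-exponential step: P_1(t) = 1 - exp(-(k s_b/mu)(e^{mu t}-1))
        k, s_b = 1.7, 0.8
        st = solve_stages(DivisionModel.adder(k=k, M=1), growth, s_b)
        expected = 1.0 - np.exp(-(k * s_b / growth.mu) * (np.exp(growth.mu * st.t_grid) - 1.0))
        assert np.abs(st.P[:, 1] - expected).max() < 1e-7

    def test_degradation_delays_absorption(self, growth):
        # back-steps can only delay the first passage to M
        k, M = 3.0, 6
        st0 = solve_stages(DivisionModel.degradation(k=k, M=M, gamma=0.0), growth, 1.0)
        st1 = solve_stages(DivisionModel.degradation(k=k, M=M, gamma=growth.mu), growth, 1.0)
        PM1 = np.interp(st0.t_grid, st1.t_grid, st1.P[:, -1])
        assert np.all(PM1 <= st0.P[:, -1] + 1e-8)

    def test_fast_kernel_matches_scipy_reference(self, growth):
        model = DivisionModel.degradation(k=4.0, M=10, gamma=2 * growth.mu)
        st_fast = solve_stages(model, growth, 0.9, method="fast")
        st_ode = solve_stages(model, growth, 0.9, method="ode")
        for m in (0, model.M // 2, model.M):
            fast = np.interp(st_ode.t_grid, st_fast.t_grid, st_fast.P[:, m])
            assert np.abs(fast - st_ode.P[:, m]).max() < 1e-5

    def test_analytic_matches_ode_for_pure_birth(self, growth):
        model = DivisionModel.power_law(k=2.0, M=6, lam=2.0)
        st_an = solve_stages(model, growth, 1.0, method="analytic")
        st_ode = solve_stages(model, growth, 1.0, method="ode")
        PM = np.interp(st_ode.t_grid, st_an.t_grid, st_an.P[:, -1])
        assert np.abs(PM - st_ode.P[:, -1]).max() < 1e-6

    def test_analytic_refused_for_degradation(self, growth):
        with pytest.raises(ValueError):
            solve_stages(DivisionModel.degradation(k=1.0, M=4, gamma=0.5), growth, 1.0, method="analytic")

    def test_incomplete_absorption_reports_mass(self, growth):
        from divstages.master_equation import IncompleteAbsorptionError

        with pytest.raises(IncompleteAbsorptionError) as err:
            solve_stages(DivisionModel.adder(k=0.001, M=20), growth, 1.0, max_doublings=1.0)
        assert 0.0 <= err.value.mass < 1.0


class TestDivisionTimeDensity:
    def test_starts_at_zero_for_multistage(self, growth):
        st = solve_stages(DivisionModel.adder(k=4 * MU, M=4), growth, 1.0)
        dtd = division_time_density(st)
        assert dtd.rho_tau[0] == 0.0

    def test_single_stage_hazard_at_birth_and_closed_form(self, growth):
        k, s_b = 2.0, 1.3
        st = solve_stages(DivisionModel.adder(k=k, M=1), growth, s_b)
        dtd = division_time_density(st)
        assert dtd.rho_tau[0] == pytest.approx(k * s_b, rel=1e-12)
        mu = growth.mu
        t = dtd.t_grid
        expected = k * s_b * np.exp(mu * t) * np.exp(-(k * s_b / mu) * (np.exp(mu * t) - 1.0))
        assert np.abs(dtd.rho_tau - expected).max() < 1e-7

    @pytest.mark.parametrize("model", _models_matrix(), ids=lambda m: m.variant)
    def test_cumulative_density_reproduces_cdf(self, model, growth):
        st = solve_stages(model, growth, 1.0)
        dtd = division_time_density(st)
        assert np.abs(dtd.cdf() - st.P[:, -1]).max() < 1e-4

    def test_model_mismatch_rejected(self, growth):
        st = solve_stages(DivisionModel.adder(k=1.0, M=2), growth, 1.0)
        other = DivisionModel.adder(k=2.0, M=2)
        with pytest.raises(ConsistencyError):
            division_time_density(st, model=other)


class TestSizeAtDivisionDensity:
    def test_single_stage_adder_is_exponential_added_size(self, growth):
        k, s_b = 3.0, 0.7
        dens = division_size_density(DivisionModel.adder(k=k, M=1), growth, s_b)
        rate = k / growth.mu
        expected = rate * np.exp(-rate * (dens.s_grid - s_b))
        assert np.abs(dens.rho_sd - expected).max() < 1e-6

    def test_adder_added_size_density_is_birth_size_invariant(self, growth):
        model = DivisionModel.adder(k=4 * MU, M=4)
        delta = np.linspace(1e-3, 4.0, 500)
        curves = []
        for s_b in (0.6, 1.0, 1.6):
            dtd = division_time_density(solve_stages(model, growth, s_b))
            dens = size_at_division_density(dtd, s_grid=s_b + delta)
            curves.append(dens.rho_sd)
        assert np.abs(curves[0] - curves[1]).max() < 1e-3
        assert np.abs(curves[2] - curves[1]).max() < 1e-3

    @pytest.mark.parametrize("M", [1, 2, 4, 10, 25])
    def test_adder_density_is_erlang(self, M, growth):
        # shape-M Erlang in the added size with rate k/mu
        k = M * MU
        dens = division_size_density(DivisionModel.adder(k=k, M=M), growth, 1.0)
        expected = gamma_dist.pdf(dens.s_grid - 1.0, a=M, scale=growth.mu / k)
        assert np.abs(dens.rho_sd - expected).max() < 1e-3

    def test_support_below_birth_size_is_zero(self, growth):
        dtd = division_time_density(solve_stages(DivisionModel.adder(k=2.0, M=3), growth, 1.0))
        dens = size_at_division_density(dtd, s_grid=np.array([0.5, 0.9, 1.0, 1.5]))
        assert dens.rho_sd[0] == 0.0 and dens.rho_sd[1] == 0.0

    def test_beyond_horizon_raises(self, growth):
        dtd = division_time_density(solve_stages(DivisionModel.adder(k=2.0, M=3), growth, 1.0))
        s_max = math.exp(growth.mu * dtd.t_grid[-1])
        with pytest.raises(ExtrapolationError):
            size_at_division_density(dtd, s_grid=np.array([1.0, 2.0 * s_max]))


class TestMomentsAndNoise:
    def test_zeroth_moment_is_one(self, growth):
        dens = division_size_density(DivisionModel.adder(k=4 * MU, M=4), growth, 1.0)
        assert dens.moment(0.0) == pytest.approx(1.0, abs=1e-9)

    def test_density_exports_as_two_column_table(self, growth):
        dens = division_size_density(DivisionModel.adder(k=4 * MU, M=4), growth, 1.0)
        frame = dens.to_frame()
        assert list(frame.columns) == ["s", "rho_sd"]
        assert len(frame) == dens.s_grid.size

    @pytest.mark.parametrize("M", [1, 2, 4, 10, 25])
    def test_adder_mean_added_and_cv2_closed_forms(self, M, growth):
        # <Delta> = M mu / k and CV2 = 1/M
        k = M * MU
        ns = noise_summary(division_size_density(DivisionModel.adder(k=k, M=M), growth, 1.0))
        assert ns.mean_added == pytest.approx(M * growth.mu / k, rel=1e-3)
        assert ns.cv2 == pytest.approx(1.0 / M, rel=1e-3)

    def test_single_stage_adder_variance(self, growth):
        k = 2.5
        ns = noise_summary(division_size_density(DivisionModel.adder(k=k, M=1), growth, 1.0))
        assert ns.var_added == pytest.approx((growth.mu / k) ** 2, rel=1e-3)

    def test_power_law_lowers_noise_at_matched_mean(self, growth):
        # at matched M and matched <Delta>, superlinear accumulation narrows
        # the added-size distribution
        from divstages import calibrate_k

        M = 6
        k_a = calibrate_k(DivisionModel.adder(1.0, M), growth, 2.0)
        k_p = calibrate_k(DivisionModel.power_law(1.0, M, lam=2.0), growth, 2.0)
        cv_a = noise_summary(division_size_density(DivisionModel.adder(k_a, M), growth, 1.0)).cv2
        cv_p = noise_summary(division_size_density(DivisionModel.power_law(k_p, M, lam=2.0), growth, 1.0)).cv2
        assert cv_p < cv_a


class TestStrategyCurves:
    def test_adder_strategy_is_flat(self, growth):
        curves = strategy_curves(DivisionModel.adder(k=4 * MU, M=4), growth, np.linspace(0.5, 1.5, 5))
        assert np.ptp(curves["mean_added"]) < 1e-3
        assert np.ptp(curves["cv2"]) < 1e-3

    def test_degradation_strategy_decreases_with_birth_size(self, growth):
        model = DivisionModel.degradation(k=6.0, M=8, gamma=growth.mu)
        curves = strategy_curves(model, growth, np.linspace(0.5, 1.5, 5))
        assert np.all(np.diff(curves["mean_added"]) < 0)

    def test_commitment_deep_regime_is_a_sizer(self, growth):
        # s0 far above the birth sizes: division targets a set size, so the
        # strategy slope is -1
        from divstages import calibrate_k

        model = DivisionModel.commitment(k=1.0, M=10, s0=5.0, beta=100.0)
        model = model.with_k(calibrate_k(model, growth, 2.0))
        curves = strategy_curves(model, growth, np.array([0.5, 1.0, 1.5]))
        slope = np.polyfit(curves["s_b"], curves["mean_added"], 1)[0]
        assert slope == pytest.approx(-1.0, rel=0.02)
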