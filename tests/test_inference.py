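"""Calibration, likelihood and fitting: oracles and recovery properties."""
import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import erlang

from divstages import (
    Dataset,
    DivisionModel,
    GrowthLaw,
    SearchConfig,
    calibrate_k,
    compare_models,
    fit_model,
    log_likelihood,
)
from divstages.inference import CalibrationError

MU = math.log(2.0)


class TestCalibrateK:
    def test_adder_closed_form(self, growth):
        # invert <Delta> = M mu / k with target <Delta> = 1
        k = calibrate_k(DivisionModel.adder(k=1.0, M=4), growth, 2.0)
        assert k == pytest.approx(4 * MU, rel=1e-5)

    def test_fixed_point_of_the_constraint(self, growth):
        k0 = 3.1
        target = 1.0 + 6 * growth.mu / k0
        k = calibrate_k(DivisionModel.adder(k=1.0, M=6), growth, target)
        assert k == pytest.approx(k0, rel=1e-5)

    def test_power_law_against_quadrature_oracle(self, growth):
        # independent oracle: brute-force quadrature of the first-passage
        # density in the size coordinate, root-finding k on a fine grid
        M, lam, target = 4, 2.0, 2.0
        s = np.linspace(1.0, 40.0, 400_000)

        def mean_sd(k):
            Lam = (k / growth.mu) * (s**lam - 1.0) / lam
            rho = (k / growth.mu) * s ** (lam - 1.0) * Lam ** (M - 1) * np.exp(-Lam) / math.factorial(M - 1)
            return np.trapezoid(s * rho, s) / np.trapezoid(rho, s)

        k_oracle = brentq(lambda k: mean_sd(k) - target, 0.1, 50.0, xtol=1e-10)
        k = calibrate_k(DivisionModel.power_law(k=1.0, M=M, lam=lam), growth, target)
        assert k == pytest.approx(k_oracle, rel=1e-3)

    def test_degradation_mode_round_trip(self, growth):
        from divstages.master_equation import division_size_density

        model = DivisionModel.degradation(k=1.0, M=6, gamma=growth.mu)
        k = calibrate_k(model, growth, 2.0)
        mean = division_size_density(model.with_k(k), growth, 1.0).moment(1.0)
        assert mean == pytest.approx(2.0, rel=1e-5)

    def test_rejects_target_below_birth_size(self, growth):
        with pytest.raises(CalibrationError):
            calibrate_k(DivisionModel.adder(k=1.0, M=4), growth, 0.9)

    def test_population_mode_close_to_conditional(self, growth, benchmark_suite_seed0):
        # the two readings of the mean constraint differ only at second order
        # in the birth-size spread
        data = benchmark_suite_seed0["adder"]
        shape = DivisionModel.adder(k=1.0, M=10)
        k_cond = calibrate_k(shape, growth, data.mean_sd)
        k_pop = calibrate_k(shape, growth, data.mean_sd, mode="population", data=data)
        assert k_pop == pytest.approx(k_cond, rel=0.05)


class TestLogLikelihood:
    def test_single_record_matches_erlang_closed_form(self, growth):
        M, k, d = 5, 4.0, 0.8
        data = Dataset(s_b=np.array([1.0]), s_d=np.array([1.0 + d]))
        model = DivisionModel.adder(k=k, M=M)
        ll = log_likelihood(data, model, growth)
        assert ll == pytest.approx(erlang.logpdf(d, a=M, scale=growth.mu / k), rel=1e-9)

    def test_grid_and_pointwise_paths_agree(self, growth, benchmark_suite_seed0):
        data = benchmark_suite_seed0["adder"]
        model = DivisionModel.adder(k=calibrate_k(DivisionModel.adder(1.0, 10), growth, data.mean_sd), M=10)
        ll_pw = log_likelihood(data, model, growth, method="pointwise")
        ll_gr = log_likelihood(data, model, growth, method="grid")
        assert ll_gr == pytest.approx(ll_pw, abs=0.05)

    def test_true_model_beats_misspecified_on_sizer_data(self, growth, benchmark_suite_seed0):
        data = benchmark_suite_seed0["power_law_strong"]
        truth = DivisionModel.from_config(data.meta["ground_truth"])
        adder = DivisionModel.adder(k=calibrate_k(DivisionModel.adder(1.0, truth.M), growth, data.mean_sd), M=truth.M)
        assert log_likelihood(data, truth, growth) > log_likelihood(data, adder, growth)

    def test_pointwise_refused_for_degradation(self, growth):
        data = Dataset(s_b=np.array([1.0]), s_d=np.array([2.0]))
        model = DivisionModel.degradation(k=1.0, M=2, gamma=0.5)
        with pytest.raises(ValueError):
            log_likelihood(data, model, growth, method="pointwise")


class TestFitModel:
    def test_adder_stage_count_recovery(self, growth, benchmark_suite_seed0):
        fit = fit_model(benchmark_suite_seed0["adder"], "adder", growth)
        assert fit.model.M in (9, 10, 11)  # truth M = 10
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.logL, rel=1e-12)
        assert fit.n_params == 1

    def test_degradation_rate_recovery(self, growth):
        from divstages import ConditionSpec, generate_condition

        truth = DivisionModel.degradation(k=1.0, M=15, gamma=MU)
        truth = truth.with_k(calibrate_k(truth, growth, 2.0))
        data = generate_condition(ConditionSpec(label="deg", model=truth, n_cycles=5000, seed=17))
        fit = fit_model(data, "degradation", growth)
        assert fit.model.gamma == pytest.approx(MU, rel=0.25)

    def test_power_law_pinned_to_one_reproduces_adder(self, growth, benchmark_suite_seed0):
        data = benchmark_suite_seed0["adder"]
        fit_a = fit_model(data, "adder", growth)
        fit_p = fit_model(data, "power_law", growth, SearchConfig(fixed={"lam": 1.0}))
        assert fit_p.logL == pytest.approx(fit_a.logL, abs=1e-6)
        assert fit_p.model.M == fit_a.model.M


class TestCompareModels:
    def test_relative_likelihood_and_ranking_identities(self, growth):
        from divstages import ConditionSpec, generate_condition

        model = DivisionModel.adder(k=6 * MU, M=6)
        data = generate_condition(ConditionSpec(label="small", model=model, n_cycles=600, seed=23))
        table = compare_models(data, growth, variants=("adder", "power_law"))
        assert table.best.rel_likelihood == 1.0
        for f in table.fits:
            assert 0.0 < f.rel_likelihood <= 1.0
            assert f.rel_likelihood == pytest.approx(math.exp((table.best.aic - f.aic) / 2.0), rel=1e-9)
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.logL, rel=1e-12)
        # nesting: the power law contains the adder, so its maximized logL
        # cannot fall below the adder's by more than optimizer tolerance
        by_variant = {f.variant: f for f in table.fits}
        assert by_variant["power_law"].logL >= by_variant["adder"].logL - 1e-6
        for f in table.fits:
            assert f.discarded == (f.rel_likelihood < 0.05)
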