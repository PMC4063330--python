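"""Rate-function derivation, evaluation, and ODE-consistency checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from scalartime import (
    DegenerateNoiseError,
    Direction,
    DomainError,
    NoiseModel,
    ParameterError,
    RateFunction,
    ScalarLaw,
    TabulatedRate,
    derive_proportional_rate,
    derive_rate_function,
    ode_residual,
    ode_residual_tabulated,
    solve_rate_numeric,
)


class TestDerivation:
    @pytest.mark.parametrize(
        "rho, n_expected",
        [(0.5, 2.0), (0.0, 1.0), (0.25, 4.0 / 3.0), (0.75, 4.0)],
    )
    def test_exponent_identity(self, rho, n_expected):
        rf = derive_rate_function(
            NoiseModel(1.0, rho), ScalarLaw.linear(0.1), tau=0.1, t0=5.0,
            direction="increasing",
        )
        assert rf.n == pytest.approx(n_expected, abs=1e-15)

    def test_amplitude_worked_example(self, example_rate):
        # K = (1/tau) (beta (1-rho)/alpha)^n = 10 * (0.5/0.2)^2 = 62.5 spikes/s
        assert example_rate.K == pytest.approx(62.5)
        assert example_rate.n == 2.0
        assert example_rate.direction is Direction.DECREASING

    @given(
        beta=hst.floats(0.2, 5.0),
        rho=hst.floats(0.0, 0.9),
        alpha=hst.floats(0.01, 0.5),
        tau=hst.floats(0.01, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_parameter_identities_sweep(self, beta, rho, alpha, tau):
        rf = derive_rate_function(
            NoiseModel(beta, rho), ScalarLaw.linear(alpha), tau=tau, t0=3.0,
            direction="decreasing",
        )
        n = 1.0 / (1.0 - rho)
        assert rf.n == pytest.approx(n, rel=1e-14)
        assert rf.K == pytest.approx((1.0 / tau) * (beta * (1 - rho) / alpha) ** n,
                                     rel=1e-12)

    def test_proportional_noise_rejected(self):
        with pytest.raises(DegenerateNoiseError):
            derive_rate_function(
                NoiseModel(1.0, 1.0), ScalarLaw.linear(0.1), tau=0.1, t0=5.0,
                direction="increasing",
            )

    @pytest.mark.parametrize("bad", [dict(alpha=-0.1), dict(tau=0.0), dict(t0=-1.0)])
    def test_invalid_parameters(self, bad):
        kw = dict(alpha=0.1, tau=0.1, t0=5.0)
        kw.update(bad)
        with pytest.raises(ParameterError):
            derive_rate_function(
                NoiseModel(1.0, 0.5), ScalarLaw.linear(kw["alpha"]),
                tau=kw["tau"], t0=kw["t0"], direction="increasing",
            )


class TestEvaluation:
    def test_zero_at_t0(self, example_rate):
        assert example_rate(10.0) == 0.0

    def test_unit_log_point(self, example_rate):
        # -log((t0/e)/t0) = 1, so r = K
        assert example_rate(10.0 / math.e) == pytest.approx(62.5, rel=1e-12)

    def test_worked_value_at_one_second(self, example_rate):
        # K (log 10)^2, cross-checked by quadrature of the governing ODE
        assert example_rate(1.0) == pytest.approx(62.5 * math.log(10.0) ** 2,
                                                  rel=1e-12)
        assert example_rate(1.0) == pytest.approx(331.3686, abs=1e-4)

    def test_domain_error_beyond_t0(self, example_rate):
        with pytest.raises(DomainError):
            example_rate(10.5)
        rf_inc = RateFunction(K=10.0, n=2.0, t0=1.0, direction="increasing", tau=0.1)
        with pytest.raises(DomainError):
            rf_inc(0.5)

    @given(t1=hst.floats(0.2, 9.9), t2=hst.floats(0.2, 9.9))
    @settings(max_examples=50, deadline=None)
    def test_strict_monotonicity(self, example_rate, t1, t2):
        if t1 == t2:
            return
        lo, hi = min(t1, t2), max(t1, t2)
        assert example_rate(lo) > example_rate(hi)  # decreasing branch

    def test_linearized_weber_consistency(self, example_rate):
        # sigma_R(t)/|tau r'(t)| must equal alpha*t exactly for the derived form
        noise, alpha = NoiseModel(1.0, 0.5), 0.2
        for t in (0.7, 2.0, 5.0, 9.0):
            sigma_R = noise.sigma_R(example_rate.tau * example_rate(t))
            slope = abs(example_rate.derivative(t)) * example_rate.tau
            assert sigma_R / slope == pytest.approx(alpha * t, rel=1e-12)


class TestWindowCount:
    def test_approx_zero_at_t0(self, example_rate):
        assert example_rate.mean_window_count(10.0 - 0.05, "approx") == pytest.approx(
            0.1 * example_rate(9.95)
        )

    def test_approx_value(self, example_rate):
        assert example_rate.mean_window_count(10.0 / math.e, "approx") == pytest.approx(
            6.25, rel=1e-12
        )

    def test_exact_close_to_approx(self, example_rate):
        t = np.linspace(1.0, 9.0, 17)
        exact = example_rate.mean_window_count(t, "exact")
        approx = example_rate.mean_window_count(t, "approx")
        assert np.all(np.abs(exact - approx) / exact <= 0.01)

    def test_window_leaving_domain(self, example_rate):
        with pytest.raises(DomainError):
            example_rate.mean_window_count(9.99, "exact")  # window crosses t0


class TestOdeResidual:
    @pytest.mark.parametrize("rho", [0.0, 0.25, 0.5, 0.75])
    @pytest.mark.parametrize("direction", ["increasing", "decreasing"])
    def test_derived_solution_satisfies_ode(self, rho, direction):
        noise, law = NoiseModel(1.3, rho), ScalarLaw.linear(0.08)
        rf = derive_rate_function(noise, law, tau=0.1, t0=2.0, direction=direction)
        t = (np.geomspace(2.02, 20.0, 100) if direction == "increasing"
             else np.geomspace(0.2, 1.98, 100))
        res = ode_residual(rf, noise, law, t)
        assert np.max(np.abs(res)) <= 1e-9

    def test_perturbed_amplitude_breaks_ode(self, example_rate):
        noise, law = NoiseModel(1.0, 0.5), ScalarLaw.linear(0.2)
        bad = RateFunction(K=example_rate.K * 1.1, n=2.0, t0=10.0,
                           direction="decreasing", tau=0.1)
        assert abs(ode_residual(bad, noise, law, 2.0)) > 1e-3

    def test_residual_undefined_at_t0(self, example_rate):
        with pytest.raises(DomainError):
            ode_residual(example_rate, NoiseModel(1.0, 0.5), ScalarLaw.linear(0.2),
                         10.0)


class TestProportionalRate:
    def test_linear_power_law(self):
        tab = derive_proportional_rate(
            NoiseModel(1.0, 1.0), ScalarLaw.linear(1.0), 1.0, 1.0, "increasing",
            grid=np.linspace(0.5, 4.0, 30),
        )
        assert tab(2.0) == pytest.approx(2.0, rel=1e-9)

    def test_decreasing_power_law_value(self):
        grid = np.linspace(0.5, 5.0, 46)  # contains t = 4.0 as a node
        tab = derive_proportional_rate(
            NoiseModel(1.0, 1.0), ScalarLaw.linear(0.5), 1.0, 10.0, "decreasing",
            grid=grid,
        )
        assert tab(4.0) == pytest.approx(10.0 * 4.0 ** (-2.0), rel=1e-9)

    def test_tabulated_solution_satisfies_ode(self):
        beta, alpha = 1.0, 0.5
        grid = np.geomspace(0.5, 5.0, 4000)  # dense: derivative via interpolant
        tab = derive_proportional_rate(
            NoiseModel(1.0, 1.0), ScalarLaw.linear(alpha), 1.0, 10.0, "decreasing",
            grid=grid,
        )
        res = ode_residual_tabulated(
            tab, lambda t, r: -(beta / alpha) * r / t, t=grid[5:-5]
        )
        assert np.max(np.abs(res)) <= 1e-6

    def test_requires_rho_one(self):
        with pytest.raises(ParameterError):
            derive_proportional_rate(NoiseModel(1.0, 0.5), ScalarLaw.linear(0.1),
                                     1.0, 1.0, "increasing")


class TestNumericSolver:
    def test_reproduces_closed_form(self, example_rate):
        grid = np.geomspace(0.5, 9.5, 200)
        tab = solve_rate_numeric(
            NoiseModel(1.0, 0.5), ScalarLaw.linear(0.2), tau=0.1,
            boundary=(2.0, float(example_rate(2.0))), direction="decreasing",
            grid=grid,
        )
        dev = np.abs(np.asarray(tab.rates) - example_rate(grid)) / example_rate(grid)
        assert np.max(dev) <= 1e-5

    def test_constant_noise_gives_logarithmic_solution(self):
        # sigma_R = c: dr/dt = c/(alpha tau t) -> r = (c/(alpha tau)) log(t/t0)
        c, alpha, tau, t0 = 2.0, 0.1, 0.1, 1.0
        grid = np.geomspace(1.5, 20.0, 100)
        tab = solve_rate_numeric(
            lambda R: c, ScalarLaw.linear(alpha), tau=tau,
            boundary=(grid[0], c / (alpha * tau) * math.log(grid[0] / t0)),
            direction="increasing", grid=grid,
        )
        expected = c / (alpha * tau) * np.log(grid / t0)
        assert np.max(np.abs(np.asarray(tab.rates) - expected) / expected) <= 1e-6

    def test_nonlinear_scaling_satisfies_generalized_ode(self):
        # sigma_t = 0.05 t^1.2 (tabulated), Poisson noise: residual is the oracle
        tgrid = np.geomspace(0.3, 12.0, 200)
        law = ScalarLaw.tabulated(tgrid, 0.05 * tgrid**1.2)
        tau = 0.1
        grid = np.geomspace(1.0, 10.0, 800)
        tab = solve_rate_numeric(
            NoiseModel(1.0, 0.5), law, tau=tau, boundary=(1.0, 500.0),
            direction="increasing", grid=grid,
        )

        def rhs(t, r):
            return math.sqrt(tau * r) / (tau * float(law.sigma_t(t)))

        res = ode_residual_tabulated(tab, rhs, t=grid[10:-10])
        assert np.max(np.abs(res)) <= 1e-5

    def test_boundary_outside_grid_rejected(self):
        with pytest.raises(ParameterError):
            solve_rate_numeric(
                NoiseModel(1.0, 0.5), ScalarLaw.linear(0.1), tau=0.1,
                boundary=(20.0, 5.0), direction="increasing",
                grid=np.linspace(1.0, 10.0, 10),
            )


class TestTabulatedRate:
    def test_monotonicity_enforced(self):
        with pytest.raises(ParameterError):
            TabulatedRate((1.0, 2.0, 3.0), (1.0, 3.0, 2.0), "increasing")

    def test_csv_round_trip(self, tmp_path):
        tab = TabulatedRate((1.0, 2.0, 4.0), (8.0, 4.0, 1.0), "decreasing")
        path = tmp_path / "rate.csv"
        tab.to_frame().to_csv(path, index=False)
        import pandas as pd

        back = TabulatedRate.from_frame(pd.read_csv(path), "decreasing")
        assert back.times == tab.times and back.rates == tab.rates
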