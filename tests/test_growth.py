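"""Within-generation growth ODEs: fixed points, logistic limit, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coinvade as cv
from coinvade.growth import (_rk4, _rk4_numpy, growth_rhs_arrays,
                             integrate_growth_arrays)
from coinvade.params import GrowthParams, ParameterError, SolverSettings


class TestGrowthRHS:
    def test_extinct_state_is_fixed(self, defaults):
        assert cv.growth_rhs(cv.PointState(0, 0, 0), defaults) == (0.0, 0.0, 0.0)

    def test_partner_carrying_capacity_is_equilibrium(self, defaults):
        # r_P/d_P = 3: alone, P sits at its logistic carrying capacity
        dP, dF1, dF2 = cv.growth_rhs(cv.PointState(3.0, 0, 0), defaults)
        assert dP == pytest.approx(0.0, abs=1e-14)
        assert dF1 == dF2 == 0.0

    def test_dependent_competitor_equilibrium_without_partner(self, defaults):
        # F1 alone: (1-delta)r/d = 0.1*0.3/0.1 = 0.3
        _, dF1, _ = cv.growth_rhs(cv.PointState(0, 0.3, 0), defaults)
        assert dF1 == pytest.approx(0.0, abs=1e-14)

    def test_negative_density_rejected(self, defaults):
        with pytest.raises(ParameterError):
            cv.PointState(-0.1, 0, 0)

    @given(st.floats(0, 5), st.floats(0, 5), st.floats(0, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_zero_component_has_zero_derivative(self, P, F1, F2):
        p = GrowthParams(tau_12=0.2, tau_21=0.1)
        d = growth_rhs_arrays(np.array([0.0, P]), np.array([F1, 0.0]),
                              np.array([F2, F2]), p)
        assert d[0][0] == 0.0 and d[1][1] == 0.0


class TestIntegrateGrowth:
    def test_all_zero_field_stays_zero(self, defaults):
        out = integrate_growth_arrays(np.zeros(8), np.zeros(8), np.zeros(8), defaults)
        assert all(np.all(a == 0) for a in out)

    def test_uniform_carrying_capacity_unchanged(self, defaults):
        P = np.full(16, 3.0)
        out = integrate_growth_arrays(P, np.zeros(16), np.zeros(16), defaults)
        assert np.allclose(out[0], 3.0, atol=1e-8)

    def test_repeated_integration_converges_to_logistic_limit(self, defaults):
        # closed form: K/(1+(K/P0-1)e^{-rt}) with K=3, r=0.3
        P = np.array([0.1])
        F = np.zeros(1)
        for _ in range(200):
            P, _, _ = integrate_growth_arrays(P, F, F, defaults)
        K, r, t = 3.0, 0.3, 200.0
        exact = K / (1 + (K / 0.1 - 1) * np.exp(-r * t))
        assert P[0] == pytest.approx(exact, abs=1e-3)

    def test_logistic_closed_form_along_trajectory(self):
        # with all interactions off, each species follows the logistic solution
        p = GrowthParams(alpha_P_F1=0, alpha_P_F2=0, alpha_F1_P=0, alpha_F2_P=0,
                         delta_F1=0, delta_F2=0)
        P = np.array([0.1])
        for step_i in range(1, 31):
            P, _, _ = integrate_growth_arrays(P, np.zeros(1), np.zeros(1), p)
            t = step_i * p.T_growth
            exact = 3.0 / (1 + (3.0 / 0.1 - 1) * np.exp(-0.3 * t))
            assert P[0] == pytest.approx(exact, rel=1e-7)

    def test_decoupling_from_partner_when_independent(self, defaults):
        # delta=0 for both competitors: F dynamics ignore P entirely
        p = GrowthParams(delta_F1=0.0, delta_F2=0.0, tau_12=0.1, tau_21=0.2)
        F1 = np.array([0.5])
        F2 = np.array([0.8])
        a = integrate_growth_arrays(np.array([0.0]), F1, F2, p)
        b = integrate_growth_arrays(np.array([2.7]), F1, F2, p)
        assert a[1][0] == pytest.approx(b[1][0], rel=1e-12)
        assert a[2][0] == pytest.approx(b[2][0], rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_nonnegativity_preserved(self, seed):
        rng = np.random.default_rng(seed)
        p = GrowthParams(tau_12=rng.uniform(0, 0.4), tau_21=rng.uniform(0, 0.4))
        P, F1, F2 = rng.uniform(0, 5, (3, 32))
        out = integrate_growth_arrays(P, F1, F2, p)
        assert all(np.all(a >= 0) for a in out)

    def test_adaptive_solver_agrees_with_rk4(self, defaults):
        rng = np.random.default_rng(7)
        p = GrowthParams(tau_12=0.2, tau_21=0.15)
        P, F1, F2 = rng.uniform(0, 4, (3, 16))
        fixed = integrate_growth_arrays(P, F1, F2, p, SolverSettings(n_steps=200))
        adapt = integrate_growth_arrays(P, F1, F2, p,
                                        SolverSettings(method="adaptive",
                                                       rtol=1e-10, atol=1e-12))
        for a, b in zip(fixed, adapt):
            assert np.allclose(a, b, rtol=1e-6)

    def test_compiled_rk4_matches_numpy_reference(self):
        rng = np.random.default_rng(3)
        p = GrowthParams(tau_12=0.3, tau_21=0.1)
        P, F1, F2 = rng.uniform(0, 4, (3, 64))
        for a, b in zip(_rk4(P, F1, F2, p, 20), _rk4_numpy(P, F1, F2, p, 20)):
            assert np.allclose(a, b, rtol=1e-13)


class TestLowDensityGrowthExponent:
    def test_partner_alone_reduces_to_intrinsic_rate(self, defaults):
        assert cv.low_density_growth_exponent(defaults, "P") == pytest.approx(0.3)

    def test_low_dependence_competitor_without_partner(self, defaults):
        # (1-0.1)*0.3 = 0.27
        assert cv.low_density_growth_exponent(defaults, "F2") == pytest.approx(0.27)

    def test_fully_dependent_competitor_without_partner_is_zero(self):
        p = GrowthParams(delta_F1=1.0)
        assert cv.low_density_growth_exponent(p, "F1") == pytest.approx(0.0)

    def test_partner_background_adds_saturating_benefit(self, defaults):
        # F1 with P at 3: 0.03 + 0.9*0.5*3/3.3
        got = cv.low_density_growth_exponent(defaults, "F1", partner_density=3.0)
        assert got == pytest.approx(0.03 + 0.9 * 0.5 * 3 / 3.3)

    def test_unknown_species_rejected(self, defaults):
        with pytest.raises(ParameterError):
            cv.low_density_growth_exponent(defaults, "F3")


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"r_P": -0.1}, {"delta_F1": 1.2}, {"tau_12": 0.5}, {"T_growth": 0.0},
        {"tau_21": -0.01},
    ])
    def test_invalid_growth_params_rejected(self, kw):
        with pytest.raises(ParameterError):
            GrowthParams(**kw)

    def test_T_growth_is_configurable_below_one(self):
        p = GrowthParams(T_growth=0.5)
        assert cv.low_density_growth_exponent(p, "P") == pytest.approx(0.15)
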