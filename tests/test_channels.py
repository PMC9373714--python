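"""Boltzmann gating, ohmic/partial/GHK currents and the calcium pool."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from dopanet.channels import (CalciumPool, ChannelSpec, GateSpec, GHKParams,
                              TauTable, ca_permeability, ca_pool_derivative,
                              gate_derivative, gate_tau, ghk_current,
                              ohmic_current, partial_inactivation_current,
                              steady_state_gate)
from dopanet.errors import InvalidStateError, ParameterError, WrongModeError

ACT = GateSpec(power=1, v_half=-40.0, slope=-6.0, tau=2.0)
INACT = GateSpec(power=1, v_half=-60.0, slope=7.0, tau=10.0, role="inactivation")


class TestGates:
    def test_midpoint_is_half(self):
        for slope in (-12.0, -3.0, 4.0, 9.0):
            g = GateSpec(power=1, v_half=-35.0, slope=slope, tau=1.0)
            assert steady_state_gate(-35.0, g) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert steady_state_gate(-500.0, ACT) == pytest.approx(0.0, abs=1e-12)
        assert steady_state_gate(+500.0, ACT) == pytest.approx(1.0, abs=1e-12)
        # inactivation gates (positive slope) saturate the other way round
        assert steady_state_gate(-500.0, INACT) == pytest.approx(1.0, abs=1e-12)

    def test_one_slope_above_midpoint(self):
        # v = v_half + slope gives exactly 1/(1+e)
        g = GateSpec(power=2, v_half=-50.0, slope=-5.0, tau=1.0)
        assert steady_state_gate(-55.0, g) == pytest.approx(1.0 / (1.0 + math.e))

    def test_zero_slope_rejected(self):
        with pytest.raises(ParameterError):
            GateSpec(power=1, v_half=-40.0, slope=0.0, tau=1.0)

    @settings(derandomize=True, max_examples=50)
    @given(v1=st.floats(-120, 60), v2=st.floats(-120, 60))
    def test_strict_monotonicity(self, v1, v2):
        if abs(v1 - v2) < 1e-6:
            return
        lo, hi = sorted((v1, v2))
        # negative slope: increasing in v; positive slope: decreasing
        assert steady_state_gate(lo, ACT) < steady_state_gate(hi, ACT)
        assert steady_state_gate(lo, INACT) > steady_state_gate(hi, INACT)

    def test_derivative_fixed_point_and_forced_value(self):
        v = -47.3
        m_inf = steady_state_gate(v, ACT)
        assert gate_derivative(m_inf, v, ACT) == pytest.approx(0.0, abs=1e-14)
        g = GateSpec(power=1, v_half=0.0, slope=-1e-6, tau=2.0)
        assert gate_derivative(0.0, 50.0, g) == pytest.approx(0.5, rel=1e-6)

    def test_voltage_clamp_relaxation_matches_closed_form(self):
        v = -30.0
        m_inf, tau = steady_state_gate(v, ACT), gate_tau(v, ACT)
        dt, n = 0.02, 500
        m = 0.0
        from dopanet.simulate import rk_step
        for _ in range(n):
            m = rk_step(np.array([m]), lambda y: gate_derivative(y, v, ACT), dt)[0]
        expected = m_inf * (1.0 - math.exp(-n * dt / tau))
        assert m == pytest.approx(expected, rel=1e-6)

    def test_tau_table_interpolates_and_clips(self):
        tab = TauTable(v=(-80.0, -40.0, 0.0), tau=(10.0, 2.0, 1.0))
        g = GateSpec(power=1, v_half=-40.0, slope=-6.0, tau=tab)
        assert gate_tau(-60.0, g) == pytest.approx(6.0)
        assert gate_tau(-200.0, g) == pytest.approx(10.0)  # clipped
        with pytest.raises(ParameterError):
            TauTable(v=(-80.0, -40.0), tau=(1.0, -2.0))


OHMIC = ChannelSpec(name="K", g_max=1.0, mode="ohmic", e_rev=-90.0,
                    activation=GateSpec(power=2, v_half=-30, slope=-9, tau=1.0))


class TestOhmicAndPartial:
    def test_zero_at_reversal_and_closed_gate(self):
        assert ohmic_current(OHMIC, 0.7, 1.0, -90.0) == pytest.approx(0.0)
        assert ohmic_current(OHMIC, 0.0, 1.0, 0.0) == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        # g=1, m=0.5, x=2, y=0, v-e = 10 -> 2.5
        spec = ChannelSpec(name="K", g_max=1.0, mode="ohmic", e_rev=0.0,
                           activation=GateSpec(power=2, v_half=-30, slope=-9, tau=1.0))
        assert ohmic_current(spec, 0.5, 1.0, 10.0) == pytest.approx(2.5)

    def test_linear_in_driving_force_and_sign_flip(self):
        lo = ohmic_current(OHMIC, 0.5, 1.0, -100.0)
        hi = ohmic_current(OHMIC, 0.5, 1.0, -80.0)
        assert lo == pytest.approx(-hi)

    def test_wrong_mode_rejected(self):
        ghk_spec = ChannelSpec(name="Ca", g_max=1e-6, mode="ghk", ghk=GHKParams(),
                               activation=GateSpec(power=2, v_half=-10, slope=-7, tau=1.0))
        with pytest.raises(WrongModeError):
            ohmic_current(ghk_spec, 0.5, 1.0, 0.0)
        with pytest.raises(WrongModeError):
            partial_inactivation_current(OHMIC, 0.5, 1.0, 0.0)

    @pytest.mark.parametrize("m,h,v", [(0.3, 0.8, -50.0), (1.0, 0.1, 20.0)])
    def test_partial_reduces_to_ohmic_at_a_one(self, m, h, v):
        base = dict(name="KAs", g_max=2.0, e_rev=-90.0,
                    activation=GateSpec(power=2, v_half=-26, slope=-13, tau=5.0),
                    inactivation=GateSpec(power=1, v_half=-79, slope=10, tau=900.0,
                                          role="inactivation"))
        part = ChannelSpec(mode="partial", partial_fraction=1.0, **base)
        ohm = ChannelSpec(mode="ohmic", **base)
        assert partial_inactivation_current(part, m, h, v) == \
            pytest.approx(ohmic_current(ohm, m, h, v))

    def test_partial_fraction_scales_residual_term(self):
        base = dict(name="KAs", g_max=2.0, e_rev=-90.0,
                    activation=GateSpec(power=2, v_half=-26, slope=-13, tau=5.0))
        a_zero = ChannelSpec(mode="partial", partial_fraction=0.0, **base)
        m, v = 0.6, -40.0
        # the gating factor is linear in a at fixed h: (a*h - (1-a))
        for h in (0.0, 0.4, 1.0):
            for a in (0.25, 0.5, 0.9):
                spec = ChannelSpec(mode="partial", partial_fraction=a, **base)
                expected = 2.0 * m ** 2 * (a * h - (1.0 - a)) * (v + 90.0)
                assert partial_inactivation_current(spec, m, h, v) == \
                    pytest.approx(expected)
        # a = 0: the current flips sign regardless of h
        expected = -2.0 * m ** 2 * (v - (-90.0))
        for h in (0.0, 0.4, 1.0):
            assert partial_inactivation_current(a_zero, m, h, v) == pytest.approx(expected)

    def test_partial_fraction_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            ChannelSpec(name="KAs", g_max=1.0, mode="partial", e_rev=-90.0,
                        partial_fraction=1.5)


class TestGHK:
    params = GHKParams(ca_out=5.0)

    def test_zero_at_symmetric_concentrations(self):
        assert ghk_current(1e-5, 0.0, 5.0, self.params) == pytest.approx(0.0, abs=1e-12)

    def test_zero_voltage_limit_is_lhopital(self):
        p, ca_in = 2e-6, 0.001
        expected = p * 2 * self.params.faraday * (ca_in - self.params.ca_out)
        got = ghk_current(p, 0.0, ca_in, self.params)
        assert got == pytest.approx(expected)
        assert got < 0  # inward for ca_in << ca_out

    def test_series_branch_brackets_and_matches_direct(self):
        p, ca_in = 1e-6, 0.001
        at0 = ghk_current(p, 0.0, ca_in, self.params)
        below = ghk_current(p, -0.1, ca_in, self.params)
        above = ghk_current(p, +0.1, ca_in, self.params)
        assert min(below, above) <= at0 <= max(below, above)
        # continuity across the |zFV/RT| = 1e-4 switch point
        v_switch = 1e-4 / self.params.xi_per_volt * 1e3  # mV
        for v in (v_switch * 0.999, v_switch * 1.001):
            series = ghk_current(p, v, ca_in, self.params)
        assert abs(series - ghk_current(p, v_switch, ca_in, self.params)) \
            <= 1e-6 * abs(series)

    def test_continuity_on_a_voltage_grid(self):
        v = np.linspace(-1.0, 1.0, 20001)
        i = ghk_current(1e-6, v, 0.001, self.params)
        assert np.all(np.isfinite(i))
        assert np.max(np.abs(np.diff(i))) < 1e-3 * (np.max(i) - np.min(i) + 1e-30) * 100

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidStateError):
            ghk_current(1e-6, -20.0, 0.0, self.params)

    def test_permeability_product(self):
        assert ca_permeability(3.0, 1.0, 2, 1.0, 1) == pytest.approx(3.0)
        assert ca_permeability(3.0, 0.0, 1) == pytest.approx(0.0)
        assert ca_permeability(2.0, 0.5, 2, 1.0, 0) == pytest.approx(0.5)


class TestCalciumPool:
    def test_pump_only_at_rest_with_no_current(self):
        pool = CalciumPool(ca_in=0.001, ca_rest=0.001)
        expected = -pool.pump_p * pool.k_t * 0.001 / (0.001 + pool.k_d)
        assert ca_pool_derivative(pool, 0.0) == pytest.approx(expected)

    def test_inward_current_raises_calcium(self):
        pool = CalciumPool()
        assert ca_pool_derivative(pool, -0.01) > ca_pool_derivative(pool, 0.0)

    def test_steady_state_matches_bisection_oracle(self):
        pool = CalciumPool()
        i_ca = -0.005  # mA/cm^2, constant inward
        root = brentq(lambda ca: ca_pool_derivative(pool, i_ca, ca_in=ca),
                      1e-6, 50.0)
        sol = solve_ivp(lambda t, y: [ca_pool_derivative(pool, i_ca, ca_in=y[0])],
                        (0.0, 2000.0), [pool.ca_in], rtol=1e-9, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(root, rel=1e-4)

    def test_calcium_stays_positive_under_extreme_inward_current(self):
        pool = CalciumPool()
        # 100 ms of an extreme inward current, then free relaxation
        def rhs(t, y):
            i_ca = -1.0 if t < 100.0 else 0.0
            return [ca_pool_derivative(pool, i_ca, ca_in=y[0])]
        sol = solve_ivp(rhs, (0.0, 1000.0), [pool.ca_in], rtol=1e-8, atol=1e-14,
                        max_step=1.0)
        assert np.all(sol.y[0] > 0)
        # after the transient the shell relaxes back toward rest
        assert sol.y[0, -1] < sol.y[0].max()
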