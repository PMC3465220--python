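"""Compartment model: input bookkeeping, simulation, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoglyc import (
    GlucoseInputProfile,
    InsulinSchedule,
    ModelParameters,
    NutritionEntry,
    NutritionSchedule,
    PatientState,
    ValidationError,
    simulate,
    steady_state_glucose,
    total_glucose_input,
)
from neoglyc.exceptions import NoSteadyStateError
from neoglyc.model import forecast_glucose, insulin_state_path, steady_state_insulin


def euler_path(params, G0, I0, Q0, si, u, P, T, dt, out_every):
    """Brute-force fixed-step Euler oracle on the full three-state system."""
    n = int(round(T / dt))
    k = int(round(out_every / dt))
    G, I, Q = G0, I0, Q0
    out = [G]
    for i in range(1, n + 1):
        dG = (-params.pG * G - si * G * Q / (1 + params.alphaG * Q)
              + (P + params.EGPnet) / (180.16 * params.Vg))
        dI = -params.nI * I / (1 + params.alphaI * I) + u * (1000 / 60) / params.Vi
        dQ = params.kIQ * (I - Q)
        G, I, Q = G + dt * dG, I + dt * dI, Q + dt * dQ
        if i % k == 0:
            out.append(G)
    return np.array(out)


def rk4_path(params, G0, I0, Q0, si, u, P, T, dt, out_every):
    """Fixed-step classical RK4 oracle (high-order reference for transients)."""
    def f(y):
        G, I, Q = y
        return np.array([
            -params.pG * G - si * G * Q / (1 + params.alphaG * Q)
            + (P + params.EGPnet) / (180.16 * params.Vg),
            -params.nI * I / (1 + params.alphaI * I) + u * (1000 / 60) / params.Vi,
            params.kIQ * (I - Q),
        ])

    n = int(round(T / dt))
    k = int(round(out_every / dt))
    y = np.array([G0, I0, Q0], dtype=float)
    out = [y[0]]
    for i in range(1, n + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i % k == 0:
            out.append(y[0])
    return np.array(out)


class TestGlucoseInput:
    def test_parenteral_conversion(self):
        """10% dextrose at 1 mL/hr into a 1 kg infant is 100 mg/kg/hr."""
        nut = NutritionSchedule([NutritionEntry(0, 600, 10.0, 1.0, 0, 0, 0)])
        prof = total_glucose_input(nut, 1.0)
        assert prof.total_at(10.0) == pytest.approx(100.0 / 60.0, abs=1e-12)
        assert prof.components_at(10.0)["parenteral"] == pytest.approx(1.6667, abs=1e-3)

    def test_all_zero_flows(self):
        nut = NutritionSchedule([NutritionEntry(0, 600, 0, 0, 0, 0, 0)])
        prof = total_glucose_input(nut, 0.8)
        assert np.all(np.asarray(prof.total_at(np.linspace(0, 600, 50))) == 0.0)

    def test_ebm_conversion_cohort_median(self):
        """15.8 mL/kg/day of EBM at 72 mg/mL carbohydrate is 0.79 mg/kg/min."""
        nut = NutritionSchedule([NutritionEntry(0, 600, 0, 0, 15.8, 0, 0)])
        prof = total_glucose_input(nut, 0.76)
        assert prof.total_at(1.0) == pytest.approx(15.8 * 72 / 1440, rel=1e-12)
        assert prof.total_at(1.0) == pytest.approx(0.79, abs=1e-3)

    def test_carrier_same_formula_and_gap_zero(self):
        nut = NutritionSchedule([
            NutritionEntry(0, 60, 10.0, 2.0, 0, 5.0, 0.5),
            NutritionEntry(120, 240, 12.5, 1.0, 8.0, 0, 0),
        ])
        prof = total_glucose_input(nut, 0.8)
        c = prof.components_at(30.0)
        assert c["carrier"] == pytest.approx(5 * 10 * 0.5 / 0.8 / 60)
        assert prof.total_at(90.0) == 0.0   # gap between entries
        assert prof.total_at(130.0) == pytest.approx(
            12.5 * 10 * 1.0 / 0.8 / 60 + 8.0 * 72 / 1440)

    def test_breakdown_sums_to_total(self):
        nut = NutritionSchedule([
            NutritionEntry(60 * k, 60 * (k + 1), 10.0, 1.0 + 0.1 * k, 5.0 * k, 5.0, 0.2)
            for k in range(8)
        ])
        prof = total_glucose_input(nut, 0.7)
        t = np.linspace(-10, 600, 200)
        comps = prof.components_at(t)
        np.testing.assert_array_equal(
            np.asarray(prof.total_at(t)),
            comps["parenteral"] + comps["ebm"] + comps["carrier"])

    def test_validation(self):
        with pytest.raises(ValidationError):
            total_glucose_input(
                NutritionSchedule([NutritionEntry(0, 60, 10.0, 1.0, 0, 0, 0)]), 0.0)
        with pytest.raises(ValidationError):
            NutritionEntry(0, 60, -1.0, 1.0, 0, 0, 0)
        with pytest.raises(ValidationError):
            NutritionSchedule([NutritionEntry(0, 120, 10, 1, 0, 0, 0),
                               NutritionEntry(60, 180, 10, 1, 0, 0, 0)])


class TestSimulate:
    def test_all_fluxes_zero_holds_state(self):
        p = ModelParameters(pG=1e-12, EGPnet=0.0)
        # pG must be > 0 by the invariants; a vanishing value makes every flux 0
        res = simulate(PatientState(0, 5.0), p, 0.0, InsulinSchedule([0.0], [0.0]),
                       GlucoseInputProfile.constant(0.0), 240, step=30)
        np.testing.assert_allclose(res.G, 5.0, atol=1e-9)

    def test_monotone_nonincreasing_without_glucose_input(self, params):
        p = ModelParameters(EGPnet=0.0)
        res = simulate(PatientState(0, 10.0), p, 1.5e-3,
                       InsulinSchedule([0.0], [0.02]),
                       GlucoseInputProfile.constant(0.0), 240, step=10)
        assert np.all(np.diff(res.G) <= 1e-12)

    def test_transient_endpoint_matches_euler_oracle(self, params):
        """Adaptive endpoint vs fixed-step Euler (0.01 min) after 4 h."""
        res = simulate(PatientState(0, 10.0), params, 1.5e-3,
                       InsulinSchedule([0.0], [0.02]),
                       GlucoseInputProfile.constant(7.9), 240, step=240)
        oracle = euler_path(params, 10.0, 0.0, 0.0, 1.5e-3, 0.02, 7.9, 240, 0.01, 240)
        assert abs(res.G[-1] - oracle[-1]) < 1e-6

    def test_transient_trajectory_matches_rk4_oracle(self, params):
        res = simulate(PatientState(0, 10.0), params, 1.5e-3,
                       InsulinSchedule([0.0], [0.02]),
                       GlucoseInputProfile.constant(7.9), 240, step=10,
                       rtol=1e-9, atol=1e-11)
        oracle = rk4_path(params, 10.0, 0.0, 0.0, 1.5e-3, 0.02, 7.9, 240, 0.01, 10)
        assert np.max(np.abs(res.G - oracle)) < 1e-6

    def test_euler_trajectory_within_analytic_bound(self, params):
        """Euler's whole-trajectory error vs the adaptive integrator is
        bounded by its first-order truncation estimate, not by 1e-6."""
        res = simulate(PatientState(0, 10.0), params, 1.5e-3,
                       InsulinSchedule([0.0], [0.02]),
                       GlucoseInputProfile.constant(7.9), 240, step=1,
                       rtol=1e-9, atol=1e-11)
        oracle = euler_path(params, 10.0, 0.0, 0.0, 1.5e-3, 0.02, 7.9, 240, 0.01, 1)
        err = np.max(np.abs(res.G - oracle))
        assert 1e-6 < err < 5e-3   # Euler bias dominates; stays within O(dt)

    def test_si_monotonicity(self, params):
        """Raising SI never raises G anywhere on the trajectory."""
        prof = GlucoseInputProfile.constant(7.9)
        ins = InsulinSchedule([0.0], [0.01])
        prev = None
        for si in [0.0, 2e-4, 1e-3, 3e-3, 1e-2]:
            res = simulate(PatientState(0, 12.0), params, si, ins, prof, 240, step=15)
            if prev is not None:
                assert np.all(res.G <= prev + 1e-9)
            prev = res.G

    def test_si_trace_must_cover_horizon(self, params):
        from neoglyc import SITrace
        tr = SITrace.constant(1e-3, 0.0, 120.0)
        with pytest.raises(ValidationError):
            simulate(PatientState(0, 8.0), params, tr, InsulinSchedule([0.0], [0.0]),
                     GlucoseInputProfile.constant(5.0), 240)

    def test_insulin_cascade_converges_to_steady_state(self, params):
        """I and Q converge to the analytic steady state within 0.1% by ten
        insulin time constants."""
        u = 0.02
        i_star, q_star = steady_state_insulin(params, u)
        t10 = 10.0 / params.nI
        res = simulate(PatientState(0, 8.0), params, 0.0, InsulinSchedule([0.0], [u]),
                       GlucoseInputProfile.constant(5.0), 20 * t10, step=t10)
        # also exercise the slower interstitial compartment
        t10q = 10.0 / params.kIQ
        resq = simulate(PatientState(0, 8.0), params, 0.0, InsulinSchedule([0.0], [u]),
                        GlucoseInputProfile.constant(5.0), 2 * t10q, step=t10q)
        assert abs(res.I[1] - i_star) / i_star < 1e-3
        assert abs(resq.Q[-1] - q_star) / q_star < 1e-3


class TestSteadyState:
    def test_closed_form_without_insulin(self, params):
        g = steady_state_glucose(params, 0.0, 0.0, 7.9)
        assert g == pytest.approx((7.9 + params.EGPnet)
                                  / (180.16 * params.Vg * params.pG), rel=1e-12)

    def test_linearity_in_p_without_insulin(self):
        p0 = ModelParameters(EGPnet=0.0)
        assert steady_state_glucose(p0, 0.0, 0.0, 8.0) == pytest.approx(
            2 * steady_state_glucose(p0, 0.0, 0.0, 4.0), rel=1e-12)

    def test_simulate_from_steady_state_drifts_below_1e6(self, params):
        si, u, P = 1.5e-3, 0.01, 7.9
        g0 = steady_state_glucose(params, si, u, P)
        i0, q0 = steady_state_insulin(params, u)
        res = simulate(PatientState(0, g0, i0, q0), params, si,
                       InsulinSchedule([0.0], [u]), GlucoseInputProfile.constant(P),
                       24 * 60, step=60)
        assert np.max(np.abs(res.G - g0)) < 1e-6

    def test_no_steady_state_when_clearance_saturates(self, params):
        with pytest.raises(NoSteadyStateError):
            steady_state_insulin(params, 0.5)  # input exceeds nI/alphaI capacity


class TestFastPaths:
    def test_insulin_state_path_matches_adaptive(self, params):
        ins = InsulinSchedule([0.0, 90.0], [0.02, 0.005])
        t, I, Q = insulin_state_path(params, ins, 0.0, 240.0, 0.0, 0.0, dt=0.5)
        res = simulate(PatientState(0, 8.0), params, 0.0, ins,
                       GlucoseInputProfile.constant(5.0), 240, step=0.5,
                       rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(I, res.I, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(Q, res.Q, rtol=1e-5, atol=1e-6)

    def test_forecast_glucose_matches_simulate(self, params):
        prof = GlucoseInputProfile.constant(7.9)
        for si in (0.0, 1e-3, 5e-3):
            for u in (0.0, 0.01, 0.05):
                ref = simulate(PatientState(0, 12.0), params, si,
                               InsulinSchedule([0.0], [u]), prof, 240, step=240)
                fast = forecast_glucose(12.0, 0.0, 0.0, params, [si], [u],
                                        prof, 0.0, 240.0)
                # absolute agreement in the dosing range; relative at the
                # extreme-overdose corner where G decays by ~2 orders
                assert abs(fast[0, 0] - ref.G[-1]) < max(5e-4, 0.015 * ref.G[-1])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(si=st.floats(1e-5, 1e-2), u=st.floats(0.0, 0.3), g0=st.floats(3.0, 25.0))
    def test_forecast_glucose_positive_and_finite(self, params, si, u, g0):
        g = forecast_glucose(g0, 0.0, 0.0, params, [si], [u],
                             GlucoseInputProfile.constant(8.0), 0.0, 240.0)
        assert np.isfinite(g).all() and (g > 0).all()
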