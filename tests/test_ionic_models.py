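"""CRN membrane-kinetics unit tests: parameter sets, fixed points, gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optocardiax import ionic_models as im
from optocardiax.analysis import apd

from conftest import paced_trace


class TestParameterSets:
    def test_healthy_baseline(self, healthy):
        assert healthy.g_K1 == pytest.approx(0.117)
        # healthy = unmodified baseline: identity shifts and scales
        assert healthy.shift_oa_act == 0.0
        assert healthy.shift_d_act == 0.0
        assert healthy.shift_na_inact == 0.0
        assert healthy.gto_scale == healthy.gcal_scale == healthy.gk1_scale == 1.0

    def test_caf_modifiers(self, caf):
        assert caf.gto_scale == pytest.approx(0.15)   # I_to reduced by 85%
        assert caf.gcal_scale == pytest.approx(0.26)  # I_CaL reduced by 74%
        assert caf.gk1_scale == pytest.approx(3.5)    # G_K1 increased by 250%
        assert caf.tau_d_scale == pytest.approx(1.62)
        assert caf.shift_oa_act == pytest.approx(16.0)
        assert caf.shift_d_act == pytest.approx(-5.4)
        assert caf.shift_na_inact == pytest.approx(1.6)
        assert caf.g_K1_eff == pytest.approx(0.117 * 3.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            im.IonicParams(g_Na=-1.0)
        with pytest.raises(ValueError):
            im.IonicParams(gk1_scale=0.0)

    def test_caf_modifiers_invert_to_healthy_bitwise(self, healthy, caf):
        """Resetting the cAF scale/shift records must reproduce healthy
        kinetics exactly (the modifiers are pure algebraic layers)."""
        from dataclasses import replace

        undone = replace(caf, name="healthy", gto_scale=1.0, gcal_scale=1.0,
                         gk1_scale=1.0, tau_d_scale=1.0, shift_oa_act=0.0,
                         shift_d_act=0.0, shift_na_inact=0.0)
        V = np.linspace(-100.0, 60.0, 401)
        inf_a, tau_a = im.gate_inf_tau(V, healthy)
        inf_b, tau_b = im.gate_inf_tau(V, undone)
        for g in inf_a:
            np.testing.assert_array_equal(inf_a[g], inf_b[g])
            np.testing.assert_array_equal(tau_a[g], tau_b[g])
        s = im.initial_state().as_array()
        ca = im.compute_currents(s, healthy)
        cb = im.compute_currents(s, undone)
        for k in ca:
            np.testing.assert_array_equal(ca[k], cb[k])


class TestDerivatives:
    def test_rest_is_fixed_point(self, healthy, healthy_rest):
        d = im.ionic_derivatives(healthy_rest, healthy)
        assert abs(d[0]) < 1e-3  # mV/ms

    def test_suprathreshold_injection_depolarises(self, healthy, healthy_rest):
        d = im.ionic_derivatives(healthy_rest, healthy, I_inject=20.0)
        assert d[0] > 0.0

    def test_nonfinite_state_raises(self, healthy, healthy_rest):
        bad = healthy_rest.copy()
        bad[0] = np.nan
        with pytest.raises(FloatingPointError):
            im.ionic_derivatives(bad, healthy)


class TestEquilibration:
    def test_healthy_resting_potential(self, healthy_rest):
        # regression value from the 0D integrator (CRN resting range)
        assert -83.5 < healthy_rest[0] < -81.0

    def test_caf_rest_more_negative(self, healthy_rest, caf_rest):
        assert caf_rest[0] < healthy_rest[0]  # G_K1 x3.5 pulls V toward E_K

    def test_idempotent(self, healthy):
        s1 = im.equilibrate_rest(healthy, duration=8000.0)
        # re-equilibrating the settled state barely moves it
        from optocardiax._kernels import run_zero_d
        from optocardiax.chr2 import ChR2Params

        a = s1.as_array().copy()
        n = 50_000
        run_zero_d(a, np.array([0., 0., 1., 0., 0.]), healthy, ChR2Params(),
                   0.02, np.zeros(n), np.zeros(n))
        assert abs(a[0] - s1.as_array()[0]) < 0.05

    def test_too_short_duration_rejected(self, healthy):
        with pytest.raises(ValueError):
            im.equilibrate_rest(healthy, duration=500.0)

    def test_no_spontaneous_activity(self, healthy, caf, healthy_rest,
                                     caf_rest):
        for p, rest in ((healthy, healthy_rest), (caf, caf_rest)):
            t, V, _ = paced_trace(p, beats=2, amp=0.0, cell=rest)
            assert V.max() - V.min() < 2.0  # quiescent: no APs in 2 s


@settings(deadline=None, max_examples=50)
@given(V=st.floats(min_value=-100.0, max_value=60.0))
def test_gate_curves_well_formed(V):
    """Steady states lie in [0, 1] and time constants are positive for any
    physiological voltage (healthy and cAF kinetics)."""
    for p in (im.make_healthy_params(), im.make_caf_params()):
        inf, tau = im.gate_inf_tau(V, p)
        for g in inf:
            assert 0.0 <= float(inf[g]) <= 1.0
            assert float(tau[g]) > 0.0


class TestPacedDynamics:
    def test_gates_stay_in_unit_interval(self, healthy):
        _, _, cell = paced_trace(healthy, beats=2)
        gates = cell[1:16]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_apd90_dt_convergence(self, healthy, healthy_rest):
        vals = {}
        for dt in (0.02, 0.01):
            t, V, _ = paced_trace(healthy, beats=2, dt=dt, cell=healthy_rest,
                                  record_every=int(round(0.1 / dt)))
            vals[dt] = apd(t, V)[-1]["apd"]
        assert abs(vals[0.02] - vals[0.01]) < 1.0  # ms

    def test_caf_apd_much_shorter(self, healthy, caf, healthy_rest, caf_rest):
        _, Vh, _ = paced_trace(healthy, beats=3, cell=healthy_rest)
        th, Vh2, _ = paced_trace(healthy, beats=3, cell=healthy_rest)
        tc, Vc, _ = paced_trace(caf, beats=3, amp=33.0, cell=caf_rest)
        a_h = apd(th, Vh2)[-1]["apd"]
        a_c = apd(tc, Vc)[-1]["apd"]
        assert a_c < 0.5 * a_h  # cAF remodelling collapses the APD

    def test_kernel_matches_reference_formulas(self, healthy, healthy_rest):
        """The table-interpolated production stepper must track a direct
        formula-level Rush-Larsen/Euler stepper to sub-0.5 mV over an AP
        upstroke and plateau."""
        from optocardiax.chr2 import ChR2Params
        from optocardiax._kernels import run_zero_d

        dt = 0.02
        n = 10_000  # 200 ms
        t = np.arange(n) * dt
        stim = np.where(t < 2.0, 20.0, 0.0)
        cell = healthy_rest.copy()
        ch = np.array([0., 0., 1., 0., 0.])
        tt, V_fast = run_zero_d(cell, ch, healthy, ChR2Params(), dt, stim,
                                np.zeros(n), record_every=1)

        s = healthy_rest.copy()
        V_ref = np.empty(n)
        gate_names = im.STATE_NAMES[1:12] + ("w",)
        gate_idx = list(range(1, 12)) + [15]
        for k in range(n):
            ds = im.ionic_derivatives(s, healthy, I_inject=stim[k])
            inf, tau = im.gate_inf_tau(s[0], healthy)
            new = s + dt * ds  # Euler for V, concentrations, f_Ca, u, v
            for g, gi in zip(gate_names, gate_idx):
                new[gi] = float(inf[g]) + (s[gi] - float(inf[g])) * np.exp(
                    -dt / float(tau[g]))
            # f_Ca, u, v: exponential update against their own targets
            fca_inf = 1.0 / (1.0 + s[18] / 0.00035)
            new[12] = fca_inf + (s[12] - fca_inf) * np.exp(-dt / 2.0)
            s = new
            V_ref[k] = s[0]
        assert np.max(np.abs(V_ref - V_fast)) < 0.5
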