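"""Membrane dynamics: intrinsic current, AHP conductance, Euler step, clamps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfmli import (NEVER, ClampMode, ModelParams, NeuronParams, NeuronState,
                   ahp_conductance, draw_intrinsic_current, isolated_rate,
                   membrane_step, render_spikes)


class TestIntrinsicCurrent:
    def test_mean_matches_closed_form_kappa_beta(self, params):
        p = params.neuron
        rng = np.random.default_rng(0)
        draws = np.array([draw_intrinsic_current(rng, p) for _ in range(200_000)])
        # Monte-Carlo mean vs closed form kappa*beta; se = sqrt(kappa)*beta/sqrt(n)
        se = math.sqrt(p.kappa) * p.beta / math.sqrt(len(draws))
        assert draws.min() >= 0.0
        assert abs(draws.mean() - p.kappa * p.beta) < 4 * se
        assert abs(p.kappa * p.beta - 0.0264) < 1e-4

    def test_degenerate_scale_limit(self):
        p = NeuronParams(beta=1e-300)
        rng = np.random.default_rng(1)
        assert all(draw_intrinsic_current(rng, p) < 1e-290 for _ in range(100))

    def test_fixed_seed_reproducible(self, params):
        a = [draw_intrinsic_current(np.random.default_rng(7), params.neuron)
             for _ in range(1)]
        seq1 = np.random.default_rng(7).gamma(params.neuron.kappa,
                                              params.neuron.beta, 50)
        seq2 = np.random.default_rng(7).gamma(params.neuron.kappa,
                                              params.neuron.beta, 50)
        assert np.array_equal(seq1, seq2)
        assert a[0] == seq1[0]


class TestAhpConductance:
    def test_zero_lag_is_peak(self, params):
        assert ahp_conductance(10.0, 10.0, params.neuron) == pytest.approx(50.0)

    def test_one_time_constant_e_fold(self, params):
        g = ahp_conductance(12.5, 10.0, params.neuron)  # lag = tau_ahp = 2.5 ms
        assert g == pytest.approx(50.0 * math.exp(-1.0))

    def test_never_spiked_is_zero(self, params):
        assert ahp_conductance(1e6, NEVER, params.neuron) == 0.0


class TestMembraneStep:
    def test_leak_equilibrium_is_fixed_point(self, params):
        s = NeuronState(V=params.neuron.E_leak)
        s2, spiked = membrane_step(s, params.neuron, 0.0, 0.0, 0.0,
                                   dt=0.25, t=0.0, i_spont=0.0)
        assert s2.V == pytest.approx(params.neuron.E_leak)
        assert not spiked

    def test_constant_current_steady_state(self):
        # raise threshold so the cell cannot fire; V -> E_leak + I/g_leak
        p = NeuronParams(V_threshold=-1.0, E_exc=0.0)
        s = NeuronState(V=p.E_leak)
        I = 0.0264  # nA; 26.4 pA / 1.6 nS = 16.5 mV depolarization
        t = 0.0
        for _ in range(4000):
            s, _ = membrane_step(s, p, 0.0, 0.0, 0.0, dt=0.25, t=t, i_spont=I)
            t += 0.25
        assert s.V == pytest.approx(-68.0 + 16.5, abs=1e-6)
        # the steady state sits above the real threshold, hence tonic firing
        assert s.V > -53.0

    @settings(max_examples=50, deadline=None)
    @given(V=st.floats(-90, -40), g_a=st.floats(0, 5), g_n=st.floats(0, 1),
           I=st.floats(-0.05, 0.05), lag=st.floats(0.0, 50.0))
    def test_one_step_matches_hand_computed_euler_update(self, V, g_a, g_n, I, lag):
        p = NeuronParams()
        t = 100.0
        s = NeuronState(V=V, t_spiked=t - lag)
        s2, _ = membrane_step(s, p, g_a, g_n, I, dt=0.25, t=t, i_spont=0.0)
        g_ahp = p.g_ahp_max * math.exp(-lag / p.tau_ahp)
        dV = (0.25 / p.C) * (-p.g_leak * (V - p.E_leak)
                             - g_ahp * (V - p.E_ahp)
                             - (g_a + g_n) * (V - p.E_exc) + 1000.0 * I)
        assert s2.V == pytest.approx(V + dV, rel=1e-12)

    def test_spike_sets_time_and_flag(self, params):
        s = NeuronState(V=-53.5)
        s2, spiked = membrane_step(s, params.neuron, 0.0, 0.0, 0.5,
                                   dt=0.25, t=10.0, i_spont=0.0)
        assert spiked and s2.t_spiked == pytest.approx(10.25)

    def test_voltage_clamp_pins_potential_and_never_spikes(self, params):
        s = NeuronState(V=-68.0, clamp=ClampMode("voltage_clamp", -60.0))
        t = 0.0
        for _ in range(1000):
            s, spiked = membrane_step(s, params.neuron, 10.0, 1.0, 1.0,
                                      dt=0.25, t=t, i_spont=0.05)
            assert s.V == -60.0 and not spiked
            t += 0.25

    def test_nonfinite_voltage_aborts(self, params):
        s = NeuronState(V=float("nan"))
        with pytest.raises(FloatingPointError):
            membrane_step(s, params.neuron, 0.0, 0.0, 0.0, dt=0.25, t=0.0,
                          i_spont=0.0)


class TestIntegrationStability:
    def test_halving_dt_changes_spike_count_by_less_than_10pct(self, params):
        from dataclasses import replace
        rate_coarse = isolated_rate(params, 0.0, 60000.0, seed=3)
        fine = replace(params, dt=0.125)
        rate_fine = isolated_rate(fine, 0.0, 60000.0, seed=3)
        assert abs(rate_fine - rate_coarse) / rate_coarse < 0.10


def test_render_spikes_is_cosmetic_only():
    t = np.arange(1, 11, dtype=float)
    v = np.full(10, -60.0)
    out = render_spikes(t, v, np.array([3.0, 7.0]))
    assert out[2] == 0.0 and out[6] == 0.0
    assert np.all(v == -60.0)  # input untouched
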