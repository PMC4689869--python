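"""Protocol registry, the coupled loop, summaries and outcome classification."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pfmli import (ModelParams, ProtocolSpec, RateSchedule, Segment,
                   build_protocol, classify_outcome, run_protocol, run_repeats,
                   summarize_trials, trial_table)
from pfmli import protocols as proto
from pfmli import _kernel
from conftest import reference_loop


class TestRegistry:
    def test_simulation_one_dimensions(self):
        spec = build_protocol("I")
        assert spec.n_pf == 1
        assert spec.trial_onset == 5000.0
        assert spec.n_trials == 60
        assert spec.n_repeats == 10

    def test_simulation_five_voltage_clamp_phase(self):
        spec = build_protocol("V")
        (ph,) = spec.clamp_phases
        assert ph.mode == "voltage_clamp" and ph.level == -60.0
        assert ph.t_start == 2500.0
        assert spec.n_pf == 8

    def test_simulation_nine_gamma_schedule(self):
        spec = build_protocol("IX")
        (gp,) = spec.gamma_phases
        assert gp.gamma == 1.5 and gp.t_start == 5000.0
        assert spec.duration == 605000.0
        x = build_protocol("X")
        assert x.gamma_phases[0].gamma == 0.5

    def test_simulation_eight_starts_below_equilibrium(self):
        spec = build_protocol("VIII")
        assert spec.w_hat_init == 0.1
        assert spec.clamp_phases[0].mode == "voltage_clamp"
        assert spec.clamp_phases[1].mode == "firing_target"
        assert spec.clamp_phases[1].level == 50.0

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            build_protocol("XI")

    def test_pf_rate_override(self):
        spec = build_protocol("VII", pf_rate=1.0)
        assert spec.pf_schedule.rate_at(10000.0) == 1.0


def _tiny_spec(**kw):
    defaults = dict(
        id="custom", n_pf=2, duration=2000.0,
        pf_schedule=RateSchedule.constant(40.0, 0.0, 2000.0),
        trial_onset=500.0, trial_period=500.0, summary_interval=500.0,
        n_repeats=1, base_seed=99, w_hat_init=0.3)
    defaults.update(kw)
    return ProtocolSpec(**defaults)


class TestCoupledLoop:
    def test_kernel_matches_reference_composition_of_step_ops(self, params):
        """Compiled loop equals the public single-step operations composed in order."""
        spec = _tiny_spec()
        n_steps = int(spec.duration / params.dt)
        rng = proto.repeat_rng(spec, 0)
        spikes = np.random.default_rng(1).random((n_steps, 2)) < 0.01
        spikes = spikes.astype(np.uint8)
        ispont = rng.gamma(params.neuron.kappa, params.neuron.beta, n_steps)
        clamp_mode = np.zeros(n_steps, dtype=np.int8)
        clamp_mode[4000:] = _kernel.CLAMP_CURRENT
        clamp_level = np.where(np.arange(n_steps) >= 4000, 0.01, 0.0)
        gamma = np.where(np.arange(n_steps) < 2000, 1.0, 1.3)
        w0 = np.array([0.3, 0.1])

        V, rate, xbar, what, pfx, spk = _kernel.simulate(
            params, spikes, ispont, clamp_mode, clamp_level, gamma, w0,
            rec_every=1)
        V_ref, xbar_ref, what_ref = reference_loop(
            params, spikes, ispont, clamp_mode, clamp_level, gamma, w0)
        np.testing.assert_allclose(V, V_ref, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(xbar, xbar_ref, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(what, what_ref, rtol=1e-10, atol=1e-12)

    def test_kernel_reference_agreement_with_voltage_clamp(self, params):
        spec = _tiny_spec()
        n_steps = int(spec.duration / params.dt)
        rng = proto.repeat_rng(spec, 1)
        spikes = (rng.random((n_steps, 2)) < 0.02).astype(np.uint8)
        ispont = rng.gamma(params.neuron.kappa, params.neuron.beta, n_steps)
        clamp_mode = np.full(n_steps, _kernel.CLAMP_VOLTAGE, dtype=np.int8)
        clamp_level = np.full(n_steps, -60.0)
        gamma = np.ones(n_steps)
        w0 = np.array([0.5, 0.5])
        V, _, xbar, what, _, spk = _kernel.simulate(
            params, spikes, ispont, clamp_mode, clamp_level, gamma, w0,
            rec_every=1)
        V_ref, xbar_ref, what_ref = reference_loop(
            params, spikes, ispont, clamp_mode, clamp_level, gamma, w0)
        assert len(spk) == 0
        assert np.all(V == -60.0)
        np.testing.assert_allclose(what, what_ref, rtol=1e-10, atol=1e-12)

    def test_zero_pf_input_leaves_weights_unchanged(self):
        spec = _tiny_spec(pf_schedule=RateSchedule.constant(0.0, 0.0, 2000.0))
        res = run_protocol(spec, 0)
        assert np.all(res.w_hat == 0.3)

    def test_seed_reproducibility_bit_identical(self):
        spec = _tiny_spec()
        a = run_protocol(spec, 0)
        b = run_protocol(spec, 0)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.w_hat, b.w_hat)
        assert np.array_equal(a.mli_spike_times, b.mli_spike_times)

    def test_distinct_repeats_differ(self):
        spec = _tiny_spec()
        a = run_protocol(spec, 0)
        b = run_protocol(spec, 1)
        assert not np.array_equal(a.V, b.V)

    def test_weight_bounds_throughout_run(self):
        res = run_protocol(build_protocol("VI", n_repeats=1), 0)
        w0 = res.spec.params.synapse.w0
        assert np.all(res.w_hat >= 0.0) and np.all(res.w_hat <= 1.0)
        assert np.all(res.w_eff >= w0 - 1e-12) and np.all(res.w_eff <= 1.0 + 1e-12)

    def test_voltage_clamp_suppresses_spiking_and_trace(self):
        res = run_protocol(build_protocol("V", n_repeats=1), 0)
        assert np.all(res.mli_spike_times <= 2500.0 + res.spec.params.dt)
        late = res.t_rec > 2500.0 + 5 * res.spec.params.mli_trace.tau_psi
        assert np.all(res.mli_xbar[late] < 0.01)

    def test_sim_v_mean_weight_monotone_decreasing_after_onset(self):
        res = run_protocol(build_protocol("V", n_repeats=1), 0)
        m = res.t_rec > 5000.0 + 5 * res.spec.params.mli_trace.tau_psi
        mean_what = res.w_hat[m].mean(axis=1)
        assert np.all(np.diff(mean_what) <= 1e-12)


class TestSummaries:
    def test_constant_weights_give_zero_percent_change(self):
        spec = _tiny_spec(pf_schedule=RateSchedule.constant(0.0, 0.0, 2000.0))
        df = trial_table([run_protocol(spec, 0)])
        assert np.allclose(df["pct_change_w"], 0.0)
        assert len(df) == 3  # boundaries at 1000, 1500, 2000 ms

    def test_identical_repeats_collapse_range(self):
        spec = _tiny_spec()
        a = run_protocol(spec, 0)
        b = run_protocol(spec, 0)
        b.repeat_index = 1  # same stream, labelled as another repeat
        s = summarize_trials([a, b])[-1]
        assert s.pct_w_min == s.pct_w_max == s.pct_w_mean

    def test_trial_table_contains_all_repeats(self):
        spec = _tiny_spec(n_repeats=2)
        df = trial_table(run_repeats(spec))
        assert set(df["repeat"]) == {0, 1}

    def test_classification_thresholds(self):
        base = summarize_trials([run_protocol(_tiny_spec(), 0)])[-1]
        assert classify_outcome(replace(base, pct_w_mean=20.0)) == "LTP"
        assert classify_outcome(replace(base, pct_w_mean=-80.0)) == "LTD"
        assert classify_outcome(replace(base, pct_w_mean=1.0)) == "none"

    def test_percent_change_bounded_below_by_floor(self):
        """pct change of w can never fall below (w0/w_start - 1)*100."""
        res = run_protocol(build_protocol("V", n_repeats=1), 0)
        df = trial_table([res])
        w_start, _ = res.mean_weights_at(5000.0)
        floor_pct = 100.0 * (res.spec.params.synapse.w0 / w_start - 1.0)
        assert df["pct_change_w"].min() >= floor_pct - 1e-9


class TestEquilibriumInitialization:
    def test_baseline_equilibrium_near_normalized_spontaneous_rate(self, params):
        x = proto.baseline_mli_activity(params)
        # ~30 Hz spontaneous / f_max 150 -> ~0.2
        assert x == pytest.approx(0.2, abs=0.03)

    def test_equilibrium_init_uses_gamma_at_time_zero(self, params):
        spec = build_protocol("I")
        w = proto.resolve_w_hat_init(spec)
        assert w.shape == (1,)
        assert w[0] == pytest.approx(proto.baseline_mli_activity(params), abs=1e-12)
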