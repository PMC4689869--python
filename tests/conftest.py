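"""Shared fixtures and the pure-Python reference simulation loop.

The reference loop composes the public single-step operations
(ampa_step, nmda_step, membrane_step, trace_step, weight_step) in the
documented per-step order.  It is deliberately independent of the
compiled kernel and is used to cross-check it on short runs with shared
pre-drawn randomness.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from pfmli import (ClampMode, ModelParams, NeuronState, NmdaState,
                   PlasticityParams, SynapseState, TraceState, ampa_step,
                   membrane_step, nmda_conductance, nmda_step, trace_step,
                   weight_step)


hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


def reference_loop(params: ModelParams, spikes, ispont, clamp_mode,
                   clamp_level, gamma_arr, w_hat0):
    """Slow reference simulation from the public step operations.

    Returns per-step arrays of V, mli x_bar and per-synapse w_hat.
    """
    n_steps, n_pf = spikes.shape
    dt = params.dt
    syn = [SynapseState(w_hat=float(w_hat0[i])) for i in range(n_pf)]
    nmda = NmdaState()
    pf_tr = [TraceState() for _ in range(n_pf)]
    mli_tr = TraceState()
    state = NeuronState(V=params.neuron.E_leak)

    V_out = np.empty(n_steps)
    xbar_out = np.empty(n_steps)
    what_out = np.empty((n_steps, n_pf))
    for k in range(n_steps):
        t = k * dt
        m = int(clamp_mode[k])
        clamp = (ClampMode("free") if m == 0 else
                 ClampMode("voltage_clamp", float(clamp_level[k])) if m == 1 else
                 ClampMode("current_inject", float(clamp_level[k])))
        state = replace(state, clamp=clamp)

        g_ampa = 0.0
        n_spk = 0
        for i in range(n_pf):
            syn[i], g = ampa_step(syn[i], params.synapse, bool(spikes[k, i]), dt)
            g_ampa += g
            n_spk += int(spikes[k, i])
        nmda = nmda_step(nmda, params.synapse, n_spk, dt)
        g_nmda = nmda_conductance(nmda, params.synapse, state.V)
        state, spiked = membrane_step(state, params.neuron, g_ampa, g_nmda,
                                      0.0, dt, t, i_spont=float(ispont[k]))
        for i in range(n_pf):
            pf_tr[i] = trace_step(pf_tr[i], params.pf_trace, bool(spikes[k, i]), dt)
        mli_tr = trace_step(mli_tr, params.mli_trace, spiked, dt)

        pp = PlasticityParams(eta=params.plasticity.eta, gamma=float(gamma_arr[k]))
        for i in range(n_pf):
            syn[i] = replace(syn[i], w_hat=weight_step(
                syn[i].w_hat, pf_tr[i].x_bar, mli_tr.x_bar, pp, dt))

        V_out[k] = state.V
        xbar_out[k] = mli_tr.x_bar
        for i in range(n_pf):
            what_out[k, i] = syn[i].w_hat
    return V_out, xbar_out, what_out
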