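"""JIT-compiled inner simulation loop.

The coupled per-step update (synaptic kinetics -> membrane Euler step ->
spike detection -> activity traces -> weight update) is a scalar
recurrence over millions of 0.25 ms steps, so it is compiled with numba.
All randomness (per-step intrinsic-current draws, PF Bernoulli spikes)
is generated *outside* with a seeded numpy Generator and passed in as
arrays, which keeps the fast path bit-reproducible and lets the
pure-Python single-step operations be checked against it exactly.

Clamp codes: 0 = free, 1 = voltage clamp (level in mV),
2 = current injection (level in nA).
"""

from __future__ import annotations

import numpy as np
from numba import njit

CLAMP_FREE = 0
CLAMP_VOLTAGE = 1
CLAMP_CURRENT = 2


def simulate(params, spikes, ispont, clamp_mode, clamp_level, gamma_arr,
             w_hat0, rec_every):
    """Convenience wrapper unpacking a ModelParams bundle into the JIT kernel."""
    np_, sp, pf, mli, pl = (params.neuron, params.synapse, params.pf_trace,
                            params.mli_trace, params.plasticity)
    dt = params.dt
    return run_coupled(
        dt,
        np_.C, np_.V_threshold, np_.g_leak, np_.E_leak, np_.E_exc,
        np_.g_ahp_max, np_.E_ahp, np_.tau_ahp,
        sp.g_ampa_max, np.exp(-dt / sp.tau_fast), np.exp(-dt / sp.tau_slow),
        sp.alpha_fast, sp.alpha_slow,
        sp.g_nmda_max, sp.tau_rise, sp.tau_decay, np.exp(-dt / sp.tau_n),
        sp.rho * sp.mg_out, sp.sigma, sp.w0,
        np.exp(-dt / pf.tau_psi), np.exp(-dt / pf.nu_psi),
        1.0 / (pf.tau_psi - pf.nu_psi), pf.f_max,
        np.exp(-dt / mli.tau_psi), np.exp(-dt / mli.nu_psi),
        1.0 / (mli.tau_psi - mli.nu_psi), mli.f_max,
        pl.eta,
        np.ascontiguousarray(spikes, dtype=np.uint8),
        np.ascontiguousarray(ispont, dtype=np.float64),
        np.ascontiguousarray(clamp_mode, dtype=np.int8),
        np.ascontiguousarray(clamp_level, dtype=np.float64),
        np.ascontiguousarray(gamma_arr, dtype=np.float64),
        np.ascontiguousarray(w_hat0, dtype=np.float64),
        rec_every,
    )


@njit(cache=True)
def run_coupled(dt,
                # neuron
                C, V_th, g_leak, E_leak, E_exc, g_ahp_max, E_ahp, tau_ahp,
                # synapse
                g_ampa_max, dec_fast, dec_slow, alpha_fast, alpha_slow,
                g_nmda_max, tau_rise, tau_decay, dec_n, mg_coef, sigma, w0,
                # traces: decays and constants for PF and MLI populations
                pf_dec_tau, pf_dec_nu, pf_inv_diff, pf_fmax,
                mli_dec_tau, mli_dec_nu, mli_inv_diff, mli_fmax,
                # plasticity
                eta,
                # per-step inputs
                spikes,       # (n_steps, n_pf) uint8 PF spike raster
                ispont,       # (n_steps,) intrinsic current draws (nA)
                clamp_mode,   # (n_steps,) int8
                clamp_level,  # (n_steps,) float64
                gamma_arr,    # (n_steps,) float64
                w_hat0,       # (n_pf,) initial variable weight components
                rec_every,    # record once per this many steps
                ):
    n_steps = spikes.shape[0]
    n_pf = spikes.shape[1]
    n_rec = n_steps // rec_every

    V_rec = np.empty(n_rec)
    rate_rec = np.empty(n_rec)
    xbar_rec = np.empty(n_rec)
    what_rec = np.empty((n_rec, n_pf))
    pfx_rec = np.empty((n_rec, n_pf))
    spike_steps = np.empty(n_steps, dtype=np.int64)
    n_spk = 0

    V = E_leak
    has_spiked = False
    t_spiked = 0.0
    a_fast = np.zeros(n_pf)
    a_slow = np.zeros(n_pf)
    what = w_hat0.copy()
    n_acc = 0.0
    R = 0.0
    pfA = np.zeros(n_pf)
    pfB = np.zeros(n_pf)
    pfx = np.zeros(n_pf)
    mliA = 0.0
    mliB = 0.0
    mli_rate = 0.0
    mli_x = 0.0
    one_minus_w0 = 1.0 - w0

    for k in range(n_steps):
        t = k * dt
        # --- synaptic kinetics (exact decay, instantaneous rise) ---
        tot_spikes = 0.0
        g_ampa = 0.0
        for i in range(n_pf):
            af = a_fast[i] * dec_fast
            asl = a_slow[i] * dec_slow
            if spikes[k, i]:
                af += alpha_fast
                asl += alpha_slow
                tot_spikes += 1.0
            a_fast[i] = af
            a_slow[i] = asl
            g_ampa += (w0 + one_minus_w0 * what[i]) * (af + asl)
        g_ampa *= g_ampa_max

        n_acc = n_acc * dec_n + tot_spikes
        R = R + dt * (np.log(n_acc + 1.0) * (1.0 - R) / tau_rise - R / tau_decay)
        if R < 0.0:
            R = 0.0
        elif R > 1.0:
            R = 1.0
        g_nmda = g_nmda_max * R / (1.0 + mg_coef * np.exp(sigma * V))

        # --- membrane ---
        mode = clamp_mode[k]
        spiked = False
        if mode == CLAMP_VOLTAGE:
            V = clamp_level[k]
        else:
            g_ahp = 0.0
            if has_spiked:
                g_ahp = g_ahp_max * np.exp(-(t - t_spiked) / tau_ahp)
            I = ispont[k]
            if mode == CLAMP_CURRENT:
                I += clamp_level[k]
            V = V + (dt / C) * (
                -g_leak * (V - E_leak)
                - g_ahp * (V - E_ahp)
                - (g_ampa + g_nmda) * (V - E_exc)
                + 1000.0 * I
            )
            if not np.isfinite(V):
                raise FloatingPointError("membrane potential diverged (non-finite V)")
            if V >= V_th:
                spiked = True
                has_spiked = True
                t_spiked = t + dt
                spike_steps[n_spk] = k
                n_spk += 1

        # --- activity traces ---
        for i in range(n_pf):
            pfA[i] *= pf_dec_tau
            pfB[i] *= pf_dec_nu
            if spikes[k, i]:
                pfA[i] += 1.0
                pfB[i] += 1.0
            r = 1000.0 * (pfA[i] - pfB[i]) * pf_inv_diff
            if r < 0.0:
                r = 0.0
            if r > pf_fmax:
                r = pf_fmax
            pfx[i] = r / pf_fmax
        mliA *= mli_dec_tau
        mliB *= mli_dec_nu
        if spiked:
            mliA += 1.0
            mliB += 1.0
        mli_rate = 1000.0 * (mliA - mliB) * mli_inv_diff
        if mli_rate < 0.0:
            mli_rate = 0.0
        mr = mli_rate
        if mr > mli_fmax:
            mr = mli_fmax
        mli_x = mr / mli_fmax

        # --- gated steepest descent weight update ---
        g = gamma_arr[k]
        for i in range(n_pf):
            wh = what[i] + dt * eta * pfx[i] * (mli_x - g * what[i])
            if wh < 0.0:
                wh = 0.0
            elif wh > 1.0:
                wh = 1.0
            what[i] = wh

        if (k + 1) % rec_every == 0:
            j = (k + 1) // rec_every - 1
            V_rec[j] = V
            rate_rec[j] = mli_rate
            xbar_rec[j] = mli_x
            for i in range(n_pf):
                what_rec[j, i] = what[i]
                pfx_rec[j, i] = pfx[i]

    return V_rec, rate_rec, xbar_rec, what_rec, pfx_rec, spike_steps[:n_spk]
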