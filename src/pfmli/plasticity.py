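"""Gated steepest descent synaptic weight update.

The variable weight component of each PF->MLI synapse follows

    d(w_hat)/dt = eta * PF_bar * (MLI_bar - gamma * w_hat),

where PF_bar and MLI_bar are the normalized pre- and postsynaptic
activity traces in [0, 1].  Presynaptic activity gates learning (no PF
activity, no change) and gamma * w_hat acts as a dynamic threshold:
the rule potentiates while MLI_bar exceeds it and depresses below it,
so w_hat chases MLI_bar / gamma and is self-stabilizing.  gamma models
the "basal tone" set by tonic metabotropic receptor activity and is 1
unless a protocol schedules otherwise.
"""

from __future__ import annotations

from .params import PlasticityParams


def weight_derivative(pf_bar: float, mli_bar: float, w_hat: float,
                      p: PlasticityParams) -> float:
    """Instantaneous d(w_hat)/dt (1/ms)."""
    return p.eta * pf_bar * (mli_bar - p.gamma * w_hat)


def weight_step(w_hat: float, pf_bar: float, mli_bar: float,
                p: PlasticityParams, dt: float) -> float:
    """One forward-Euler step of the rule, clipped to [0, 1]."""
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    w = w_hat + dt * weight_derivative(pf_bar, mli_bar, w_hat, p)
    return min(max(w, 0.0), 1.0)


def equilibrium_weight(mli_bar: float, gamma: float) -> float:
    """Fixed point of the rule, clip(MLI_bar / gamma, 0, 1).

    Used to start weights "near equilibrium" for the baseline activity
    regime before a plasticity-inducing phase begins.
    """
    if gamma <= 0:
        raise ValueError("gamma must be strictly positive")
    return min(max(mli_bar / gamma, 0.0), 1.0)
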