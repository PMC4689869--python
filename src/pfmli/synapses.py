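"""PF->MLI synaptic conductances.

AMPA (per synapse): instantaneous rise, double-exponential decay

    alpha(t) = alpha_fast * exp(-t/tau_fast) + alpha_slow * exp(-t/tau_slow),

realized as two first-order kernel states that decay exactly
(multiplication by exp(-dt/tau)) and jump by their amplitude on each
presynaptic spike — on the simulation grid this equals convolving the
spike train with alpha.  The conductance is scaled by the effective
weight w = w0 + (1 - w0) * w_hat.

NMDA (pooled over the whole PF bundle): MLI NMDA receptors are
extrasynaptic and activated by glutamate spillover, so a single
accumulator n(t) integrates all PF spikes with decay tau_n, the open
fraction R follows

    dR/dt = log(n + 1) (1 - R) / tau_rise - R / tau_decay,

and the conductance carries the voltage-dependent magnesium block

    g_NMDA = g_nmda_max * R / (1 + rho * [Mg]_o * exp(sigma * V)).

The NMDA conductance is not scaled by synaptic weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

from .params import SynapseParams


def effective_weight(w0: float, w_hat: float) -> float:
    """Effective synaptic weight w = w0 + (1 - w0) * w_hat, in [w0, 1]."""
    if not (0.0 < w0 < 1.0):
        raise ValueError("w0 must lie in (0, 1)")
    if not (0.0 <= w_hat <= 1.0):
        raise ValueError("w_hat must lie in [0, 1]")
    return w0 + (1.0 - w0) * w_hat


@dataclass(frozen=True)
class SynapseState:
    """Per-synapse AMPA kernel state and variable weight component."""

    a_fast: float = 0.0
    a_slow: float = 0.0
    w_hat: float = 0.0

    def w_eff(self, p: SynapseParams) -> float:
        return effective_weight(p.w0, self.w_hat)


@dataclass(frozen=True)
class NmdaState:
    """Pooled NMDA state: glutamate accumulator n and open-channel fraction R."""

    n: float = 0.0
    R: float = 0.0


def ampa_step(s: SynapseState, p: SynapseParams, spiked: bool, dt: float
              ) -> Tuple[SynapseState, float]:
    """Advance one synapse's AMPA kinetics one step; return (state, conductance nS).

    Both kernel components decay exactly over dt; a presynaptic spike at
    the step boundary adds its amplitude before the conductance is read,
    so a lone spike contributes g_ampa_max * w at lag zero
    (alpha_fast + alpha_slow = 1).
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    a_fast = s.a_fast * math.exp(-dt / p.tau_fast)
    a_slow = s.a_slow * math.exp(-dt / p.tau_slow)
    if spiked:
        a_fast += p.alpha_fast
        a_slow += p.alpha_slow
    g = p.g_ampa_max * effective_weight(p.w0, s.w_hat) * (a_fast + a_slow)
    return replace(s, a_fast=a_fast, a_slow=a_slow), g


def nmda_step(s: NmdaState, p: SynapseParams, n_spikes_this_step: int, dt: float) -> NmdaState:
    """Advance the pooled NMDA state one step.

    n decays with tau_n and increments by one per PF spike (pooled over
    the bundle); R takes one Euler step driven by log(n + 1), clipped to
    [0, 1] to guard against Euler overshoot.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    if n_spikes_this_step < 0:
        raise ValueError("spike count must be non-negative")
    n = s.n * math.exp(-dt / p.tau_n) + n_spikes_this_step
    R = s.R + dt * (math.log(n + 1.0) * (1.0 - s.R) / p.tau_rise - s.R / p.tau_decay)
    R = min(max(R, 0.0), 1.0)
    return NmdaState(n=n, R=R)


def mg_block(p: SynapseParams, V: float) -> float:
    """Voltage-dependent magnesium unblock factor in (0, 1), increasing in V."""
    return 1.0 / (1.0 + p.rho * p.mg_out * math.exp(p.sigma * V))


def nmda_conductance(s: NmdaState, p: SynapseParams, V: float) -> float:
    """Pooled NMDA conductance (nS) at membrane potential V (mV)."""
    if not (0.0 <= s.R <= 1.0):
        raise ValueError("R must lie in [0, 1]")
    return p.g_nmda_max * s.R * mg_block(p, V)
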