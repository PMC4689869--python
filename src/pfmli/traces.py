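"""Normalized spike-activity traces.

Each neuron population (PF, MLI) carries a smooth firing-rate trace:
its spike train convolved with the unit-area kernel

    psi(t) = (exp(-t/tau_psi) - exp(-t/nu_psi)) / (tau_psi - nu_psi),

evaluated every step in state-space form (two exponential accumulators,
each decaying exactly and incremented by 1 per spike).  With time in ms
the convolution estimates spikes/ms; it is scaled by 1000 to Hz,
truncated at the population maximum f_max, then divided by f_max to
give the normalized activity x_bar in [0, 1] used by the learning rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import TraceParams


def psi_kernel(t: float, p: TraceParams) -> float:
    """Difference-of-exponentials rate kernel (1/ms); unit area, psi(0) = 0."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return (math.exp(-t / p.tau_psi) - math.exp(-t / p.nu_psi)) / (p.tau_psi - p.nu_psi)


@dataclass(frozen=True)
class TraceState:
    """State-space activity trace."""

    e_tau: float = 0.0   # sum of exp(-(t - t_k)/tau_psi) over past spikes
    e_nu: float = 0.0    # sum of exp(-(t - t_k)/nu_psi) over past spikes
    rate_hz: float = 0.0
    x_bar: float = 0.0


def trace_step(s: TraceState, p: TraceParams, spiked: bool, dt: float) -> TraceState:
    """Advance the trace one step; a spike lands at the new step boundary.

    The two accumulators decay exactly over dt and gain 1 per spike, so
    (e_tau - e_nu)/(tau_psi - nu_psi) equals the convolution of the spike
    train with psi on the grid.  The rate is truncated at f_max *before*
    normalization, guaranteeing x_bar in [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    e_tau = s.e_tau * math.exp(-dt / p.tau_psi)
    e_nu = s.e_nu * math.exp(-dt / p.nu_psi)
    if spiked:
        e_tau += 1.0
        e_nu += 1.0
    rate_hz = 1000.0 * (e_tau - e_nu) / (p.tau_psi - p.nu_psi)
    rate_hz = max(rate_hz, 0.0)  # guard floating-point noise at tiny values
    x_bar = min(rate_hz, p.f_max) / p.f_max
    return TraceState(e_tau=e_tau, e_nu=e_nu, rate_hz=rate_hz, x_bar=x_bar)
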