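"""Membrane dynamics of the model molecular layer interneuron.

The MLI is a conductance-based leaky integrate-and-fire cell,

    C dV/dt = -g_leak (V - E_leak) - g_ahp(t) (V - E_ahp)
              - (g_AMPA + g_NMDA) (V - E_exc) + I_spont + I_inject,

advanced with forward Euler.  There is no hard voltage reset: when V
crosses threshold a spike is registered (at most one per step) and the
after-hyperpolarization conductance

    g_ahp(t) = g_ahp_max * exp(-(t - t_spiked) / tau_ahp)

takes over repolarization, driving V toward E_ahp.  The intrinsic
current I_spont is redrawn from Gamma(kappa, beta) every step and makes
the isolated cell fire tonically at roughly 30 Hz.

Clamp modes emulate the electrophysiology rig: ``voltage_clamp`` pins V
at the command potential (and suppresses spiking), ``current_inject``
adds a constant bias current, ``free`` is the unperturbed cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .params import NeuronParams

#: Sentinel for "the neuron has never spiked".
NEVER = -math.inf

_MODES = ("free", "voltage_clamp", "current_inject")


@dataclass(frozen=True)
class ClampMode:
    """Recording-mode of the cell: free, voltage clamp (mV) or current injection (nA)."""

    mode: str = "free"
    level: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown clamp mode {self.mode!r}; expected one of {_MODES}")


FREE = ClampMode("free", 0.0)


@dataclass(frozen=True)
class NeuronState:
    """Evolving membrane state."""

    V: float                      # membrane potential (mV)
    t_spiked: float = NEVER       # time of most recent spike (ms)
    i_spont: float = 0.0          # intrinsic current used this step (nA)
    clamp: ClampMode = FREE


def draw_intrinsic_current(rng: np.random.Generator, p: NeuronParams) -> float:
    """Draw one intrinsic depolarizing current sample, Gamma(kappa, scale=beta), in nA."""
    return float(rng.gamma(p.kappa, p.beta))


def ahp_conductance(t: float, t_spiked: float, p: NeuronParams) -> float:
    """After-hyperpolarization conductance (nS) at time ``t`` given the last spike time.

    Computed from the most recent spike only; returns 0 if the neuron has
    never spiked.
    """
    if t_spiked == NEVER:
        return 0.0
    if t < t_spiked:
        raise ValueError("t must not precede the last spike time")
    return p.g_ahp_max * math.exp(-(t - t_spiked) / p.tau_ahp)


def membrane_step(
    s: NeuronState,
    p: NeuronParams,
    g_ampa_total: float,
    g_nmda_total: float,
    I_inject: float,
    dt: float,
    t: float,
    rng: Optional[np.random.Generator] = None,
    i_spont: Optional[float] = None,
) -> Tuple[NeuronState, bool]:
    """Advance the membrane one Euler step from time ``t`` to ``t + dt``.

    ``I_inject`` (nA) is added on top of any ``current_inject`` clamp level.
    The intrinsic current is redrawn from ``rng`` unless an explicit
    ``i_spont`` sample is supplied (used by deterministic cross-checks).
    Returns the new state and a spiked flag; in voltage clamp the
    potential is pinned and no spike is ever emitted.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    if g_ampa_total < 0 or g_nmda_total < 0:
        raise ValueError("synaptic conductances must be non-negative")

    if s.clamp.mode == "voltage_clamp":
        return replace(s, V=s.clamp.level, i_spont=0.0), False

    if i_spont is None:
        if rng is None:
            raise ValueError("either rng or an explicit i_spont sample is required")
        i_spont = draw_intrinsic_current(rng, p)

    I_total = i_spont + I_inject
    if s.clamp.mode == "current_inject":
        I_total += s.clamp.level

    g_ahp = ahp_conductance(t, s.t_spiked, p)
    # currents in nA are scaled by 1000 so every term is in pA (= nS * mV)
    dV = (dt / p.C) * (
        -p.g_leak * (s.V - p.E_leak)
        - g_ahp * (s.V - p.E_ahp)
        - (g_ampa_total + g_nmda_total) * (s.V - p.E_exc)
        + 1000.0 * I_total
    )
    V = s.V + dV
    if not math.isfinite(V):
        raise FloatingPointError(
            f"membrane potential diverged at t={t:.3f} ms (V={V!r}); "
            "check dt and conductance magnitudes"
        )
    spiked = V >= p.V_threshold
    t_spiked = t + dt if spiked else s.t_spiked
    return replace(s, V=V, t_spiked=t_spiked, i_spont=i_spont), spiked


def render_spikes(t_ms: np.ndarray, v_mv: np.ndarray, spike_times: np.ndarray,
                  peak: float = 0.0) -> np.ndarray:
    """Return a copy of a voltage recording with ``peak`` mV inserted at spike times.

    Purely cosmetic (figure-style action potentials); never part of the dynamics.
    """
    v = np.array(v_mv, dtype=float, copy=True)
    if len(spike_times):
        idx = np.searchsorted(t_ms, spike_times)
        idx = np.clip(idx, 0, len(v) - 1)
        v[idx] = peak
    return v
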