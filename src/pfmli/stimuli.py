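"""Parallel-fiber spike generation and injected-current calibration.

PF spike trains are inhomogeneous Poisson processes realized by
Bernoulli thinning on the integration grid (per-step spike probability
rate * dt / 1000, valid while rate * dt / 1000 <= 1, so at most one
spike per fiber per step).  Rate schedules are piecewise constant with
an optional periodic burst pattern ("100 Hz bursts for 100 ms every
1 s": the burst occupies the first burst_len ms of each period).

Injected currents in the clamp protocols are stated as firing-rate
targets ("depolarize to ~40 Hz"), so `calibrate_injection` finds the
constant current by bisection against simulated isolated-cell rates,
which are monotone in the injected current.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import _kernel
from .params import ModelParams


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant schedule segment over [t_start, t_end) ms."""

    t_start: float
    t_end: float
    rate: float                       # Hz; the off-burst rate if bursting
    burst_rate: Optional[float] = None  # Hz during the burst window
    burst_len: Optional[float] = None   # ms, burst occupies start of each period
    period: Optional[float] = None      # ms

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_end > t_start")
        if self.rate < 0:
            raise ValueError("rates must be non-negative")
        bursty = (self.burst_rate, self.burst_len, self.period)
        if any(v is not None for v in bursty) and any(v is None for v in bursty):
            raise ValueError("burst_rate, burst_len and period must be given together")
        if self.burst_rate is not None:
            if self.burst_rate < 0 or self.burst_len <= 0 or self.period <= 0:
                raise ValueError("invalid burst pattern")
            if self.burst_len > self.period:
                raise ValueError("burst_len must not exceed period")


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant (optionally bursting) PF rate function lambda(t)."""

    segments: Tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end:
                raise ValueError("schedule segments must not overlap")
        object.__setattr__(self, "segments", segs)

    @staticmethod
    def constant(rate: float, t_start: float, t_end: float) -> "RateSchedule":
        return RateSchedule((Segment(t_start, t_end, rate),))

    def rate_at(self, t: float) -> float:
        """Instantaneous rate (Hz) at time t (ms)."""
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                if seg.burst_rate is not None:
                    phase = (t - seg.t_start) % seg.period
                    return seg.burst_rate if phase < seg.burst_len else seg.rate
                return seg.rate
        return 0.0

    def rate_array(self, n_steps: int, dt: float) -> np.ndarray:
        """Per-step rates (Hz) on the grid t_k = k * dt, vectorized."""
        out = np.zeros(n_steps)
        t = np.arange(n_steps) * dt
        for seg in self.segments:
            m = (t >= seg.t_start) & (t < seg.t_end)
            if seg.burst_rate is not None:
                phase = (t[m] - seg.t_start) % seg.period
                out[m] = np.where(phase < seg.burst_len, seg.burst_rate, seg.rate)
            else:
                out[m] = seg.rate
        return out


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one neuron, aligned to the dt grid (ms, strictly increasing)."""

    neuron_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("spike times must be a strictly increasing 1-D array")
        object.__setattr__(self, "times", t)


def spike_raster(schedule: RateSchedule, n_steps: int, dt: float,
                 rng: np.random.Generator, n_fibers: int = 1) -> np.ndarray:
    """Bernoulli-thinned Poisson raster, shape (n_steps, n_fibers), dtype uint8.

    Fibers are independent and share the same rate schedule.
    """
    p = schedule.rate_array(n_steps, dt) * dt / 1000.0
    if np.any(p > 1.0):
        raise ValueError("rate * dt exceeds one spike per step; reduce dt or rate")
    return (rng.random((n_fibers, n_steps)).T < p[:, None]).astype(np.uint8)


def poisson_spikes(schedule: RateSchedule, dt: float, rng: np.random.Generator,
                   duration: Optional[float] = None, neuron_id: int = 0) -> SpikeTrain:
    """Draw one Poisson spike train from a rate schedule.

    Spikes are assigned to step boundaries (time k * dt for step k);
    reproducible under a fixed generator state.
    """
    if duration is None:
        duration = max(seg.t_end for seg in schedule.segments)
    n_steps = int(round(duration / dt))
    raster = spike_raster(schedule, n_steps, dt, rng, n_fibers=1)[:, 0]
    times = np.nonzero(raster)[0] * dt
    return SpikeTrain(neuron_id=neuron_id, times=times)


def clamped_rate(params: ModelParams, current_nA: float, duration_ms: float,
                 seed: int, n_pf: int = 0, pf_rate: float = 0.0,
                 w_hat: float = 0.0) -> float:
    """Mean firing rate (Hz) of the MLI under a constant injected current.

    Optionally includes a synaptic context: ``n_pf`` fibers firing
    Poisson at ``pf_rate`` Hz onto synapses frozen at variable weight
    ``w_hat`` (plasticity disabled so calibration does not move weights).
    """
    from dataclasses import replace
    from .params import PlasticityParams
    n_steps = int(round(duration_ms / params.dt))
    rng = np.random.default_rng(seed)
    if n_pf > 0 and pf_rate > 0:
        sched = RateSchedule.constant(pf_rate, 0.0, duration_ms)
        spikes = spike_raster(sched, n_steps, params.dt, rng, n_fibers=n_pf)
    else:
        spikes = np.zeros((n_steps, max(n_pf, 0)), dtype=np.uint8)
    ispont = rng.gamma(params.neuron.kappa, params.neuron.beta, n_steps)
    mode = np.full(n_steps, _kernel.CLAMP_CURRENT, dtype=np.int8)
    level = np.full(n_steps, current_nA)
    gamma = np.ones(n_steps)
    frozen = replace(params, plasticity=PlasticityParams(
        eta=0.0, gamma=params.plasticity.gamma))
    out = _kernel.simulate(frozen, spikes, ispont, mode, level, gamma,
                           np.full(n_pf, w_hat), rec_every=n_steps)
    spike_steps = out[5]
    return 1000.0 * len(spike_steps) / duration_ms


def isolated_rate(params: ModelParams, current_nA: float, duration_ms: float,
                  seed: int) -> float:
    """Mean firing rate (Hz) of the synapse-free MLI under a constant injected current."""
    return clamped_rate(params, current_nA, duration_ms, seed)


def calibrate_injection(target_rate: float, params: ModelParams,
                        tolerance: float = 1.0, seed: int = 20150,
                        duration_ms: float = 30000.0,
                        bracket: Tuple[float, float] = (-0.3, 0.5),
                        max_iter: int = 60, n_pf: int = 0,
                        pf_rate: float = 0.0, w_hat: float = 0.0) -> float:
    """Constant current (nA) driving the MLI at ``target_rate`` Hz.

    The model is evaluated in its protocol's synaptic context (``n_pf``
    fibers at ``pf_rate`` Hz, weights frozen at ``w_hat``), since the
    synaptic drive shifts the f-I curve.  Monotone bisection on the
    injected current; each evaluation simulates ``duration_ms`` with a
    dedicated seed so the returned current can be frozen into a protocol
    without leaking calibration randomness into the repeats.  Raises if
    the bracket does not contain the target.
    """
    def rate_of(cur: float) -> float:
        return clamped_rate(params, cur, duration_ms, seed, n_pf=n_pf,
                            pf_rate=pf_rate, w_hat=w_hat)

    lo, hi = bracket
    r_lo = rate_of(lo)
    r_hi = rate_of(hi)
    if not (r_lo <= target_rate <= r_hi):
        raise ValueError(
            f"target rate {target_rate} Hz not bracketed by currents "
            f"[{lo}, {hi}] nA (rates [{r_lo:.1f}, {r_hi:.1f}] Hz)")
    mid, r_mid = 0.5 * (lo + hi), None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = rate_of(mid)
        if abs(r_mid - target_rate) <= tolerance:
            return mid
        if r_mid < target_rate:
            lo = mid
        else:
            hi = mid
    return mid


def dispersion_index(rate_hz: float, n_seconds: int, dt: float,
                     rng: np.random.Generator) -> float:
    """Variance/mean ratio of per-second spike counts of the Bernoulli-thinned process."""
    steps_per_s = int(round(1000.0 / dt))
    draws = rng.random((n_seconds, steps_per_s)) < rate_hz * dt / 1000.0
    counts = draws.sum(axis=1)
    return float(np.var(counts) / np.mean(counts))
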