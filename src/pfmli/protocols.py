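"""Stimulation protocols I-X and the coupled simulation loop.

Each protocol is a declarative phase schedule: per-fiber PF rate
schedules, clamp phases (free / voltage clamp / current injection,
the latter stated either as an explicit current, a holding potential,
or a firing-rate target resolved by calibration), and a gamma schedule
for the learning rule.  `run_protocol` executes the coupled per-step
loop (PF spike draws -> AMPA/NMDA kinetics -> membrane Euler step ->
spike detection -> activity traces -> weight update) via the compiled
kernel, deterministically for a given (spec, repeat_index).

Protocol summary (baseline PF rate 0.33 Hz, baseline MLI ~30 Hz):

  I    1 PF, 100 Hz/100 ms bursts every 1 s from 5 s; free MLI; 60 trials; LTP
  II   1 PF at 10 Hz from 5 s; MLI hyperpolarized to ~10 Hz from 2.5 s; LTD
  III  1 PF at 10 Hz from 5 s; MLI depolarized to ~40 Hz from 2.5 s; LTP
  IV   1 PF at 2 Hz from 5 s; free MLI; no remarkable change
  V    8 PFs at 50 Hz from 5 s; voltage clamp -60 mV from 2.5 s; LTD
  VI   8 PFs bursting 100 Hz/100 ms per s from 5 s; held near -80 mV; LTP
  VII  8 PFs at 2 Hz from 5 s; held near -80 mV; LTD
  VIII 8 PFs: 0.33 Hz under voltage clamp -60 mV for 5 s (weights start
       low), then 2 Hz with MLI depolarized to ~50 Hz for 60 s; LTP
  IX   8 PFs at 0.33 Hz; free MLI; gamma 1.0 -> 1.5 at 5 s for 10 min; LTD
  X    as IX with gamma 1.0 -> 0.5; LTP
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _kernel, stimuli
from .params import ModelParams
from .plasticity import equilibrium_weight
from .stimuli import RateSchedule, Segment, SpikeTrain

BASELINE_PF_RATE = 0.33   # Hz, "spontaneous" PF firing
RECORD_STRIDE_MS = 1.0    # time-series sampling interval

#: Expected plasticity direction of each registered protocol.
EXPECTED_OUTCOME = {
    "I": "LTP", "II": "LTD", "III": "LTP", "IV": "none", "V": "LTD",
    "VI": "LTP", "VII": "LTD", "VIII": "LTP", "IX": "LTD", "X": "LTP",
}

PROTOCOL_IDS = tuple(EXPECTED_OUTCOME)


@dataclass(frozen=True)
class ClampPhase:
    """Clamp state over [t_start, t_end) ms.

    mode is one of:
      free            unperturbed cell
      voltage_clamp   V pinned at `level` mV, spiking suppressed
      current_inject  constant `level` nA added
      hold_potential  constant current holding V near `level` mV
                      (g_leak*(V_hold - E_leak) minus the mean intrinsic drive)
      firing_target   constant current calibrated so the isolated cell
                      fires at `level` Hz
    """

    t_start: float
    t_end: float
    mode: str = "free"
    level: float = 0.0

    def __post_init__(self) -> None:
        valid = ("free", "voltage_clamp", "current_inject", "hold_potential",
                 "firing_target")
        if self.mode not in valid:
            raise ValueError(f"unknown clamp phase mode {self.mode!r}")
        if self.t_end <= self.t_start:
            raise ValueError("clamp phase must have t_end > t_start")


@dataclass(frozen=True)
class GammaPhase:
    t_start: float
    t_end: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be strictly positive")


@dataclass(frozen=True)
class ProtocolSpec:
    """Fully resolved simulation protocol."""

    id: str
    n_pf: int
    duration: float                     # ms
    pf_schedule: RateSchedule           # shared by all fibers (independent draws)
    clamp_phases: Tuple[ClampPhase, ...] = ()
    gamma_phases: Tuple[GammaPhase, ...] = ()
    trial_onset: float = 5000.0         # ms; "starting value" reference time
    trial_period: float = 1000.0        # ms per trial
    summary_interval: float = 1000.0    # ms between summary points
    n_repeats: int = 1
    base_seed: int = 7041               # combined with repeat_index per run
    w_hat_init: Union[str, float] = "equilibrium"
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.n_pf < 0 or self.duration <= 0 or self.n_repeats < 1:
            raise ValueError("invalid protocol dimensions")
        if isinstance(self.w_hat_init, str) and self.w_hat_init != "equilibrium":
            raise ValueError("w_hat_init must be a float or 'equilibrium'")
        if not isinstance(self.w_hat_init, str):
            if not (0.0 <= float(self.w_hat_init) <= 1.0):
                raise ValueError("w_hat_init must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        return int((self.duration - self.trial_onset) // self.trial_period)


@dataclass
class SimulationResult:
    """Recorded time series and spikes of one protocol repeat."""

    spec: ProtocolSpec
    repeat_index: int
    t_rec: np.ndarray           # ms, sample times
    V: np.ndarray               # mV
    mli_rate_hz: np.ndarray
    mli_xbar: np.ndarray
    w_hat: np.ndarray           # (n_rec, n_pf)
    pf_xbar: np.ndarray         # (n_rec, n_pf)
    mli_spike_times: np.ndarray
    pf_spikes: List[SpikeTrain]
    w_hat_start: np.ndarray     # initial per-synapse variable weights

    @property
    def w_eff(self) -> np.ndarray:
        """Effective per-synapse weight time series, w0 + (1 - w0) * w_hat."""
        w0 = self.spec.params.synapse.w0
        return w0 + (1.0 - w0) * self.w_hat

    def mean_weights_at(self, t_ms: float) -> Tuple[float, float]:
        """Across-synapse mean (w_eff, w_hat) at the recorded sample closest to t_ms."""
        j = int(np.searchsorted(self.t_rec, t_ms - 1e-9))
        j = min(j, len(self.t_rec) - 1)
        return float(self.w_eff[j].mean()), float(self.w_hat[j].mean())


# ---------------------------------------------------------------------------
# protocol registry

def _baseline_then(rate: float, t_switch: float, duration: float,
                   burst: Optional[Tuple[float, float, float]] = None) -> RateSchedule:
    segs = [Segment(0.0, t_switch, BASELINE_PF_RATE)]
    if burst is not None:
        br, bl, per = burst
        segs.append(Segment(t_switch, duration, rate, burst_rate=br,
                            burst_len=bl, period=per))
    else:
        segs.append(Segment(t_switch, duration, rate))
    return RateSchedule(tuple(segs))


def build_protocol(protocol_id: str, *, n_repeats: Optional[int] = None,
                   base_seed: int = 7041, pf_rate: Optional[float] = None,
                   w_hat_init: Optional[Union[str, float]] = None,
                   params: Optional[ModelParams] = None) -> ProtocolSpec:
    """Return the fully resolved spec for one of the registered protocols I-X.

    ``pf_rate`` overrides the post-onset PF rate where the protocol uses a
    constant rate (II-V, VII-X); ``w_hat_init`` overrides the initial
    variable weight component (default: the baseline equilibrium, except
    VIII which starts below it at 0.1).
    """
    pid = protocol_id.strip().upper()
    if pid not in PROTOCOL_IDS:
        raise ValueError(f"unknown protocol id {protocol_id!r}; expected one of {PROTOCOL_IDS}")
    params = params or ModelParams()
    D = 65000.0
    burst = (100.0, 100.0, 1000.0)   # 100 Hz for 100 ms every 1 s

    def rate(default: float) -> float:
        return default if pf_rate is None else float(pf_rate)

    kw: Dict = dict(base_seed=base_seed, params=params)
    if pid == "I":
        spec = ProtocolSpec("I", 1, D, _baseline_then(0.0, 5000.0, D, burst),
                            n_repeats=10, **kw)
    elif pid == "II":
        spec = ProtocolSpec("II", 1, D, _baseline_then(rate(10.0), 5000.0, D),
                            clamp_phases=(ClampPhase(2500.0, D, "firing_target", 10.0),),
                            n_repeats=10, **kw)
    elif pid == "III":
        spec = ProtocolSpec("III", 1, D, _baseline_then(rate(10.0), 5000.0, D),
                            clamp_phases=(ClampPhase(2500.0, D, "firing_target", 40.0),),
                            n_repeats=10, **kw)
    elif pid == "IV":
        spec = ProtocolSpec("IV", 1, D, _baseline_then(rate(2.0), 5000.0, D),
                            n_repeats=10, **kw)
    elif pid == "V":
        spec = ProtocolSpec("V", 8, D, _baseline_then(rate(50.0), 5000.0, D),
                            clamp_phases=(ClampPhase(2500.0, D, "voltage_clamp", -60.0),),
                            **kw)
    elif pid == "VI":
        spec = ProtocolSpec("VI", 8, D, _baseline_then(0.0, 5000.0, D, burst),
                            clamp_phases=(ClampPhase(2500.0, D, "hold_potential", -80.0),),
                            **kw)
    elif pid == "VII":
        spec = ProtocolSpec("VII", 8, D, _baseline_then(rate(2.0), 5000.0, D),
                            clamp_phases=(ClampPhase(2500.0, D, "hold_potential", -80.0),),
                            **kw)
    elif pid == "VIII":
        spec = ProtocolSpec("VIII", 8, D, _baseline_then(rate(2.0), 5000.0, D),
                            clamp_phases=(ClampPhase(0.0, 5000.0, "voltage_clamp", -60.0),
                                          ClampPhase(5000.0, D, "firing_target", 50.0)),
                            w_hat_init=0.1, **kw)
    elif pid in ("IX", "X"):
        D = 605000.0   # 5 s baseline + 10 min
        g = 1.5 if pid == "IX" else 0.5
        spec = ProtocolSpec(pid, 8, D,
                            RateSchedule((Segment(0.0, D, rate(BASELINE_PF_RATE)),)),
                            gamma_phases=(GammaPhase(5000.0, D, g),),
                            summary_interval=60000.0, **kw)
    if n_repeats is not None:
        spec = replace(spec, n_repeats=n_repeats)
    if w_hat_init is not None:
        spec = replace(spec, w_hat_init=w_hat_init)
    return spec


def list_protocols() -> pd.DataFrame:
    """Tabular registry of the built-in protocols."""
    rows = []
    for pid in PROTOCOL_IDS:
        spec = build_protocol(pid)
        rows.append({
            "protocol": pid,
            "n_pf": spec.n_pf,
            "duration_s": spec.duration / 1000.0,
            "n_repeats": spec.n_repeats,
            "expected": EXPECTED_OUTCOME[pid],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# schedule resolution

_CALIBRATION_CACHE: Dict[Tuple, float] = {}
_EQUILIBRIUM_CACHE: Dict[ModelParams, float] = {}

#: Dedicated seeds for calibration-time randomness (frozen, protocol-independent).
CALIBRATION_SEED = 20150
EQUILIBRIUM_SEED = 20151


def calibrated_current(params: ModelParams, target_rate: float, n_pf: int = 0,
                       pf_rate: float = 0.0, w_hat: float = 0.0) -> float:
    """Cached firing-rate-to-current calibration in the given synaptic context."""
    key = (params, float(target_rate), int(n_pf), float(pf_rate), float(w_hat))
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = stimuli.calibrate_injection(
            target_rate, params, seed=CALIBRATION_SEED, n_pf=n_pf,
            pf_rate=pf_rate, w_hat=w_hat)
    return _CALIBRATION_CACHE[key]


def hold_current(params: ModelParams, v_hold: float) -> float:
    """Constant current (nA) holding the cell near ``v_hold`` mV.

    Balances the leak at the holding potential and cancels the mean
    intrinsic drive: I = g_leak * (V_hold - E_leak) / 1000 - kappa * beta.
    """
    n = params.neuron
    return n.g_leak * (v_hold - n.E_leak) / 1000.0 - n.mean_intrinsic_current


def baseline_mli_activity(params: ModelParams, duration_ms: float = 5000.0) -> float:
    """Mean normalized MLI activity x_bar at spontaneous baseline (seed-fixed).

    Simulates the isolated cell for ``duration_ms`` and averages x_bar
    over the second half, after the trace has equilibrated.  Cached per
    parameter set.
    """
    if params not in _EQUILIBRIUM_CACHE:
        n_steps = int(round(duration_ms / params.dt))
        rng = np.random.default_rng(EQUILIBRIUM_SEED)
        ispont = rng.gamma(params.neuron.kappa, params.neuron.beta, n_steps)
        out = _kernel.simulate(
            params, np.zeros((n_steps, 0), dtype=np.uint8), ispont,
            np.zeros(n_steps, dtype=np.int8), np.zeros(n_steps),
            np.ones(n_steps), np.zeros(0),
            rec_every=max(1, int(round(RECORD_STRIDE_MS / params.dt))))
        xbar = out[2]
        _EQUILIBRIUM_CACHE[params] = float(xbar[len(xbar) // 2:].mean())
    return _EQUILIBRIUM_CACHE[params]


def resolve_w_hat_init(spec: ProtocolSpec) -> np.ndarray:
    """Initial per-synapse variable weights for a protocol."""
    if isinstance(spec.w_hat_init, str):   # "equilibrium"
        gamma0 = _gamma_at(spec, 0.0)
        w = equilibrium_weight(baseline_mli_activity(spec.params), gamma0)
    else:
        w = float(spec.w_hat_init)
    return np.full(spec.n_pf, w)


def _gamma_at(spec: ProtocolSpec, t: float) -> float:
    for ph in spec.gamma_phases:
        if ph.t_start <= t < ph.t_end:
            return ph.gamma
    return spec.params.plasticity.gamma


def _clamp_arrays(spec: ProtocolSpec, n_steps: int) -> Tuple[np.ndarray, np.ndarray]:
    dt = spec.params.dt
    mode = np.zeros(n_steps, dtype=np.int8)
    level = np.zeros(n_steps)
    t = np.arange(n_steps) * dt
    for ph in spec.clamp_phases:
        m = (t >= ph.t_start) & (t < ph.t_end)
        if ph.mode == "free":
            mode[m], level[m] = _kernel.CLAMP_FREE, 0.0
        elif ph.mode == "voltage_clamp":
            mode[m], level[m] = _kernel.CLAMP_VOLTAGE, ph.level
        elif ph.mode == "current_inject":
            mode[m], level[m] = _kernel.CLAMP_CURRENT, ph.level
        elif ph.mode == "hold_potential":
            mode[m], level[m] = _kernel.CLAMP_CURRENT, hold_current(spec.params, ph.level)
        elif ph.mode == "firing_target":
            # calibrate in the phase's synaptic context: the f-I curve shifts
            # with synaptic drive, and the stated rate is what the cell does
            # during the stimulation phase
            mid = 0.5 * (ph.t_start + ph.t_end)
            ctx_rate = spec.pf_schedule.rate_at(mid)
            ctx_w = float(resolve_w_hat_init(spec).mean()) if spec.n_pf else 0.0
            mode[m] = _kernel.CLAMP_CURRENT
            level[m] = calibrated_current(spec.params, ph.level, n_pf=spec.n_pf,
                                          pf_rate=ctx_rate, w_hat=ctx_w)
    return mode, level


def _gamma_array(spec: ProtocolSpec, n_steps: int) -> np.ndarray:
    dt = spec.params.dt
    g = np.full(n_steps, spec.params.plasticity.gamma)
    t = np.arange(n_steps) * dt
    for ph in spec.gamma_phases:
        g[(t >= ph.t_start) & (t < ph.t_end)] = ph.gamma
    return g


def repeat_rng(spec: ProtocolSpec, repeat_index: int) -> np.random.Generator:
    """Per-repeat generator: independent streams from (base_seed, repeat_index)."""
    return np.random.default_rng(np.random.SeedSequence([spec.base_seed, repeat_index]))


# ---------------------------------------------------------------------------
# execution

def run_protocol(spec: ProtocolSpec, repeat_index: int = 0) -> SimulationResult:
    """Execute one repeat of a protocol; deterministic for (spec, repeat_index)."""
    params = spec.params
    dt = params.dt
    n_steps = int(round(spec.duration / dt))
    rec_every = max(1, int(round(RECORD_STRIDE_MS / dt)))

    rng = repeat_rng(spec, repeat_index)
    spikes = stimuli.spike_raster(spec.pf_schedule, n_steps, dt, rng,
                                  n_fibers=spec.n_pf)
    ispont = rng.gamma(params.neuron.kappa, params.neuron.beta, n_steps)
    clamp_mode, clamp_level = _clamp_arrays(spec, n_steps)
    gamma_arr = _gamma_array(spec, n_steps)
    w_hat0 = resolve_w_hat_init(spec)

    V, rate, xbar, what, pfx, spike_steps = _kernel.simulate(
        params, spikes, ispont, clamp_mode, clamp_level, gamma_arr,
        w_hat0, rec_every)

    n_rec = len(V)
    t_rec = (np.arange(n_rec) + 1) * rec_every * dt
    pf_trains = [SpikeTrain(i, np.nonzero(spikes[:, i])[0] * dt)
                 for i in range(spec.n_pf)]
    return SimulationResult(
        spec=spec, repeat_index=repeat_index, t_rec=t_rec, V=V,
        mli_rate_hz=rate, mli_xbar=xbar, w_hat=what, pf_xbar=pfx,
        mli_spike_times=spike_steps * dt + dt, pf_spikes=pf_trains,
        w_hat_start=w_hat0)


def run_repeats(spec: ProtocolSpec) -> List[SimulationResult]:
    """Run all repeats of a protocol sequentially."""
    return [run_protocol(spec, r) for r in range(spec.n_repeats)]


# ---------------------------------------------------------------------------
# summaries

@dataclass(frozen=True)
class TrialSummary:
    """Across-repeat summary of weight change at one trial/summary boundary."""

    trial: int                 # 1-based
    t_ms: float
    mean_w: float              # across-repeat mean of the across-synapse mean w
    mean_w_hat: float
    pct_w_mean: float          # percent change of mean w from its value at trial_onset
    pct_w_min: float
    pct_w_max: float
    pct_w_hat_mean: float
    pct_w_hat_min: float
    pct_w_hat_max: float


def trial_table(results: Sequence[SimulationResult]) -> pd.DataFrame:
    """Tidy per-repeat, per-trial weight summary.

    "Starting value" is the across-synapse mean weight at trial_onset;
    percent change is relative to it, evaluated at the end of each
    summary interval (each trial for I-VIII, each minute for IX/X).
    """
    if not results:
        raise ValueError("need at least one simulation result")
    spec = results[0].spec
    boundaries = np.arange(spec.trial_onset + spec.summary_interval,
                           spec.duration + 1e-9, spec.summary_interval)
    rows = []
    for res in results:
        w_start, what_start = res.mean_weights_at(spec.trial_onset)
        for i, t in enumerate(boundaries, start=1):
            w, what = res.mean_weights_at(t)
            rows.append({
                "repeat": res.repeat_index, "trial": i, "t_ms": t,
                "mean_w": w, "mean_w_hat": what,
                "pct_change_w": 100.0 * (w / w_start - 1.0),
                "pct_change_w_hat": 100.0 * (what / what_start - 1.0)
                if what_start > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def summarize_trials(results: Sequence[SimulationResult]) -> List[TrialSummary]:
    """Across-repeat mean and min-max range of percent weight change per trial."""
    df = trial_table(results)
    out = []
    for trial, g in df.groupby("trial"):
        out.append(TrialSummary(
            trial=int(trial), t_ms=float(g["t_ms"].iloc[0]),
            mean_w=float(g["mean_w"].mean()),
            mean_w_hat=float(g["mean_w_hat"].mean()),
            pct_w_mean=float(g["pct_change_w"].mean()),
            pct_w_min=float(g["pct_change_w"].min()),
            pct_w_max=float(g["pct_change_w"].max()),
            pct_w_hat_mean=float(g["pct_change_w_hat"].mean()),
            pct_w_hat_min=float(g["pct_change_w_hat"].min()),
            pct_w_hat_max=float(g["pct_change_w_hat"].max()),
        ))
    return out


def classify_outcome(final: TrialSummary, threshold_pct: float = 5.0) -> str:
    """LTP / LTD / none from the final across-repeat mean percent change of w."""
    if final.pct_w_mean > threshold_pct:
        return "LTP"
    if final.pct_w_mean < -threshold_pct:
        return "LTD"
    return "none"


def run_and_classify(protocol_id: str, n_repeats: Optional[int] = None,
                     base_seed: int = 7041) -> Tuple[str, List[TrialSummary]]:
    """Convenience: run a registered protocol and classify its outcome."""
    spec = build_protocol(protocol_id, n_repeats=n_repeats, base_seed=base_seed)
    summaries = summarize_trials(run_repeats(spec))
    return classify_outcome(summaries[-1]), summaries
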