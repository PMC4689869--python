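"""Model parameter sets with published default values.

All times are in milliseconds, potentials in mV, conductances in nS,
capacitance in pF and currents in nA.  With those units the membrane
equation balances in pA, so currents expressed in nA are multiplied by
1000 inside the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class NeuronParams:
    """Membrane constants of the molecular layer interneuron (MLI).

    The cell is a conductance-based leaky integrate-and-fire neuron with
    an after-hyperpolarization (AHP) conductance in place of a hard
    voltage reset, and a stochastic intrinsic depolarizing current drawn
    each time step from a gamma distribution Gamma(kappa, beta) (beta is
    the *scale* parameter, so the mean drive is kappa*beta ~ 26.4 pA).
    """

    C: float = 14.6                # membrane capacitance (pF)
    V_threshold: float = -53.0     # spike threshold (mV)
    g_leak: float = 1.6            # leak conductance (nS)
    E_leak: float = -68.0          # leak reversal (mV)
    E_exc: float = 0.0             # excitatory reversal (mV)
    g_ahp_max: float = 50.0        # peak AHP conductance (nS)
    E_ahp: float = -82.0           # AHP reversal (mV)
    tau_ahp: float = 2.5           # AHP decay time constant (ms)
    kappa: float = 3.966333        # gamma-distribution shape
    beta: float = 0.006653         # gamma-distribution scale (nA)

    def __post_init__(self) -> None:
        for name in ("C", "g_leak", "g_ahp_max", "tau_ahp", "kappa", "beta"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(self.E_ahp < self.V_threshold < self.E_exc,
                 "require E_ahp < V_threshold < E_exc")

    @property
    def mean_intrinsic_current(self) -> float:
        """Mean of the intrinsic current distribution, kappa*beta (nA)."""
        return self.kappa * self.beta


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics of the PF->MLI synaptic conductances.

    AMPA: instantaneous rise, double-exponential decay with amplitudes
    alpha_fast + alpha_slow = 1, scaled per synapse by the effective
    weight w = w0 + (1 - w0) * w_hat.

    NMDA: pooled over the PF bundle (extrasynaptic, spillover-activated
    receptors), glutamate accumulator n with decay tau_n, open fraction R
    driven by log(n+1), and a voltage-dependent magnesium block
    (1 + rho * [Mg]_o * exp(sigma * V))^-1 with sigma < 0.
    """

    g_ampa_max: float = 3.0        # nS
    tau_fast: float = 0.8          # ms
    tau_slow: float = 18.0         # ms
    alpha_fast: float = 0.8
    alpha_slow: float = 0.2
    g_nmda_max: float = 1.0        # nS
    tau_rise: float = 3.0          # ms
    tau_decay: float = 40.0        # ms
    tau_n: float = 10.0            # ms
    rho: float = 1.0 / 3.57        # 1/mM
    mg_out: float = 1.2            # mM
    sigma: float = -0.062          # 1/mV
    w0: float = 0.2                # minimum (fixed) weight component

    def __post_init__(self) -> None:
        for name in ("g_ampa_max", "tau_fast", "tau_slow", "g_nmda_max",
                     "tau_rise", "tau_decay", "tau_n"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(self.tau_fast < self.tau_slow, "require tau_fast < tau_slow")
        _require(abs(self.alpha_fast + self.alpha_slow - 1.0) < 1e-9,
                 "AMPA kernel amplitudes must sum to one")
        _require(0.0 < self.w0 < 1.0, "w0 must lie in (0, 1)")
        _require(self.sigma < 0, "sigma must be negative (depolarization relieves block)")


@dataclass(frozen=True)
class TraceParams:
    """Difference-of-exponentials activity-trace kernel parameters.

    psi(t) = (exp(-t/tau_psi) - exp(-t/nu_psi)) / (tau_psi - nu_psi) has
    unit area, so convolving a spike train with psi estimates the firing
    rate in spikes/ms; the trace is scaled to Hz, truncated at f_max and
    divided by f_max to give the normalized activity x_bar in [0, 1].
    """

    tau_psi: float                 # slow time constant (ms)
    nu_psi: float                  # fast time constant (ms)
    f_max: float                   # normalizing maximum firing rate (Hz)

    def __post_init__(self) -> None:
        _require(self.nu_psi > 0, "nu_psi must be strictly positive")
        _require(self.tau_psi > self.nu_psi, "require tau_psi > nu_psi")
        _require(self.f_max > 0, "f_max must be strictly positive")


#: Published trace parameters for the postsynaptic MLI population.
MLI_TRACE = TraceParams(tau_psi=60.0, nu_psi=15.0, f_max=150.0)

#: Published trace parameters for the presynaptic parallel fibers.
PF_TRACE = TraceParams(tau_psi=10.0, nu_psi=2.0, f_max=300.0)


@dataclass(frozen=True)
class PlasticityParams:
    """Gated steepest descent parameters: d(w_hat)/dt = eta*PF*(MLI - gamma*w_hat)."""

    eta: float = 0.001             # learning rate (1/ms)
    gamma: float = 1.0             # dynamic-threshold scale

    def __post_init__(self) -> None:
        # eta = 0 freezes learning (used while calibrating injected currents)
        _require(self.eta >= 0, "eta must be non-negative")
        _require(self.gamma > 0, "gamma must be strictly positive")


#: Default integration time step (ms); forward Euler.
DT = 0.25


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all parameter sets used by a simulation run."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    mli_trace: TraceParams = field(default_factory=lambda: MLI_TRACE)
    pf_trace: TraceParams = field(default_factory=lambda: PF_TRACE)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    dt: float = DT

    def __post_init__(self) -> None:
        _require(self.dt > 0, "dt must be strictly positive")

    def with_overrides(self, overrides: Optional[dict] = None) -> "ModelParams":
        """Return a copy with flat ``key: value`` overrides applied.

        Keys are searched across the nested parameter sets; unknown keys
        raise ``ValueError`` naming the key.
        """
        if not overrides:
            return self
        out = self
        for key, value in overrides.items():
            if key == "dt":
                out = replace(out, dt=float(value))
                continue
            if "." in key:  # e.g. "pf_trace.tau_psi" disambiguates the two trace sets
                group, name = key.split(".", 1)
                if group not in ("neuron", "synapse", "plasticity", "mli_trace", "pf_trace"):
                    raise ValueError(f"unknown parameter group: {group!r}")
                out = replace(out, **{group: replace(getattr(out, group), **{name: float(value)})})
                continue
            hit = None
            for group in ("neuron", "synapse", "plasticity", "mli_trace", "pf_trace"):
                sub = getattr(out, group)
                if key in {f.name for f in fields(sub)}:
                    hit = group
                    break
            if hit is None:
                raise ValueError(f"unknown parameter override: {key!r}")
            out = replace(out, **{hit: replace(getattr(out, hit), **{key: float(value)})})
        return out
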