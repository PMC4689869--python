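# pfmli

Simulation of synaptic plasticity at cerebellar **parallel fiber (PF) →
molecular layer interneuron (MLI)** synapses: a conductance-based leaky
integrate-and-fire MLI with AMPA/NMDA input, normalized spike-activity
traces, and the **gated steepest descent** learning rule, together with
a registry of in-silico electrophysiology protocols that reproduce the
classic in vitro LTP/LTD induction experiments at this synapse.

The package is aimed at computational neuroscientists studying
cerebellar learning: it provides both a Python API (the `pfmli` module)
and a small command-line tool (`pfmli`) for running protocols, sweeping
parameters and exporting spike trains, membrane-potential traces and
trial-wise weight summaries.

## The model

**Neuron.** The MLI is a conductance-based leaky integrate-and-fire cell,

```
C dV/dt = −g_leak (V − E_leak) − g_ahp(t) (V − E_ahp)
          − (g_AMPA(t) + g_NMDA(t)) (V − E_exc) + I_spont(t)
```

with `I_spont ~ Γ(κ, β)` redrawn every step (mean κβ ≈ 26.4 pA), which
makes the isolated cell fire tonically near 30 Hz.  There is no hard
reset: on threshold crossing a spike is registered and an
after-hyperpolarization conductance `g_ahp(t) = ḡ_AHP e^{−(t−t_spiked)/τ_AHP}`
repolarizes the membrane toward E_AHP.

**Synapses.** Each PF drives a per-synapse AMPA conductance with
instantaneous rise and double-exponential decay
(`α(t) = 0.8 e^{−t/0.8ms} + 0.2 e^{−t/18ms}`), scaled by the effective
weight `w = w0 + (1 − w0) ŵ ∈ [w0, 1]`.  NMDA receptors are
extrasynaptic and spillover-activated, so their state is pooled over
the PF bundle: a glutamate accumulator `n(t)` integrates all PF spikes,
the open fraction follows `dR/dt = log(n+1)(1−R)/τ_rise − R/τ_decay`,
and the conductance carries the voltage-dependent magnesium block
`(1 + ρ[Mg²⁺]_o e^{σV})⁻¹`.

**Traces and plasticity.** Each population's spiking is smoothed by a
unit-area difference-of-exponentials kernel, truncated at a maximum
rate f_max and normalized to the activity trace `x̄ ∈ [0,1]`.  The
variable weight component evolves by gated steepest descent,

```
dŵ/dt = η · PF̄(t) · [ MLĪ(t) − γ ŵ ]
```

presynaptic activity gates learning, and `γŵ` is a dynamic threshold:
LTP while `MLĪ > γŵ`, LTD below, so `ŵ` chases `MLĪ/γ` and never blows
up.  `γ` models the "basal tone" set by tonic metabotropic receptor
(mGluR1/GABA_B) activity.

All differential equations are advanced by forward Euler at dt = 0.25 ms;
the linear kernel states use exact per-step decay factors.

## Protocols

`build_protocol("I")` … `build_protocol("X")` return declarative phase
schedules covering burst-driven LTP, paired current-injection LTP/LTD,
voltage-clamp LTD, current-clamp burst LTP, and basal-tone (γ) shifts:

| id | stimulus | postsynaptic condition | outcome |
|----|----------|------------------------|---------|
| I   | 1 PF, 100 Hz/100 ms bursts each 1 s | spontaneous (~30 Hz) | LTP |
| II  | 1 PF, 10 Hz | hyperpolarized to ~10 Hz | LTD |
| III | 1 PF, 10 Hz | depolarized to ~40 Hz | LTP |
| IV  | 1 PF, 2 Hz | spontaneous | — |
| V   | 8 PFs, 50 Hz | voltage clamp −60 mV | LTD |
| VI  | 8 PFs, bursts | held near −80 mV | LTP |
| VII | 8 PFs, 2 Hz | held near −80 mV | LTD |
| VIII| 8 PFs, 2 Hz (weights start low) | depolarized to ~50 Hz | LTP |
| IX  | 8 PFs, 0.33 Hz | spontaneous, γ → 1.5 for 10 min | LTD |
| X   | 8 PFs, 0.33 Hz | spontaneous, γ → 0.5 for 10 min | LTP |

Current-injection levels stated as firing-rate targets are resolved by
bisection against simulated rates in the protocol's own synaptic
context (`calibrate_injection`).

## Worked example

```python
from pfmli import build_protocol, run_repeats, summarize_trials, classify_outcome

spec = build_protocol("I", n_repeats=3)          # burst-driven LTP
summaries = summarize_trials(run_repeats(spec))
final = summaries[-1]
print(f"final mean w = {final.mean_w:.3f} ({final.pct_w_mean:+.1f}%)")
print(classify_outcome(final))
```

prints

```
final mean w = 0.432 (+21.6%)
LTP
```

i.e. after 60 one-second burst trials the effective synaptic weight has
risen about 20% above its starting value (it started at the baseline
equilibrium w = 0.2 + 0.8·0.194 ≈ 0.36) and the run is classified as
long-term potentiation.  The same protocol from the shell:

```bash
pfmli simulate --protocol I --repeats 10 --seed 7041 --out run_I/
pfmli summarize run_I/
```

The `examples/` directory holds short narrative scripts, one per
capability (spontaneous firing, burst LTP, voltage-clamp LTD,
basal-tone shifts, custom protocols).

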