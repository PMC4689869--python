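# Methods

This note documents the model implemented by `pfmli`, its numerical
choices, the design decisions taken where the problem was genuinely
open, and the limits of what the simulated protocols show.

## Neuron model

The molecular layer interneuron (MLI) is a single-compartment
conductance-based leaky integrate-and-fire cell:

C dV/dt = −g_leak(V − E_leak) − g_ahp(t)(V − E_ahp) − (g_AMPA + g_NMDA)(V − E_exc) + I_spont(t)

| parameter | value | meaning |
|---|---|---|
| C | 14.6 pF | membrane capacitance |
| V_threshold | −53 mV | spike threshold |
| g_leak, E_leak | 1.6 nS, −68 mV | leak conductance and reversal |
| E_exc | 0 mV | excitatory reversal |
| ḡ_AHP, E_AHP, τ_AHP | 50 nS, −82 mV, 2.5 ms | after-hyperpolarization |
| κ, β | 3.966333, 0.006653 nA | intrinsic current Γ(κ, β) |

Units: with V in mV, g in nS, C in pF and t in ms, every term of the
membrane equation is in pA; currents carried in nA are multiplied by
1000 inside the integrator.

**Intrinsic current.** `I_spont` is redrawn independently every time
step from a gamma distribution with shape κ and *scale* β (mean
κβ ≈ 26.4 pA).  The scale reading is the only one consistent with the
physiology: it depolarizes the cell to a subthreshold-noise regime with
steady state E_leak + κβ/g_leak = −51.5 mV, just past the −53 mV
threshold, producing tonic firing at ≈ 29–30 Hz (measured 29.2 Hz over
5 × 60 s).  A rate reading would imply a ~600 nA drive.

**No hard reset.** Spike emission registers at most one spike per step
and sets the AHP clock; repolarization is carried entirely by the AHP
conductance, which is computed from the most recent spike only (not
summed over history).  With the published magnitudes the 50 nS AHP
repolarizes ~25 mV within one step, playing the role of a reset while
keeping the dynamics purely conductance-based.  No absolute refractory
period is imposed.

**Clamp modes.** Voltage clamp pins V at the command potential and
suppresses spiking (the clamped cell emits zero spikes by construction).
Current injection adds a constant bias.  Two conveniences mirror the
experimental literature: `hold_potential` computes the current holding
the cell near a potential (g_leak·(V_hold − E_leak) minus the mean
intrinsic drive), and `firing_target` calibrates the current to a
stated firing rate (below).

## Synaptic conductances

**AMPA** (per synapse): instantaneous rise, double-exponential decay
α(t) = 0.8·e^(−t/0.8 ms) + 0.2·e^(−t/18 ms), peak conductance
ḡ_AMPA = 3 nS scaled by the effective weight w.  The kernel is realized
as two first-order states with exact per-step decay exp(−dt/τ) and
additive spike increments — on the grid this equals convolution of the
spike train with α (verified against a brute-force convolution oracle
to 1e−9 relative).

**NMDA** (pooled): MLI NMDA receptors are extrasynaptic and activated
by glutamate spillover, so a single accumulator serves the whole PF
bundle: n(t) decays with τ_n = 10 ms and gains 1 per PF spike; the open
fraction follows dR/dt = log(n+1)(1−R)/τ_rise − R/τ_decay
(τ_rise = 3 ms, τ_decay = 40 ms; the logarithm tames the drive at high
n), clipped to [0,1] against Euler overshoot.  The conductance is
ḡ_NMDA·R·(1 + ρ[Mg²⁺]_o·e^(σV))⁻¹ with ρ = (3.57 mM)⁻¹,
[Mg²⁺]_o = 1.2 mM and σ = −0.062 mV⁻¹, the standard phenomenological
magnesium block (larger at hyperpolarized potentials, monotonically
relieved by depolarization; 0.748 nS fully open at 0 mV vs 0.042 nS at
−68 mV).  Two deliberate choices: NMDA state is **pooled**, not
per-synapse, and the NMDA conductance is **not** scaled by synaptic
weight — weights act on AMPA only, consistent with the spillover
picture.

**Weights.** w = w0 + (1 − w0)·ŵ with floor w0 = 0.2 and variable
component ŵ ∈ [0,1]; hence w ∈ [0.2, 1] always.

## Activity traces

Each population's spike train is convolved with the unit-area kernel
ψ(t) = (e^(−t/τ_ψ) − e^(−t/ν_ψ))/(τ_ψ − ν_ψ); MLI: τ_ψ = 60 ms,
ν_ψ = 15 ms, f_max = 150 Hz; PF: τ_ψ = 10 ms, ν_ψ = 2 ms,
f_max = 300 Hz.  With time in ms the convolution estimates spikes/ms,
so it is multiplied by 1000 before comparison with f_max — the only
scaling under which the baseline MLI trace lands at ≈ 30/150 = 0.2 and
the normalization bound is meaningful.  Truncation at f_max happens
*before* division by f_max, so x̄ ∈ [0,1] is guaranteed, not merely
asymptotic.  The state-space form (two exponential accumulators with
per-spike unit increments) reproduces the convolution exactly on the
grid; because ψ has unit area the un-truncated trace is an unbiased
rate estimate (checked against Poisson trains at 10–100 Hz).

## Plasticity rule

dŵ/dt = η·PF̄·(MLĪ − γŵ), η = 0.001 ms⁻¹, γ = 1 unless scheduled.
The update runs every time step (the traces already carry spike
timing), Euler-stepped and clipped to [0,1].  η carries units of 1/ms,
the simulation clock's unit; with constant traces the discrete
recursion has closed form ŵ_k = ŵ* + (ŵ_0 − ŵ*)(1 − dt·η·PF̄·γ)^k with
fixed point ŵ* = clip(MLĪ/γ, 0, 1), which the tests recover to 1e−6.
γ is a piecewise-constant schedule to realize the basal-tone protocols.

A consequence worth noting: under stochastic activity the rule's true
fixed point is the PF-gated average E[PF̄·MLĪ]/(γ·E[PF̄]), which sits
slightly above MLĪ/γ because PF spikes transiently raise MLI firing.
The basal-tone protocols converge toward this weighted fixed point with
time constant 1/(η·γ·E[PF̄]) — ~606 s for γ = 1.5 at 0.33 Hz PF input —
and the test suite checks the trajectory against this self-consistent
closed form rather than the idealized target.

## Stimuli and calibration

PF spikes are Bernoulli-thinned Poisson trains on the dt grid
(p = rate·dt/1000, valid for rate·dt ≤ 1; dispersion index of
per-second counts ≈ 1).  Burst schedules ("100 Hz for 100 ms every
1 s") place the burst in the first 100 ms of each window; the rate
outside the burst window is 0 (the off-burst rate is configurable).
The baseline "spontaneous" PF rate is 0.33 Hz.

Protocols stating firing-rate targets ("depolarize to ~40 Hz") are
resolved to constant currents by monotone bisection on 30 s simulated
runs (tolerance 1 Hz, dedicated frozen seed, cached).  Calibration runs
include the protocol's stimulation-phase synaptic context — n_pf fibers
at the phase rate with weights frozen at their initial value — because
the synaptic drive shifts the f-I curve substantially (holding a cell
at 10 Hz against a 10 Hz PF input needs visibly more hyperpolarization
than holding an isolated cell).  Plasticity is disabled (η = 0) during
calibration so weights do not drift.

## Protocol bookkeeping

Time step dt = 0.25 ms throughout; time series are recorded every 1 ms;
spike times and per-synapse weights are kept in full.  Each repeat uses
an independent stream from SeedSequence(base_seed, repeat_index), and
identical (spec, repeat) reruns are bit-identical.  Trials are the 1 s
intervals starting at trial onset (5 s in the standard protocols);
"starting value" means the across-synapse mean weight at trial onset,
and percent changes are reported for both the effective weight w and
the variable component ŵ.  Classification uses the final across-repeat
mean percent change of **w** (the plotted "synaptic strength") with a
±5% dead band.  The basal-tone protocols are summarized per minute
rather than per trial.  Repeats default to 10 for protocols I–IV and 1
for V–X, all configurable.

Weight initialization "near equilibrium" is computed, not assumed: a
seed-fixed 5 s isolated-cell run measures the baseline MLI activity
(≈ 0.194) and ŵ_0 = clip(MLĪ_baseline/γ(0), 0, 1).  Protocol VIII
starts below equilibrium (ŵ_0 = 0.1, configurable) to represent the
weight depression accumulated during its long voltage-clamp induction
period; its real-world counterpart depolarizes the cell to 0 mV, which
a spike-driven activity trace cannot represent, so — like the original
simulation design — the protocol injects current to make the cell fire
at ~50 Hz as a surrogate.

Where the protocol descriptions conflict on PF rates (VII: 1 vs 2 Hz;
IX/X: 1 vs 0.33 Hz) the package defaults to 2 Hz and 0.33 Hz
respectively, with a `pf_rate` override exposed on `build_protocol`.

## Numerical choices

- Forward Euler at dt = 0.25 ms for the nonlinear states (V, R);
  exact exponential decay factors for all linear kernel states (AMPA,
  n, traces).  Halving dt changes the 60 s spontaneous spike count by
  well under 10%.
- The coupled per-step loop is JIT-compiled (numba); the public
  single-step operations are plain Python and the compiled loop is
  cross-checked against their composition to ~1e−10 on mixed-clamp runs
  with shared pre-drawn randomness.
- All randomness is drawn outside the kernel from numpy Generators, so
  results are reproducible across the compiled and reference paths.
- Guards: R and ŵ clipped to [0,1]; the rate trace floored at 0 against
  floating-point noise; non-finite membrane potential aborts with a
  diagnostic.
- Spikes arriving mid-step are treated as arriving at the step boundary
  (0.25 ms resolution); at most one spike per neuron per step.

## What the simulations do and do not show

The synthetic stimulation protocols match the published in-silico
experimental conditions (rates, burst structure, clamp levels,
durations, repeat counts), and the quantitative endpoints — ~30 Hz
spontaneous rate, ~+20% burst-driven potentiation, decay to the weight
floor under voltage clamp, and the LTP/LTD direction of all ten
protocols — emerge from the dynamics rather than being fitted.  The
individual weight trajectories under Poisson input are stochastic and
are validated through properties (bounds, convergence rates, direction)
rather than point-wise curves.

The model is phenomenological: calcium signaling, AMPA-receptor
phenotype composition, metabotropic cascades and presynaptic release
are summarized by traces, w and γ, not simulated; inhibitory input to
the MLI is deliberately absent (the protocols emulate pharmacological
isolation); granule cells are not modeled (PFs are Poisson sources);
and weight changes take effect instantaneously, whereas biological
efficacy changes develop over minutes.  Conclusions therefore apply to
the in vitro-like single-cell setting, not to network or in vivo
conditions.
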