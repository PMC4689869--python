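"""Voltage-clamp LTD (protocol V) — weights decay to the floor w0.

Eight parallel fibers fire 50 Hz Poisson trains onto an MLI held in
voltage clamp at -60 mV.  The clamp suppresses spiking, so the MLI
activity trace is ~0 while the PF traces are high: the learning rule is
gated on with a negative drive and the variable weight component decays
to zero, leaving the effective weight at its floor w0 = 0.2.
"""

from pfmli import build_protocol, run_protocol

spec = build_protocol("V")
res = run_protocol(spec, repeat_index=0)

for t in (2500.0, 5000.0, 15000.0, 30000.0, 65000.0):
    w, w_hat = res.mean_weights_at(t)
    print(f"t = {t / 1000:5.1f} s: mean w_hat = {w_hat:.4f}, mean w = {w:.4f}")
n_spikes_clamped = (res.mli_spike_times > 2500.0).sum()
print(f"MLI spikes after clamp onset: {n_spikes_clamped}")
print(f"-> w converges to the minimum weight w0 = {spec.params.synapse.w0}:")
print("   plasticity cannot silence the synapse completely, only shrink its")
print("   variable component to zero.")
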