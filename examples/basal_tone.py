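"""Basal tone modulation (protocols IX and X).

gamma scales the dynamic plasticity threshold gamma*w_hat and models the
tonic activity of metabotropic receptors (mGluR1/GABA_B) that sets the
"basal tone" of the synapse.  Raising gamma to 1.5 makes the baseline
MLI activity fall below threshold -> gradual LTD; lowering it to 0.5
does the opposite -> LTP.  PFs and MLI fire at baseline throughout; the
gamma step happens at 5 s and lasts 10 simulated minutes.
"""

from pfmli import build_protocol, classify_outcome, run_repeats, summarize_trials

for pid, gamma in (("IX", 1.5), ("X", 0.5)):
    spec = build_protocol(pid)
    summaries = summarize_trials(run_repeats(spec))
    final = summaries[-1]
    print(f"protocol {pid} (gamma -> {gamma}):")
    for s in summaries:
        print(f"  minute {s.trial:2d}: mean w_hat = {s.mean_w_hat:.4f} "
              f"({s.pct_w_mean:+6.2f}% in w)")
    print(f"  outcome: {classify_outcome(final)}")
print("-> the weights drift toward the new equilibrium ~ MLI_bar/gamma; the")
print("   drift is slow because baseline PF activity (0.33 Hz) provides only")
print("   a weak gate for the learning rule.")
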