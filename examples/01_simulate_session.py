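"""Generate one synthetic penetration and inspect its structure.

A session emulates ~16 laminar probe sites recorded at 1 kHz during a
two-stimulus adaptation paradigm: 500 ms adapter, 500 ms blank, 500 ms test,
with repetition (AA/BB) and alternation (AB/BA) sequences interleaved under
the constraint that a trial's adapter differs from the previously shown
stimulus.
"""

import adaptdecode as ad

config = ad.SimulationConfig(n_sites=16, n_trials_per_sequence=30, seed=42)
session = ad.generate_session(config)

print(f"LFP tensor: {session.lfp.shape}  (trials x sites x samples at "
      f"{session.sampling_rate:.0f} Hz)")
print(f"Spike counts: {session.spikes.shape}  (trials x sites x epochs)")
print("\nSequence counts (equal by design):")
print(session.trials["sequence_type"].value_counts().to_string())

adapters = session.trials["adapter_stim"].to_numpy()
tests = session.trials["test_stim"].to_numpy()
violations = int((adapters[1:] == tests[:-1]).sum())
print(f"\nSequencing-constraint violations (adapter == previous test): "
      f"{violations}")
print("Every trial's adapter differs from the stimulus the monkey saw last.")
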