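"""Decode stimulus identity per frequency band and stimulus condition.

For one penetration, a linear SVM is trained on z-normalized per-site band
power to classify stimulus A vs B, separately for the four conditions
(Adapter, Test in repetition trials, Test in alternation trials, Test after
the same adapter), with the per-class trial count equalized across
conditions (N_tot) and 1000-fold resampled half/half cross-validation
(reduced here for speed).
"""

import numpy as np
import pandas as pd

import adaptdecode as ad
from adaptdecode.pipeline import ExperimentConfig, analyze_session

sim = ad.SimulationConfig(n_sites=12, n_trials_per_sequence=30, seed=5)
config = ExperimentConfig(
    simulation=sim,
    bands=("alpha", "beta", "high_gamma"),
    n_classifiers=100,
    include_mua=True,
)
session = ad.generate_session(sim)
rows, info = analyze_session(session, config, np.random.default_rng(5))

print(f"N_tot (equalized trials per class): {info['n_tot']}")
table = pd.DataFrame(rows).pivot(
    index="band", columns="condition", values="mean_accuracy"
)
print("\nMean cross-validated accuracy (% correct):")
print(table.round(1).to_string())
print("\nHigh-gamma and MUA accuracies drop for repeated test stimuli "
      "(Test_rep) relative to the adapter — the repetition-suppression "
      "signature — while Test_sameAdapter benefits from the contrast "
      "between a suppressed and a fresh stimulus.")
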