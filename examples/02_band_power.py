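"""Preprocess a session and compute Morlet band power per trial and site.

The pipeline notch-filters the LFP (48-52 Hz zero-phase Butterworth
band-stop), rejects trials whose signal leaves the central 1-99 % of the
declared input range, convolves each trace with complex Morlet wavelets
(f0/sigma_f = 7) and averages power in the 60-310 ms poststimulus window
within five canonical bands.
"""

import adaptdecode as ad

config = ad.SimulationConfig(n_sites=8, n_trials_per_sequence=20, seed=1)
session = ad.generate_session(config, with_spikes=False)

params = ad.PreprocessParams(input_range=tuple(config.input_range))
kept, report = ad.reject_clipped_trials(
    session.lfp, session.trials["trial_id"].to_numpy(), params
)
print(f"kept {len(kept)}/{session.n_trials} trials "
      f"({len(report)} rejected for clipping)")

lfp = ad.notch_filter(session.lfp, config.sampling_rate, params)
bpt = ad.compute_band_power(
    lfp,
    config.sampling_rate,
    session.trials["trial_id"].to_numpy(),
    epoch_onsets_ms={
        "adapter": config.adapter_onset_ms,
        "test": config.test_onset_ms,
    },
)

print("\nMean band power (a.u.^2) by band and epoch, averaged over trials "
      "and sites:")
print(
    bpt.table.groupby(["band", "epoch"], sort=False)["power"]
    .mean()
    .unstack()
    .round(2)
    .to_string()
)
print("\nTest-epoch gamma power sits below adapter power: the generator's "
      "repetition/cross-adaptation gains suppress repeated stimuli most "
      "strongly at gamma frequencies.")
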