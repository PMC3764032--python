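# Methods

`adaptdecode` implements a complete analysis chain for two-class stimulus
decoding from multi-site local field potentials (LFPs) in a short-term
adaptation paradigm, together with a synthetic-session generator that makes
every stage testable without access to recordings.

## Paradigm and data model

A *session* (one probe penetration) contains trials of four sequence types.
Each trial presents an adapter stimulus for 500 ms, a 500 ms blank
inter-stimulus interval, and a test stimulus for 500 ms; the two stimuli are
either identical (repetition trials AA, BB) or different (alternation trials
AB, BA).  Trial order is pseudorandomized under the constraint that a
trial's adapter always differs from the last stimulus of the preceding
trial.  The LFP is a `trials x sites x time` tensor sampled at 1 kHz;
optional per-epoch spike counts provide a multi-unit-activity (MUA)
comparator.  The default trace spans 500 ms pre-stimulus baseline, the
1500 ms stimulus sequence and 500 ms post-stimulus, so the analysis windows
of both epochs stay clear of wavelet edge effects (see below).

## Synthetic LFP generator

Each site's trace is the sum of three components:

1. **1/f^a background** (default a = 1, amplitude 6 a.u. rms), synthesized
   by shaping a white Gaussian spectrum and inverse-transforming;
2. **50 Hz line noise** (default amplitude 2 a.u., random phase per trial
   and site);
3. **band-limited stochastic oscillations**: per canonical band
   (alpha 8-12, beta 13-30, low gamma 31-60, middle gamma 61-100, high
   gamma 101-170 Hz), white noise filtered with a 4th-order Butterworth
   band-pass, normalized to unit variance and multiplied by an amplitude
   envelope.  During a stimulus epoch the envelope equals
   `sqrt(band_gains[band][stimulus] * modifier * jitter)`; between epochs it
   sits at a baseline (default 25 % of the mean stimulus gain).  Envelope
   transitions are raised-cosine ramps of 20 ms so that no step artifacts
   are introduced (the 60 ms analysis-window onset skips evoked transients
   in the real paradigm anyway).

The *modifier* realizes adaptation: in the test epoch of repetition trials
band power is multiplied by `repetition_gain[band]` (< 1 = repetition
suppression; defaults 0.95/0.95/0.90/0.75/0.65 from alpha to high gamma),
in alternation trials by `cross_adaptation_gain[band]` (default 0.95).
With both maps set to 1 the generative law for test epochs equals that for
adapter epochs exactly, which the tests exploit as an exchangeability null.

Two kinds of variability make sites and trials partially independent:
per-site selectivity jitter (lognormal, sd 0.20 on the log scale, drawn
once per session for each band x stimulus x site) and trial-to-trial power
variability split into a component shared across sites (lognormal sd 0.25)
and a private per-site component (sd 0.35).

**Choice of default gains.**  The band gains are free parameters; no
quantitative per-band spectra are available for calibration.  They were
fixed once so that a default 16-site session decodes in the
60-80 % range with low-frequency bands above gamma, the regime reported for
IT cortex LFPs.  The structurally important choice is that gamma oscillation
power (3-5 a.u.^2) is of the same order as the 1/f background power inside
the gamma bands, while alpha/beta power (11 a.u.^2) sits well above its
in-band background.  This matters because decoding uses per-site
z-normalized features: a multiplicative power change common to both stimuli
is invisible after normalization, so repetition suppression reduces
decodability only by pushing the stimulus-specific signal toward the
additive background floor — the synthetic analogue of the SNR loss that
makes suppression costly in real recordings.

Spike counts are Poisson with stimulus- and site-specific rates (defaults
29 Hz for the preferred and 24 Hz for the non-preferred stimulus over the
250 ms analysis window) and a test-epoch rate multiplied by
`spike_adaptation_factor` (default 0.7) in repetition trials.

Aborted trials are generated with configurable probability (default 0) and
flagged; they are excluded from every analysis.  The sequencing constraint
is applied to the planned stimulus sequence (as if fixation breaks occurred
after the test stimulus).  Everything is deterministic given the config
seed.

## Preprocessing

* **Notch filter**: Butterworth band-stop 48-52 Hz, overall transfer-
  function order 4 (design order 2), applied zero-phase
  (forward-backward) so the analysis-window alignment is not shifted.  The
  notch is specified in the source literature as a "Butterworth FIR"
  filter, which is contradictory (Butterworth designs are IIR); we
  implement the IIR band-stop rather than guess an FIR design.
* **Clipping rejection**: a trial is excluded iff any sample on any
  analyzed site falls below 1 % or above 99 % of the *declared* acquisition
  input range.  The range must be declared in the parameters; it is never
  inferred from the data, because an amplifier that clips also distorts the
  observed extrema.
* **Analysis window**: 60-310 ms post stimulus onset, half-open
  `[onset+60, onset+310)`, exactly 250 samples at 1 kHz.  The printed
  source range "from 60 till 310 ms" is inclusive-ambiguous; the half-open
  convention makes the window length exact.

## Spectral estimation

Time-varying power is `|w_f * x|^2` for complex Morlet wavelets with a
constant center-frequency to spectral-bandwidth ratio `f0/sigma_f = 7`, f0
on the integer grid 1-170 Hz.  Implementation choices:

* unit-energy (L2) normalization per wavelet.  The literature leaves the
  normalization open; it only rescales per-frequency power and cannot
  change within-band classification, which is invariant to per-feature
  scaling after z-normalization;
* support truncated at +-4 temporal standard deviations (Gaussian tail
  < 1e-4);
* convolution via frequency-domain multiplication, contractually identical
  to direct convolution within 1e-10 relative tolerance (tested);
* samples within 3 sigma_t of either trace end are flagged
  edge-contaminated; frequencies whose support (6 sigma_t) exceeds the
  trace are flagged invalid as a whole rather than silently returned.  The
  wavelet transform runs on the full trial trace and the window is applied
  to the power time series afterwards; band averaging refuses windows that
  touch flagged samples.

Band power is the arithmetic mean over the integer grid frequencies inside
a band (edges inclusive: beta = {13, ..., 30}; the printed ranges partition
8-170 Hz exactly under the inclusive reading) and over the window samples,
one scalar per trial x site x band x epoch.

The session-level path (`compute_band_power`) performs the identical
computation vectorized over traces with chunked FFTs in single precision
(relative error ~1e-6, double precision available via `dtype`); FFT lengths
are rounded up to 5-smooth integers because sizes with large prime factors
degrade single-precision FFT throughput badly.

## Decoding protocol

Four stimulus conditions are built from the trial table: **Adapter**
(adapter epochs, scored separately for repetition and alternation trials),
**Test_rep** (test epochs, AA vs BB), **Test_alt** (test epochs, AB vs BA,
class = test stimulus), **Test_sameAdapter** (AA vs AB and BB vs BA, scored
separately).  Conditions with two sub-datasets average their two scores
with equal weight after a two-sided Wilcoxon check that they do not differ
(warning, not error, if they do — the averages are returned regardless with
the verdict logged).

`N_tot`, the per-class trial count used everywhere, is the largest even
integer not exceeding the smallest per-class count over all sub-datasets
("floor-to-even of the minimum"), guaranteeing an exact half/half split in
every condition; penetrations with N_tot < 4 are rejected.  Each of the
(default 1000) classifier repetitions draws N_tot trials per class without
replacement from the full pool, uses half for training and half for
testing (re-sampled cross-validation, not a fixed partition), z-normalizes
per site with training statistics only (a zero-variance site is set to 0 in
both sets — a constant feature carries no information), trains a linear
soft-margin SVM with unit cost, and scores the held-out half; a decision
value of exactly 0 counts as half correct (unbiased, measure-zero event).
The SVM cost and tie handling are declared package decisions; the optimizer
tolerance is set to 1e-8 so the solution matches the exact QP optimum.

The **label-shuffle control** re-runs the identical pipeline after randomly
permuting class labels across the trials of each sub-dataset, once per
permutation.  Its mean accuracy is the empirical chance level; averaged
over permutations it is 50 % by symmetry.  (A fixed labeling of a finite
null dataset, by contrast, has a dataset-specific cross-validated accuracy
a few points away from 50 — resampled splits of the same pool are
anticorrelated with the training draw — which is why the chance-level
tests average over permutations or datasets.)

**Site subsampling** keeps `round(n_sites/3)` sites, evenly spaced along
the probe by default (deterministic) or randomly with a seed.  Which sites
the original study kept is not stated; even spacing preserves the laminar
coverage.  **MUA decoding** feeds raw spike counts from the analysis window
through the identical pipeline under the band label "MUA".

## Group statistics

Penetrations are the unit of replication.  One- and two-way
repeated-measures ANOVAs (statsmodels `AnovaRM` backend) report uncorrected
degrees of freedom by default — consistent with the source analyses — with
an optional Greenhouse-Geisser correction (one-way designs; Box epsilon
from the sample covariance of the levels).  A zero-variance effect is
reported as F = 0, p = 1.  Bonferroni post-hoc comparisons use the pooled
within-subject error term (`t = (m_i - m_j) / sqrt(2 MS_err / n)` on the
ANOVA error degrees of freedom; the exact post-hoc variant is unstated in
the source, and the pooled term is the common default) with p multiplied by
the number of comparisons and capped at 1.  The Wilcoxon matched-pairs
test drops zero differences, uses the exact signed-rank null for n <= 25
without rank ties and the normal approximation with continuity correction
otherwise; all-zero differences return p = 1 with a flag.

## Problem sizes in the test suite

The acceptance-grade checks run at sizes chosen to keep the full suite
fast while leaving the tested effects unambiguous: the shuffle-null check
uses one default penetration (16 sites, 120 trials per sequence type, 500
permutations, 60 test trials per class); the planted-suppression recovery
uses 20 penetrations of 8 sites and 40 trials per sequence with
repetition gains 0.5/0.4 in middle/high gamma, unit gains elsewhere, unit
cross-adaptation and 200 classifiers per condition; the statistical
calibration uses 1000 null simulations at 32 penetrations.  Pilot runs at
these sizes showed per-penetration high-gamma repetition deficits of 4-6
accuracy points, far above the paired-test detection threshold at n = 20.

## What the synthetic sessions do and do not show

The generator reproduces the features the analysis depends on: stimulus-
selective band power with realistic trial variability, band-specific
multiplicative repetition suppression, cross-adaptation, partially
independent sites, 1/f background, line noise and Poisson spiking.  It does
not model evoked transients or phase-locked components, laminar depth
structure, current-source geometry, oscillatory bursts, eye-movement
artifacts, or any nonstationarity across a session.  Passing tests
therefore demonstrate that the *pipeline* recovers planted effects of the
modeled kind — not that the modeled kind exhausts real LFP structure.

## Known limitations

* The Adapter/Test accuracy comparison inherits the generic skew
  sensitivity of linear classifiers on lognormal power features: strong
  suppression can change the shape (not just the separation) of the class
  distributions, and accuracy is not a monotone function of the per-site
  Fisher ratio.  The acceptance checks therefore test exactly the planted
  contrasts, not every pairwise ordering.
* `rm_anova` requires complete (balanced) designs; penetrations with
  missing cells must be dropped by the caller.
* The clipping check is a per-sample threshold test; slew-rate or
  saturation-recovery artifacts are out of scope.
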