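"""Trial cleaning and windowing of raw LFP before spectral estimation.

Three steps precede the wavelet transform:

1. a zero-phase 50 Hz notch (48-52 Hz Butterworth band-stop) to remove
   mains interference without shifting the analysis window,
2. rejection of trials in which any sample on any analyzed site falls
   outside the central 1-99 % of the declared acquisition input range
   (amplifier clipping), and
3. extraction of the early poststimulus analysis window, 60-310 ms after
   stimulus onset (half-open, exactly 250 samples at 1 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "PreprocessParams",
    "notch_filter",
    "reject_clipped_trials",
    "extract_epoch",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Cleaning and windowing parameters.

    ``notch_order`` is the overall order of the band-stop transfer function
    (a Butterworth band-stop of design order N has transfer-function order
    2N, so the default 4 uses design order 2).  ``clip_low``/``clip_high``
    are fractions of the declared input range; ``window`` is in ms relative
    to stimulus onset.  ``input_range`` is the representable (min, max) of
    the acquisition system and is never inferred from the data.
    """

    notch_band: tuple[float, float] = (48.0, 52.0)
    notch_order: int = 4
    clip_low: float = 0.01
    clip_high: float = 0.99
    window: tuple[float, float] = (60.0, 310.0)
    input_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.clip_low < self.clip_high <= 1.0:
            raise ValueError("require 0 <= clip_low < clip_high <= 1")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")
        if self.notch_band[0] >= self.notch_band[1]:
            raise ValueError("notch band must be an increasing pair")
        if self.notch_order < 2 or self.notch_order % 2:
            raise ValueError("notch_order must be an even integer >= 2")


def notch_filter(
    trace: np.ndarray, fs: float, params: PreprocessParams | None = None
) -> np.ndarray:
    """Zero-phase Butterworth band-stop over the last axis.

    Forward-backward (``sosfiltfilt``) application preserves the timing of
    the poststimulus analysis window; trace length is preserved.  Traces
    shorter than the filter warm-up are rejected.
    """
    params = params or PreprocessParams()
    lo, hi = params.notch_band
    if hi >= fs / 2.0:
        raise ValueError("notch band must lie below the Nyquist frequency")
    x = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    sos = butter(params.notch_order // 2, [lo, hi], btype="bandstop", fs=fs,
                 output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"trace length {x.shape[-1]} shorter than filter warm-up {padlen}"
        )
    return sosfiltfilt(sos, x, axis=-1)


def reject_clipped_trials(
    lfp: np.ndarray,
    trial_ids: np.ndarray,
    params: PreprocessParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Exclude trials whose signal leaves the central portion of the input range.

    A trial is rejected iff any sample on any analyzed site falls below
    ``clip_low`` or above ``clip_high`` of the declared input range.  The
    declared range is mandatory — clipping cannot be judged against a range
    inferred from the data itself.

    Returns
    -------
    kept_ids : trial ids that survive.
    report : rejection log with columns trial_id, reason, site.
    """
    if params.input_range is None:
        raise ValueError(
            "input_range is undeclared; declare the acquisition range in "
            "PreprocessParams (it is never inferred from the data)"
        )
    lo, hi = params.input_range
    if lo >= hi:
        raise ValueError("input_range must be an increasing pair")
    lfp = np.asarray(lfp)
    if lfp.ndim != 3:
        raise ValueError("lfp must be (n_trials, n_sites, n_time)")
    low_thr = lo + params.clip_low * (hi - lo)
    high_thr = lo + params.clip_high * (hi - lo)
    bad = (lfp < low_thr) | (lfp > high_thr)
    bad_trial = bad.any(axis=(1, 2))
    rows = []
    for i in np.flatnonzero(bad_trial):
        site = int(np.flatnonzero(bad[i].any(axis=1))[0])
        reason = "clip_high" if (lfp[i] > high_thr).any() else "clip_low"
        rows.append((int(trial_ids[i]), reason, site))
    report = pd.DataFrame(rows, columns=["trial_id", "reason", "site"])
    kept = np.asarray(trial_ids)[~bad_trial]
    return kept, report


def extract_epoch(
    trace: np.ndarray,
    onset_ms: float,
    fs: float,
    window: tuple[float, float] = (60.0, 310.0),
) -> np.ndarray:
    """Samples in ``[onset + window[0], onset + window[1])`` ms (half-open).

    At 1 kHz with the default window this is exactly 250 samples starting
    60 ms after stimulus onset.
    """
    x = np.asarray(trace)
    w0, w1 = window
    if w0 >= w1:
        raise ValueError("window must have positive length")
    a = int(round((onset_ms + w0) * fs / 1000.0))
    b = int(round((onset_ms + w1) * fs / 1000.0))
    if a < 0 or b > x.shape[-1]:
        raise ValueError("analysis window exceeds the recorded trace")
    return x[..., a:b]
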