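"""Two-stage gaze filtering: 3-frame median filter, then zero-lag Butterworth.

The raw azimuth/elevation channels are first despiked with a three-frame
median filter and then low-passed with a second-order zero-lag (forward-
backward) Butterworth filter: a 30 Hz cut-off stream feeds fixation
detection and a 50 Hz cut-off stream feeds saccade detection.  Both
streams come from the same median-filtered input.

Tracking-loss gaps shorter than ``max_interp`` (default 75 ms, shorter
than the 100 ms minimum fixation duration so interpolation cannot
fabricate a fixation) are linearly interpolated; longer gaps split the
trace into independently filtered segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import GazeRecording

__all__ = [
    "median_filter3",
    "butterworth_zero_lag",
    "handle_gaps",
    "FilteredStreams",
    "preprocess",
]

#: segments shorter than this many samples are excluded rather than filtered
MIN_SEGMENT_SAMPLES = 12


def median_filter3(signal_in) -> np.ndarray:
    """Three-frame running median; first and last samples pass unchanged."""
    x = np.asarray(signal_in, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if len(x) < 3:
        raise ValueError("median filter needs at least 3 samples")
    # 'nearest' edge padding leaves the end samples unchanged for size 3
    return ndimage.median_filter(x, size=3, mode="nearest")


def butterworth_zero_lag(signal_in, rate: float, cutoff: float) -> np.ndarray:
    """Second-order low-pass Butterworth applied forward and backward.

    The two passes cancel phase exactly (zero lag) and square the
    magnitude response of the underlying second-order design.
    """
    x = np.asarray(signal_in, dtype=float)
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff must lie in (0, {rate / 2}) Hz, got {cutoff}")
    b, a = signal.butter(2, cutoff, fs=rate)
    padlen = min(len(x) - 1, 3 * max(len(a), len(b)))
    if padlen < 1:
        return x.copy()
    return signal.filtfilt(b, a, x, padlen=padlen)


def handle_gaps(recording: GazeRecording, max_interp: float = 0.075):
    """Interpolate short tracking-loss gaps and segment around long ones.

    Returns (recording', gap_mask, segments): gap_mask flags samples
    excluded from analysis; segments lists (start, stop) index ranges of
    contiguous usable samples (stop exclusive).
    """
    rec = recording.copy()
    n = len(rec)
    gap_mask = np.zeros(n, dtype=bool)
    if n == 0:
        return rec, gap_mask, []

    invalid = ~rec.valid
    dt = 1.0 / rec.rate
    i = 0
    while i < n:
        if not invalid[i]:
            i += 1
            continue
        j = i
        while j < n and invalid[j]:
            j += 1
        gap_len_s = (j - i) * dt
        interior = i > 0 and j < n
        if interior and gap_len_s <= max_interp:
            frac = (rec.t[i:j] - rec.t[i - 1]) / (rec.t[j] - rec.t[i - 1])
            rec.az[i:j] = rec.az[i - 1] + frac * (rec.az[j] - rec.az[i - 1])
            rec.el[i:j] = rec.el[i - 1] + frac * (rec.el[j] - rec.el[i - 1])
            rec.valid[i:j] = True
        else:
            gap_mask[i:j] = True
        i = j

    segments = []
    usable = ~gap_mask
    i = 0
    while i < n:
        if not usable[i]:
            i += 1
            continue
        j = i
        while j < n and usable[j]:
            j += 1
        if j - i >= MIN_SEGMENT_SAMPLES:
            segments.append((i, j))
        else:
            gap_mask[i:j] = True
        i = j
    return rec, gap_mask, segments


@dataclass
class FilteredStreams:
    """Sample-aligned filtered position streams.

    fix_az/fix_el: 30 Hz cut-off stream for fixation detection;
    sac_az/sac_el: 50 Hz cut-off stream for saccade detection.
    Samples inside excluded gaps are NaN.
    """

    t: np.ndarray
    fix_az: np.ndarray
    fix_el: np.ndarray
    sac_az: np.ndarray
    sac_el: np.ndarray
    gap_mask: np.ndarray
    segments: list
    rate: float


def preprocess(
    recording: GazeRecording,
    cutoff_fix_hz: float = 30.0,
    cutoff_sac_hz: float = 50.0,
    max_interp: float = 0.075,
) -> FilteredStreams:
    """Run the full filtering chain (median -> zero-lag Butterworth x2)."""
    rec, gap_mask, segments = handle_gaps(recording, max_interp=max_interp)
    n = len(rec)
    fix_az = np.full(n, np.nan)
    fix_el = np.full(n, np.nan)
    sac_az = np.full(n, np.nan)
    sac_el = np.full(n, np.nan)
    for i, j in segments:
        for raw, fix_out, sac_out in ((rec.az, fix_az, sac_az), (rec.el, fix_el, sac_el)):
            med = median_filter3(raw[i:j])
            fix_out[i:j] = butterworth_zero_lag(med, rec.rate, cutoff_fix_hz)
            sac_out[i:j] = butterworth_zero_lag(med, rec.rate, cutoff_sac_hz)
    return FilteredStreams(
        t=rec.t, fix_az=fix_az, fix_el=fix_el, sac_az=sac_az, sac_el=sac_el,
        gap_mask=gap_mask, segments=segments, rate=rec.rate,
    )
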