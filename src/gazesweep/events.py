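"""Oculomotor event detection: dispersion fixations, acceleration saccades.

Fixations are detected with a dispersion algorithm (I-DT family):
maximal runs of samples clustered within a 1 deg spatial tolerance
(every sample within 1 deg of the cluster centroid, the convention of
the dispersion-toolbox family) that span at least 100 ms.  Saccades are
detected where the magnitude of gaze acceleration exceeds five times the
trial's median absolute acceleration, with onset and offset refined to
the surrounding acceleration extrema.

Both detectors operate on their own filtered stream (30 Hz cut-off for
fixations, 50 Hz for saccades) and run independently per valid segment,
so events never cross tracking-loss gaps.
"""

from __future__ import annotations

import numpy as np

from .core import FixationEvent, SaccadeEvent
from .preprocessing import FilteredStreams

__all__ = [
    "compute_acceleration",
    "detect_fixations",
    "detect_saccades",
    "reconcile_events",
    "detect_events",
]

#: saccades displacing less than this are numerically degenerate (theta unstable)
MIN_SACCADE_AMPLITUDE_DEG = 0.1

#: above-threshold runs closer than this (seconds) belong to one saccade —
#: the acceleration magnitude of a single smooth saccade dips to zero at
#: its velocity peak, splitting the run in two
SACCADE_MERGE_GAP_S = 0.030


def compute_acceleration(az, el, rate: float) -> np.ndarray:
    """Magnitude of the second derivative of gaze position, deg/s^2.

    Central differences on the (filtered) position samples; one-sided at
    the segment edges.
    """
    az = np.asarray(az, dtype=float)
    el = np.asarray(el, dtype=float)
    if len(az) < 5:
        raise ValueError("acceleration needs at least 5 samples")
    dt = 1.0 / rate
    ax = np.gradient(np.gradient(az, dt), dt)
    ay = np.gradient(np.gradient(el, dt), dt)
    return np.hypot(ax, ay)


def _max_cluster_end(az, el, s, n, tolerance):
    """Largest e such that every sample in [s, e] lies within ``tolerance``
    of the window centroid (recomputed as the window grows)."""
    e = s
    while e + 1 < n:
        w_az = az[s:e + 2]
        w_el = el[s:e + 2]
        ca = w_az.mean()
        ce = w_el.mean()
        if np.max(np.hypot(w_az - ca, w_el - ce)) > tolerance:
            break
        e += 1
    return e


def detect_fixations(
    streams_or_az,
    el=None,
    t=None,
    rate: float = 120.0,
    dispersion_deg: float = 1.0,
    min_dur_s: float = 0.1,
) -> list:
    """Dispersion-based fixation detection.

    Accepts either a FilteredStreams (uses the 30 Hz stream, per
    segment) or raw (az, el, t) arrays for one contiguous segment.
    Two-stage clustering: from the current position the window grows
    while every sample stays within ``dispersion_deg`` of the running
    centroid; the boundaries are then extended outward over samples
    still within the tolerance of the fixed centroid (recovering edge
    samples blurred by the low-pass filter).  Windows spanning at least
    ``min_dur_s`` are emitted; scanning resumes after each event.
    """
    if isinstance(streams_or_az, FilteredStreams):
        st = streams_or_az
        out = []
        for i, j in st.segments:
            out.extend(detect_fixations(st.fix_az[i:j], st.fix_el[i:j], st.t[i:j],
                                        rate=st.rate, dispersion_deg=dispersion_deg,
                                        min_dur_s=min_dur_s))
        return out

    az = np.asarray(streams_or_az, dtype=float)
    el = np.asarray(el, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(az)
    if n == 0:
        return []
    if dispersion_deg <= 0 or min_dur_s <= 0:
        raise ValueError("thresholds must be positive")
    min_span = int(np.ceil(min_dur_s * rate - 1e-9))  # in sample intervals
    if n <= min_span:
        return []
    events = []
    s = 0
    floor = 0  # backward extension never crosses the previous event
    while s < n:
        e = _max_cluster_end(az, el, s, n, dispersion_deg)
        s2 = s
        if e > s:
            ca = az[s:e + 1].mean()
            ce = el[s:e + 1].mean()
            while s2 - 1 >= floor and np.hypot(az[s2 - 1] - ca, el[s2 - 1] - ce) <= dispersion_deg:
                s2 -= 1
            while e + 1 < n and np.hypot(az[e + 1] - ca, el[e + 1] - ce) <= dispersion_deg:
                e += 1
        if e - s2 >= min_span:
            events.append(FixationEvent(
                onset=float(t[s2]), offset=float(t[e]),
                az=float(az[s2:e + 1].mean()), el=float(el[s2:e + 1].mean()),
            ))
            s = e + 1
            floor = s
        else:
            s += 1
    return events


def _runs(mask) -> list:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks], idx[-1]]
    return list(zip(starts, stops))  # inclusive


def detect_saccades(
    streams_or_az,
    el=None,
    t=None,
    rate: float = 120.0,
    k: float = 5.0,
    median_abs_accel: float = None,
) -> list:
    """Adaptive acceleration-threshold saccade detection.

    Candidate events are runs where acceleration magnitude exceeds
    k x median(|acceleration|) of the trial; runs separated by less than
    SACCADE_MERGE_GAP_S are merged (one saccade's acceleration crosses
    zero at its velocity peak).  Boundaries are refined from the signed
    acceleration projected onto the saccade direction: its maximum marks
    the onset and its minimum (the deceleration peak) the offset.
    Displacement and direction are computed between the refined
    boundaries; saccades displacing < 0.1 deg are discarded.
    """
    if isinstance(streams_or_az, FilteredStreams):
        st = streams_or_az
        if not st.segments:
            return []
        accels = {}
        pooled = []
        for i, j in st.segments:
            if j - i >= 5:
                a = compute_acceleration(st.sac_az[i:j], st.sac_el[i:j], st.rate)
                accels[(i, j)] = a
                pooled.append(a)
        if not pooled:
            return []
        med = float(np.median(np.concatenate(pooled)))
        out = []
        for (i, j), _ in accels.items():
            out.extend(detect_saccades(st.sac_az[i:j], st.sac_el[i:j], st.t[i:j],
                                       rate=st.rate, k=k, median_abs_accel=med))
        return out

    az = np.asarray(streams_or_az, dtype=float)
    el = np.asarray(el, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(az) < 5:
        raise ValueError("trial too short for saccade detection (< 5 samples)")
    accel = compute_acceleration(az, el, rate)
    med = float(np.median(accel)) if median_abs_accel is None else median_abs_accel
    if med <= 0:
        return []
    threshold = k * med
    runs = _runs(accel > threshold)
    if not runs:
        return []
    merge_gap = max(1, int(round(SACCADE_MERGE_GAP_S * rate)))
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    n = len(az)
    dt = 1.0 / rate
    acc_x = np.gradient(np.gradient(az, dt), dt)
    acc_y = np.gradient(np.gradient(el, dt), dt)
    events = []
    for a, b in merged:
        lo = max(0, a - 2)
        hi = min(n - 1, b + 2)
        ux = az[hi] - az[lo]
        uy = el[hi] - el[lo]
        norm = np.hypot(ux, uy)
        if norm == 0:
            continue
        a_par = (acc_x[lo:hi + 1] * ux + acc_y[lo:hi + 1] * uy) / norm
        onset = lo + int(np.argmax(a_par))
        offset = lo + int(np.argmin(a_par))
        if offset <= onset:
            continue
        r_x = float(az[offset] - az[onset])
        r_y = float(el[offset] - el[onset])
        if np.hypot(r_x, r_y) < MIN_SACCADE_AMPLITUDE_DEG:
            continue
        events.append(SaccadeEvent(onset=float(t[onset]), offset=float(t[offset]),
                                   r_x=r_x, r_y=r_y))
    return events


def reconcile_events(fixations: list, saccades: list, min_dur_s: float = 0.1):
    """Truncate fixations at overlapping saccade boundaries.

    Fixation intervals overlapping a detected saccade are cut at the
    saccade's onset/offset (split in two if the saccade falls inside);
    resulting fragments shorter than the minimum duration are dropped.
    Saccades pass through unchanged.
    """
    out = []
    for fx in fixations:
        pieces = [(fx.onset, fx.offset)]
        for sc in saccades:
            next_pieces = []
            for p0, p1 in pieces:
                if sc.offset <= p0 or sc.onset >= p1:
                    next_pieces.append((p0, p1))
                    continue
                if sc.onset > p0:
                    next_pieces.append((p0, sc.onset))
                if sc.offset < p1:
                    next_pieces.append((sc.offset, p1))
            pieces = next_pieces
        for p0, p1 in pieces:
            if p1 - p0 >= min_dur_s - 1e-12:
                out.append(FixationEvent(onset=p0, offset=p1, az=fx.az, el=fx.el,
                                         aoi_id=fx.aoi_id))
    out.sort(key=lambda f: f.onset)
    return out, list(saccades)


def detect_events(
    recording,
    dispersion_deg: float = 1.0,
    min_dur_s: float = 0.1,
    k: float = 5.0,
    cutoff_fix_hz: float = 30.0,
    cutoff_sac_hz: float = 50.0,
    max_interp: float = 0.075,
    reconcile: bool = False,
):
    """Filter a recording and detect fixations and saccades.

    Returns (fixations, saccades).  reconcile=False by default: the two
    detectors run on their own streams without cross-adjustment.
    """
    from .preprocessing import preprocess

    streams = preprocess(recording, cutoff_fix_hz=cutoff_fix_hz,
                         cutoff_sac_hz=cutoff_sac_hz, max_interp=max_interp)
    fixations = detect_fixations(streams, dispersion_deg=dispersion_deg,
                                 min_dur_s=min_dur_s)
    saccades = detect_saccades(streams, k=k)
    if reconcile:
        fixations, saccades = reconcile_events(fixations, saccades, min_dur_s=min_dur_s)
    return fixations, saccades
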