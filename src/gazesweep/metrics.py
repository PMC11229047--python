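"""Scanpath efficiency metrics: transition entropy, anisotropy, search rate.

Gaze transition entropy is the Shannon conditional entropy of
AOI-to-AOI fixation transitions,

    H = - sum_i p(i) sum_{j != i} p(j | i) log2 p(j | i)   [bits]

with p(i) the marginal distribution of transition sources (row totals /
total transitions) and 0 * log 0 = 0.  Consecutive fixations on the same
AOI are collapsed first, so self-transitions never occur.  Low entropy
indicates a structured, predictable scan; the maximum for n AOIs is
log2(n - 1).

Saccadic direction theta = atan2(r_y, r_x) (degrees, (-180, 180]; 0 is
rightward, 180 leftward).  The intersaccadic angle theta_d is the
wrapped change in direction between successive saccades; saccades are
classified persistent when |theta_d| <= 90 (direction continues, the
boundary counting as persistent) and antipersistent when |theta_d| > 90
(the search doubles back).

Search rate is the number of fixations divided by their mean duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .aoi import AOILayout
from .core import FixationEvent, GazeRecording, SaccadeEvent, wrap_angle

__all__ = [
    "assign_aois",
    "TransitionMatrix",
    "transition_matrix",
    "transition_entropy",
    "saccadic_angle",
    "intersaccadic_angles",
    "angle_differences",
    "antipersistent_fraction",
    "time_to_first_target",
    "search_order_met",
    "TrialMetrics",
    "compute_trial_metrics",
    "aggregate_participant",
]


def assign_aois(fixations: list, layout: AOILayout, targets_first: bool = False) -> list:
    """Label each fixation with the AOI containing its centroid (or None)."""
    return [fx.with_aoi(layout.locate(fx.az, fx.el, targets_first=targets_first))
            for fx in fixations]


@dataclass
class TransitionMatrix:
    """AOI transition counts and the derived probability estimates."""

    labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be n_aois x n_aois")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("transition counts must have a zero diagonal (i != j)")

    @property
    def n_aois(self) -> int:
        return len(self.labels)

    @property
    def n_transitions(self) -> float:
        return float(self.counts.sum())

    @property
    def p_i(self) -> np.ndarray:
        """Marginal source distribution: row totals / total transitions."""
        total = self.counts.sum()
        row = self.counts.sum(axis=1)
        return row / total if total > 0 else row

    @property
    def p_cond(self) -> np.ndarray:
        """Conditional destination probabilities p(j | i); zero rows stay zero."""
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(row > 0, self.counts / row, 0.0)
        return p

    def entropy(self) -> float:
        """Transition-weighted conditional Shannon entropy, in bits."""
        if self.counts.sum() < 2:
            return 0.0
        p_i = self.p_i
        p_c = self.p_cond
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(p_c > 0, np.log2(np.where(p_c > 0, p_c, 1.0)), 0.0)
        row_h = -(p_c * logs).sum(axis=1)
        return float((p_i * row_h).sum())


def _collapse(sequence) -> list:
    """Drop unlabelled fixations and collapse consecutive repeats."""
    out = []
    for a in sequence:
        if a is None:
            continue
        if not out or out[-1] != a:
            out.append(a)
    return out


def transition_matrix(aoi_sequence, n_aois: Optional[int] = None,
                      labels: Optional[list] = None) -> TransitionMatrix:
    """Count AOI transitions from a fixation sequence.

    The label alphabet is taken from ``labels`` if given, else from
    integer ids 1..n_aois, else from the distinct labels observed.
    """
    seq = _collapse(aoi_sequence)
    if labels is None:
        labels = list(range(1, n_aois + 1)) if n_aois is not None \
            else sorted(set(seq), key=str)
    index = {a: k for k, a in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for a, b in zip(seq[:-1], seq[1:]):
        if a in index and b in index:
            counts[index[a], index[b]] += 1
    return TransitionMatrix(labels=labels, counts=counts)


def transition_entropy(aoi_sequence, n_aois: Optional[int] = None) -> float:
    """Gaze transition entropy of a fixation AOI sequence, in bits.

    Returns 0.0 when the collapsed sequence yields fewer than 2
    transitions.
    """
    return transition_matrix(aoi_sequence, n_aois=n_aois).entropy()


def saccadic_angle(r_x: float, r_y: float) -> float:
    """Direction of a saccade displacement, degrees in (-180, 180]."""
    if r_x == 0.0 and r_y == 0.0:
        raise ValueError("saccadic angle undefined for zero displacement")
    return wrap_angle(math.degrees(math.atan2(r_y, r_x)))


def angle_differences(thetas) -> list:
    """Wrapped successive differences of a direction series, (-180, 180]."""
    thetas = list(thetas)
    return [float(wrap_angle(b - a)) for a, b in zip(thetas[:-1], thetas[1:])]


def intersaccadic_angles(saccades: list) -> list:
    """Change in direction between successive saccades, degrees (-180, 180].

    Element i is theta_{i+1} - theta_i wrapped; fewer than 2 saccades
    give an empty list.
    """
    if len(saccades) < 2:
        return []
    return angle_differences([s.theta for s in saccades])


def antipersistent_fraction(theta_d) -> Optional[float]:
    """Percentage of intersaccadic angles exceeding a 90 deg direction shift.

    |theta_d| = 90 exactly counts as persistent (within 90 deg in either
    direction).  Empty input returns None.
    """
    theta_d = np.asarray(list(theta_d), dtype=float)
    if theta_d.size == 0:
        return None
    return float(100.0 * np.mean(np.abs(theta_d) > 90.0))


def time_to_first_target(recording: GazeRecording, layout: AOILayout,
                         entry_time: Optional[float] = None) -> Optional[float]:
    """Latency from room entry to the first gaze sample inside a target.

    Scans valid samples at t >= entry_time; returns None if gaze never
    intersects a target region.
    """
    if entry_time is None:
        entry_time = recording.meta.entry_time
    if len(recording) == 0 or not (recording.t[0] <= entry_time <= recording.t[-1]):
        raise ValueError("entry_time outside the recording span")
    sel = (recording.t >= entry_time) & recording.valid
    for i in np.flatnonzero(sel):
        if layout.in_target(recording.az[i], recording.el[i]):
            return float(recording.t[i] - entry_time)
    return None


def search_order_met(aoi_sequence, layout: AOILayout) -> bool:
    """Whether the trained search order was followed.

    True iff the earliest fixation on a near-corner AOI precedes the
    earliest fixation on a back-wall AOI; trials fixating a near corner
    but never the back wall count as compliant; trials fixating neither
    (or only the back wall) do not.
    """
    if not layout.near_corner or not layout.back_wall:
        raise ValueError("layout must tag near_corner and back_wall roles")
    first_corner = first_back = None
    for k, a in enumerate(aoi_sequence):
        if first_corner is None and a in layout.near_corner:
            first_corner = k
        if first_back is None and a in layout.back_wall:
            first_back = k
        if first_corner is not None and first_back is not None:
            break
    if first_corner is None:
        return False
    return first_back is None or first_corner < first_back


@dataclass
class TrialMetrics:
    """Per-trial battery of eye-movement and performance measures."""

    mean_fixation_duration: Optional[float] = None
    n_fixations: int = 0
    search_rate: Optional[float] = None
    entropy: float = 0.0
    pct_antipersistent: Optional[float] = None
    time_to_first_target: Optional[float] = None
    search_order_met: bool = False
    failures_to_inhibit: Optional[float] = None
    time_to_shoot_all: Optional[float] = None
    prop_hostiles_cleared: Optional[float] = None
    meta: object = None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "mean_fixation_duration", "n_fixations", "search_rate", "entropy",
            "pct_antipersistent", "time_to_first_target", "search_order_met",
            "failures_to_inhibit", "time_to_shoot_all", "prop_hostiles_cleared")}
        return d


def compute_trial_metrics(
    fixations: list,
    saccades: list,
    layout: AOILayout,
    recording: Optional[GazeRecording] = None,
    meta=None,
) -> TrialMetrics:
    """Assemble the full metric battery for one trial.

    Fixations are AOI-labelled if not already; entropy uses the wall
    segments as the transition alphabet.  Fields that cannot be computed
    (no fixations, fewer than 2 saccades, no target intersection) are
    None.
    """
    if fixations and all(fx.aoi_id is None for fx in fixations):
        fixations = assign_aois(fixations, layout)
    meta = meta or (recording.meta if recording is not None else None)

    tm = TrialMetrics(meta=meta)
    if fixations:
        durs = np.array([fx.duration for fx in fixations])
        tm.mean_fixation_duration = float(durs.mean())
        tm.n_fixations = len(fixations)
        tm.search_rate = float(len(fixations) / durs.mean())
    seq = [fx.aoi_id for fx in fixations]
    seg_ids = set(layout.segment_ids)
    tm.entropy = transition_entropy([a for a in seq if a in seg_ids],
                                    n_aois=layout.n_segments)
    theta_d = intersaccadic_angles(saccades)
    tm.pct_antipersistent = antipersistent_fraction(theta_d)
    if recording is not None and layout.targets:
        tm.time_to_first_target = time_to_first_target(recording, layout)
    tm.search_order_met = search_order_met(seq, layout)
    if meta is not None:
        tm.failures_to_inhibit = getattr(meta, "failures_to_inhibit", None)
        tm.time_to_shoot_all = getattr(meta, "time_to_shoot_all", None)
        tm.prop_hostiles_cleared = getattr(meta, "prop_hostiles_cleared", None)
    return tm


def aggregate_participant(trials: list) -> dict:
    """Aggregate a participant's trial metrics within one phase.

    Arithmetic mean across trials with a value; search_order_met becomes
    the percentage of trials in which the criterion was met.  Metrics
    with no usable trial aggregate to None.
    """
    if not trials:
        raise ValueError("need at least one trial to aggregate")
    out = {}
    keys = trials[0].as_dict().keys()
    for key in keys:
        vals = [t.as_dict()[key] for t in trials]
        if key == "search_order_met":
            out[key] = 100.0 * float(np.mean([bool(v) for v in vals]))
            continue
        usable = [float(v) for v in vals
                  if v is not None and not (isinstance(v, float) and math.isnan(v))]
        out[key] = float(np.mean(usable)) if usable else None
    return out
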