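"""Core containers shared across the pipeline.

Gaze is represented throughout in 2D angular coordinates (azimuth,
elevation, in degrees) on the unwrapped wall surface of the searched
room.  Times are in seconds with t = 0 at room entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TrialMeta",
    "GazeRecording",
    "FixationEvent",
    "SaccadeEvent",
    "GroundTruth",
    "wrap_angle",
]


def wrap_angle(deg):
    """Wrap an angle (or array of angles) in degrees to (-180, 180]."""
    w = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    if np.ndim(deg) == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class TrialMeta:
    """Descriptor of one room-clearance trial."""

    participant: str = "P00"
    group: str = "Control"
    pool: str = "Army"
    phase: str = "pre"
    room_config: str = "room-1"
    trial_id: str = "T00"
    entry_time: float = 0.0
    # pre-computed per-trial performance outcomes (pass-through fields)
    failures_to_inhibit: Optional[float] = None
    time_to_shoot_all: Optional[float] = None
    prop_hostiles_cleared: Optional[float] = None


@dataclass
class GazeRecording:
    """One trial's time-stamped angular gaze trace.

    Attributes
    ----------
    t : array of sample times in seconds, strictly increasing.
    az, el : gaze azimuth / elevation in degrees.
    valid : boolean per sample; False marks tracking loss (blinks).
    rate : nominal sampling rate in Hz (120 for the target tracker).
    meta : trial descriptor.
    """

    t: np.ndarray
    az: np.ndarray
    el: np.ndarray
    valid: np.ndarray
    rate: float = 120.0
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.el = np.asarray(self.el, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.az) == len(self.el) == len(self.valid) == n):
            raise ValueError("t, az, el, valid must have equal length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        good = self.valid
        if np.any(good) and not (
            np.all(np.isfinite(self.az[good])) and np.all(np.isfinite(self.el[good]))
        ):
            raise ValueError("az/el must be finite where valid")

    def __len__(self) -> int:
        return len(self.t)

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            self.t.copy(), self.az.copy(), self.el.copy(), self.valid.copy(),
            rate=self.rate, meta=self.meta,
        )


@dataclass
class FixationEvent:
    """A detected fixation: gaze dwelling within a small spatial region."""

    onset: float
    offset: float
    az: float
    el: float
    aoi_id: Optional[object] = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def centroid(self) -> tuple:
        return (self.az, self.el)

    def with_aoi(self, aoi_id) -> "FixationEvent":
        return replace(self, aoi_id=aoi_id)


@dataclass
class SaccadeEvent:
    """A detected saccade: a rapid ballistic gaze shift.

    r_x / r_y are the horizontal / vertical displacement components
    (end position minus start position, degrees); theta is the saccade
    direction atan2(r_y, r_x) in degrees, wrapped to (-180, 180]:
    0 = rightward, 180 = leftward, +90 = upward.
    """

    onset: float
    offset: float
    r_x: float
    r_y: float

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("saccade offset must follow onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.r_x, self.r_y))

    @property
    def theta(self) -> float:
        if self.r_x == 0.0 and self.r_y == 0.0:
            raise ValueError("saccadic angle undefined for zero displacement")
        return wrap_angle(np.degrees(np.arctan2(self.r_y, self.r_x)))


@dataclass
class GroundTruth:
    """Ground-truth event labels attached to a synthetic recording.

    fixations: (onset, offset, az, el, aoi_id) tuples, time ordered.
    saccades: (onset, offset, dx, dy) tuples, time ordered.
    blinks: (onset, offset) intervals of simulated tracking loss.
    """

    fixations: list
    saccades: list
    blinks: list = field(default_factory=list)

    def validate(self, min_fix_dur: float = 0.1) -> None:
        for name, events in (("fixations", self.fixations), ("saccades", self.saccades)):
            last = -np.inf
            for ev in events:
                onset, offset = ev[0], ev[1]
                if onset < last:
                    raise ValueError(f"{name} overlap or are out of order")
                if offset <= onset:
                    raise ValueError(f"{name} have non-positive duration")
                last = offset
        for fx in self.fixations:
            if fx[1] - fx[0] < min_fix_dur - 1e-12:
                raise ValueError("ground-truth fixation shorter than minimum duration")
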