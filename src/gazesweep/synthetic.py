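"""Synthetic gaze recordings and study datasets with known ground truth.

The generator emulates the signal structure a head-mounted eye tracker
produces during a room-clearance search: 120 Hz angular gaze traces
composed of fixations (dispersion well under 1 deg, duration >= 100 ms)
joined by saccades with smooth raised-cosine position profiles, over a
12-segment wall layout.  Scan *structure* is controlled by a single
``sweep_persistence`` probability: at 1 the scanpath is an orderly sweep
that visits adjacent segments in a fixed direction (the expert strategy
taught by eye-movement training); at 0 every transition doubles back to
a random segment behind the current one (an erratic, antipersistent
novice search).

Study-level generation produces the participants x group(3) x time(2)
design of the emulated experiment, with additive effects injectable per
metric and group-by-phase cell, either from simulated scanpaths
("scanpath" method) or from a fast Gaussian model of the aggregated
metrics ("parametric" method).

All randomness flows from one seeded numpy Generator per call; there is
no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .aoi import AOILayout, default_room_layout
from .core import GazeRecording, GroundTruth, TrialMeta

__all__ = [
    "ScanProfile",
    "StudyDesign",
    "generate_scanpath",
    "render_recording",
    "simulate_trial",
    "generate_study",
    "expert_profile",
    "novice_profile",
    "METRIC_NAMES",
]

#: metrics a study dataset carries; effect specifications must use these names
METRIC_NAMES = (
    "mean_fixation_duration",
    "n_fixations",
    "search_rate",
    "entropy",
    "pct_antipersistent",
    "time_to_first_target",
    "search_order_met",
    "failures_to_inhibit",
    "time_to_shoot_all",
    "prop_hostiles_cleared",
)

#: (baseline, between-participant sd, within-participant trial sd) for the
#: parametric study generator, on each metric's native scale
_PARAM_BASELINES = {
    "mean_fixation_duration": (0.30, 0.05, 0.08),
    "n_fixations": (55.0, 8.0, 10.0),
    "search_rate": (180.0, 30.0, 40.0),
    "entropy": (2.2, 0.4, 0.5),
    "pct_antipersistent": (55.0, 8.0, 12.0),
    "time_to_first_target": (2.5, 0.6, 1.0),
    "search_order_met": (60.0, 15.0, 30.0),
    "failures_to_inhibit": (0.10, 0.04, 0.06),
    "time_to_shoot_all": (8.0, 1.5, 2.0),
    "prop_hostiles_cleared": (0.90, 0.05, 0.08),
}

_BLINK_DURATION_S = 0.15
_MIN_FIX_DUR_S = 0.1
#: shortest generated fixation: one 120 Hz sample interval above the 100 ms
#: detection criterion, so every ground-truth fixation spans enough samples
#: to be detectable at any sampling phase
_MIN_GEN_FIX_DUR_S = 0.12


@dataclass(frozen=True)
class ScanProfile:
    """Behavioural parameters of a simulated searcher.

    sweep_persistence is the probability that the next fixated segment
    continues the current sweep direction (adjacent segment, same
    direction); otherwise the scan reverses to a random segment behind
    the current gaze position.  saccade_peak_velocity_scale sets peak
    saccade velocity as deg/s per degree of amplitude, which with the
    raised-cosine position profile gives every saccade the same duration
    pi / (2 * scale) seconds; peak velocity grows linearly with
    amplitude with no main-sequence plateau, keeping transition edges
    crisp at the 120 Hz sampling rate.
    """

    n_aois: int = 12
    sweep_persistence: float = 0.5
    fixation_duration_mean: float = 0.30
    fixation_duration_sd: float = 0.10
    saccade_peak_velocity_scale: float = 35.0
    noise_sd: float = 0.1
    blink_rate: float = 10.0
    trial_duration: float = 20.0

    def __post_init__(self):
        if not 0.0 <= self.sweep_persistence <= 1.0:
            raise ValueError("sweep_persistence must lie in [0, 1]")
        if self.fixation_duration_mean < _MIN_FIX_DUR_S:
            raise ValueError("fixation_duration_mean must be >= 0.1 s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.saccade_peak_velocity_scale <= 0:
            raise ValueError("saccade_peak_velocity_scale must be positive")

    def saccade_duration(self, amplitude: float) -> float:
        """Duration of a raised-cosine saccade of the given amplitude (deg)."""
        return math.pi / (2.0 * self.saccade_peak_velocity_scale)


def expert_profile(**overrides) -> ScanProfile:
    """Profile emulating a trained, low-entropy persistent sweep."""
    kw = dict(sweep_persistence=1.0, fixation_duration_mean=0.35, fixation_duration_sd=0.08)
    kw.update(overrides)
    return ScanProfile(**kw)


def novice_profile(**overrides) -> ScanProfile:
    """Profile emulating an erratic, antipersistent novice search."""
    kw = dict(sweep_persistence=0.0, fixation_duration_mean=0.25, fixation_duration_sd=0.08)
    kw.update(overrides)
    return ScanProfile(**kw)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_point(polygon, rng: np.random.Generator) -> tuple:
    """Sample a fixation centroid near the middle of an AOI polygon.

    Gaussian around the polygon centroid (sd = extent/8 per axis),
    clipped to the central half so centroids of adjacent segments stay
    horizontally separated.
    """
    cx, cy = polygon.centroid.x, polygon.centroid.y
    x0, y0, x1, y1 = polygon.bounds
    wx, wy = x1 - x0, y1 - y0
    x = float(np.clip(rng.normal(cx, wx / 8.0), cx - wx / 4.0, cx + wx / 4.0))
    y = float(np.clip(rng.normal(cy, wy / 8.0), cy - wy / 4.0, cy + wy / 4.0))
    return x, y


def generate_scanpath(
    profile: ScanProfile,
    layout: AOILayout,
    seed=None,
) -> tuple:
    """Simulate one trial's AOI walk and ground-truth event list.

    Returns (aoi_sequence, GroundTruth).  The walk starts at a random
    segment; with probability ``sweep_persistence`` each step continues
    to the adjacent segment in the current sweep direction (wrapping
    from the last segment back to the first, i.e. re-sweeping from the
    door), otherwise it reverses to a uniformly chosen segment behind
    the current one.
    """
    segments = layout.segments
    n = len(segments)
    if n < 2:
        raise ValueError("layout must contain at least 2 AOIs")
    rng = _as_rng(seed)
    az_centres = np.array([s.polygon.centroid.x for s in segments])

    idx = int(rng.integers(n))
    direction = int(rng.choice([-1, 1]))
    t = 0.0
    total = profile.trial_duration

    seq, fixations, saccades = [], [], []
    pos = None
    while True:
        dur = max(_MIN_GEN_FIX_DUR_S, rng.normal(profile.fixation_duration_mean,
                                                 profile.fixation_duration_sd))
        new_pos = _sample_point(segments[idx].polygon, rng)
        if pos is not None:
            amp = math.hypot(new_pos[0] - pos[0], new_pos[1] - pos[1])
            t_sac = profile.saccade_duration(amp)
            if t + t_sac + _MIN_GEN_FIX_DUR_S > total:
                break
            saccades.append((t, t + t_sac, new_pos[0] - pos[0], new_pos[1] - pos[1]))
            t += t_sac
        elif total < _MIN_GEN_FIX_DUR_S:
            break
        end = min(t + dur, total)
        fixations.append((t, end, new_pos[0], new_pos[1], segments[idx].aoi_id))
        seq.append(segments[idx].aoi_id)
        pos = new_pos
        t = end
        if t >= total - 1e-9:
            break
        if rng.random() < profile.sweep_persistence:
            idx = (idx + direction) % n
        else:
            # double back: a segment behind the current gaze direction,
            # favouring nearby segments (geometric distance distribution,
            # as return saccades mostly revisit recently scanned areas)
            behind = [j for j in range(n) if j != idx
                      and np.sign(az_centres[j] - az_centres[idx]) == -direction]
            if not behind:
                behind = [j for j in range(n) if j != idx]
            behind.sort(key=lambda j: abs(az_centres[j] - az_centres[idx]))
            d = min(int(rng.geometric(0.5)) - 1, len(behind) - 1)
            new_idx = behind[d]
            direction = 1 if az_centres[new_idx] > az_centres[idx] else -1
            idx = new_idx

    blinks = []
    if profile.blink_rate > 0 and total > _BLINK_DURATION_S:
        n_blinks = rng.poisson(profile.blink_rate * total / 60.0)
        onsets = np.sort(rng.uniform(0.0, total - _BLINK_DURATION_S, size=n_blinks))
        for onset in onsets:
            if blinks and onset < blinks[-1][1]:
                blinks[-1] = (blinks[-1][0], onset + _BLINK_DURATION_S)
            else:
                blinks.append((float(onset), float(onset) + _BLINK_DURATION_S))

    gt = GroundTruth(fixations=fixations, saccades=saccades, blinks=blinks)
    gt.validate()
    return seq, gt


def render_recording(
    ground_truth: GroundTruth,
    rate: float = 120.0,
    noise_sd: float = 0.0,
    seed=None,
    meta: Optional[TrialMeta] = None,
    duration: Optional[float] = None,
) -> GazeRecording:
    """Render a ground-truth event list into a uniformly sampled trace.

    Fixation samples sit at the event centroid plus clipped Gaussian
    jitter (clipped at 2.5 sd so within-fixation dispersion stays
    bounded by 5 * noise_sd per channel); saccade samples follow a
    raised-cosine position profile between the flanking fixation
    centroids, whose acceleration has exactly one maximum (onset) and
    one minimum (offset).  Blink intervals are flagged invalid, never
    rendered as extreme positions.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = _as_rng(seed)
    events = sorted(
        [("fix", f) for f in ground_truth.fixations]
        + [("sac", s) for s in ground_truth.saccades],
        key=lambda kv: kv[1][0],
    )
    if not events:
        raise ValueError("ground truth contains no events")
    last_end = -np.inf
    for _, ev in events:
        if ev[0] < last_end - 1e-12:
            raise ValueError("inconsistent ground truth: overlapping events")
        last_end = ev[1]
    if duration is None:
        duration = last_end
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    az = np.empty(n)
    el = np.empty(n)

    # initial position: centroid of the first fixation, or start of the
    # first saccade's flanking fixation if the timeline starts mid-flight
    first_fix = ground_truth.fixations[0] if ground_truth.fixations else None
    cur = (first_fix[2], first_fix[3]) if first_fix else (0.0, 0.0)
    az[:] = cur[0]
    el[:] = cur[1]
    for kind, ev in events:
        i0 = int(np.searchsorted(t, ev[0] - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, ev[1] - 1e-12, side="left"))
        if kind == "fix":
            cur = (ev[2], ev[3])
            az[i0:i1] = ev[2]
            el[i0:i1] = ev[3]
        else:
            p0 = cur
            p1 = (cur[0] + ev[2], cur[1] + ev[3])
            span = ev[1] - ev[0]
            s = (t[i0:i1] - ev[0]) / span
            f = 0.5 * (1.0 - np.cos(np.pi * s))
            az[i0:i1] = p0[0] + (p1[0] - p0[0]) * f
            el[i0:i1] = p0[1] + (p1[1] - p0[1]) * f
            cur = p1
        az[i1:] = cur[0]
        el[i1:] = cur[1]

    if noise_sd > 0:
        clip = 2.5 * noise_sd
        az += np.clip(rng.normal(0.0, noise_sd, n), -clip, clip)
        el += np.clip(rng.normal(0.0, noise_sd, n), -clip, clip)

    valid = np.ones(n, dtype=bool)
    for b0, b1 in ground_truth.blinks:
        valid[(t >= b0) & (t < b1)] = False

    return GazeRecording(t=t, az=az, el=el, valid=valid, rate=rate,
                         meta=meta or TrialMeta())


def simulate_trial(
    profile: ScanProfile,
    layout: Optional[AOILayout] = None,
    seed=None,
    rate: float = 120.0,
    meta: Optional[TrialMeta] = None,
) -> tuple:
    """Generate and render one trial; returns (recording, ground_truth, aoi_sequence)."""
    layout = layout or default_room_layout(profile.n_aois)
    rng = _as_rng(seed)
    seq, gt = generate_scanpath(profile, layout, seed=rng)
    rec = render_recording(gt, rate=rate, noise_sd=profile.noise_sd, seed=rng, meta=meta)
    return rec, gt, seq


# --------------------------------------------------------------------------
# study-level generation
# --------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """Independent-groups pre/post design with injectable effects.

    effect_spec maps metric name -> {(group, phase): additive shift}
    applied to the participant-phase aggregate of that metric.
    pool_effect maps metric name -> additive shift for participants from
    the second participant pool.
    """

    n_per_group: object = (13, 13, 12)
    groups: tuple = ("FFEMT", "FBEMT", "Control")
    phases: tuple = ("pre", "post")
    trials_per_phase: int = 20
    effect_spec: dict = field(default_factory=dict)
    pool_levels: tuple = ("Army", "RM")
    pool_effect: dict = field(default_factory=dict)
    pool_p_second: float = 0.65
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_per_group, int):
            self.n_per_group = (self.n_per_group,) * len(self.groups)
        self.n_per_group = tuple(self.n_per_group)
        if len(self.n_per_group) != len(self.groups):
            raise ValueError("n_per_group must give one size per group")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("need at least 2 participants per group")
        if self.trials_per_phase < 1:
            raise ValueError("trials_per_phase must be >= 1")
        for spec in (self.effect_spec, self.pool_effect):
            for metric in spec:
                if metric not in METRIC_NAMES:
                    raise ValueError(f"effect on unknown metric {metric!r}")
        for metric, cells in self.effect_spec.items():
            for g, p in cells:
                if g not in self.groups or p not in self.phases:
                    raise ValueError(f"effect cell ({g!r}, {p!r}) not in design")


def _blend_profile(novice: ScanProfile, expert: ScanProfile, skill: float) -> ScanProfile:
    return ScanProfile(
        n_aois=novice.n_aois,
        sweep_persistence=float(np.clip(
            novice.sweep_persistence
            + skill * (expert.sweep_persistence - novice.sweep_persistence), 0.0, 1.0)),
        fixation_duration_mean=max(
            _MIN_FIX_DUR_S,
            novice.fixation_duration_mean
            + skill * (expert.fixation_duration_mean - novice.fixation_duration_mean)),
        fixation_duration_sd=novice.fixation_duration_sd,
        saccade_peak_velocity_scale=novice.saccade_peak_velocity_scale,
        noise_sd=novice.noise_sd,
        blink_rate=novice.blink_rate,
        trial_duration=novice.trial_duration,
    )


def _trial_metrics_from_ground_truth(seq, gt: GroundTruth, layout: AOILayout,
                                     rng: np.random.Generator) -> dict:
    # local import: metrics depends on core/aoi only, no cycle at runtime
    from . import metrics as _m

    durations = np.array([f[1] - f[0] for f in gt.fixations])
    out = dict.fromkeys(METRIC_NAMES, np.nan)
    if len(durations):
        out["mean_fixation_duration"] = float(durations.mean())
        out["n_fixations"] = float(len(durations))
        out["search_rate"] = float(len(durations) / durations.mean())
    out["entropy"] = _m.transition_entropy(seq, n_aois=layout.n_segments)
    thetas = [math.degrees(math.atan2(s[3], s[2])) for s in gt.saccades
              if math.hypot(s[2], s[3]) > 0]
    theta_d = _m.angle_differences(thetas)
    frac = _m.antipersistent_fraction(theta_d)
    out["pct_antipersistent"] = np.nan if frac is None else frac
    out["search_order_met"] = 100.0 * _m.search_order_met(seq, layout)
    ttft = None
    for f in gt.fixations:
        if layout.in_target(f[2], f[3]):
            ttft = f[0]
            break
    out["time_to_first_target"] = np.nan if ttft is None else ttft
    # pass-through performance outcomes, simulated at plausible task levels
    out["failures_to_inhibit"] = float(np.clip(rng.normal(0.10, 0.05), 0.0, 1.0))
    out["time_to_shoot_all"] = float(max(1.0, rng.normal(8.0, 2.0)))
    out["prop_hostiles_cleared"] = float(np.clip(rng.normal(0.90, 0.08), 0.0, 1.0))
    return out


def generate_study(
    design: StudyDesign,
    expert: Optional[ScanProfile] = None,
    novice: Optional[ScanProfile] = None,
    layout: Optional[AOILayout] = None,
    method: str = "scanpath",
    return_recordings: bool = False,
):
    """Generate a participants x group x phase table of aggregated metrics.

    method="scanpath" simulates each trial's ground-truth scanpath and
    computes metrics from it; method="parametric" draws aggregated
    metrics from a Gaussian participant/trial model (fast, used for
    statistical calibration studies).  Injected effects are additive on
    the participant-phase aggregate, so they are realised exactly in
    expectation.

    Returns a wide DataFrame (participant, group, pool, phase, one
    column per metric); with return_recordings=True (scanpath method
    only) also a list of (TrialMeta, GazeRecording, GroundTruth).
    """
    expert = expert or expert_profile()
    novice = novice or novice_profile()
    layout = layout or default_room_layout(novice.n_aois)
    rng = np.random.default_rng(design.seed)
    if method not in ("scanpath", "parametric"):
        raise ValueError(f"unknown method {method!r}")
    if return_recordings and method != "scanpath":
        raise ValueError("recordings are only available from the scanpath method")

    rows = []
    recordings = []
    pid = 0
    for g, n_g in zip(design.groups, design.n_per_group):
        for _ in range(n_g):
            pid += 1
            participant = f"P{pid:03d}"
            pool = design.pool_levels[int(rng.random() < design.pool_p_second)]
            if method == "parametric":
                latent = {m: rng.normal(0.0, _PARAM_BASELINES[m][1]) for m in METRIC_NAMES}
            else:
                skill = float(np.clip(rng.normal(0.35, 0.15), 0.0, 1.0))
                prof = _blend_profile(novice, expert, skill)
            for phase in design.phases:
                agg = {}
                if method == "parametric":
                    for m in METRIC_NAMES:
                        base, _, wsd = _PARAM_BASELINES[m]
                        noise = rng.normal(0.0, wsd, design.trials_per_phase).mean()
                        agg[m] = base + latent[m] + noise
                else:
                    trial_vals = {m: [] for m in METRIC_NAMES}
                    for k in range(design.trials_per_phase):
                        meta = TrialMeta(participant=participant, group=g, pool=pool,
                                         phase=phase, trial_id=f"T{k:02d}")
                        seq, gt = generate_scanpath(prof, layout, seed=rng)
                        if return_recordings:
                            rec = render_recording(gt, noise_sd=prof.noise_sd,
                                                   seed=rng, meta=meta)
                            recordings.append((meta, rec, gt))
                        tm = _trial_metrics_from_ground_truth(seq, gt, layout, rng)
                        for m, v in tm.items():
                            if not (isinstance(v, float) and math.isnan(v)):
                                trial_vals[m].append(v)
                    for m in METRIC_NAMES:
                        agg[m] = float(np.mean(trial_vals[m])) if trial_vals[m] else np.nan
                for m in METRIC_NAMES:
                    shift = design.effect_spec.get(m, {}).get((g, phase), 0.0)
                    if pool == design.pool_levels[1]:
                        shift += design.pool_effect.get(m, 0.0)
                    agg[m] = agg[m] + shift
                rows.append({"participant": participant, "group": g,
                             "pool": pool, "phase": phase, **agg})

    df = pd.DataFrame(rows)
    if return_recordings:
        return df, recordings
    return df
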