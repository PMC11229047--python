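"""Pipeline configuration and the end-to-end driver.

The driver chains the analysis stages in order: preprocess (median +
zero-lag Butterworth filtering) -> event detection -> AOI assignment and
scanpath metrics -> participant-phase aggregation -> group x time
statistics.  All stage parameters default to the standard protocol
values (120 Hz sampling, 30/50 Hz cut-offs, 1 deg dispersion, 100 ms
minimum fixation, 5x median-absolute-acceleration saccade threshold).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as gio
from .aoi import AOILayout, default_room_layout
from .core import GazeRecording
from .events import detect_events
from .metrics import aggregate_participant, assign_aois, compute_trial_metrics
from .stats import analyze_study, report

log = logging.getLogger("gazesweep")

__all__ = ["PipelineConfig", "run_pipeline", "process_recordings"]


@dataclass
class PipelineConfig:
    sampling_rate: float = 120.0
    cutoff_fix_hz: float = 30.0
    cutoff_sac_hz: float = 50.0
    dispersion_deg: float = 1.0
    min_fix_dur_s: float = 0.1
    accel_k: float = 5.0
    persistence_boundary_deg: float = 90.0
    max_interp_s: float = 0.075
    alpha: float = 0.05
    posthoc_band: float = 0.06
    covariate: Optional[str] = "pool"
    reconcile: bool = False
    seed: int = 0

    def __post_init__(self):
        positive = ("sampling_rate", "cutoff_fix_hz", "cutoff_sac_hz",
                    "dispersion_deg", "min_fix_dur_s", "accel_k",
                    "persistence_boundary_deg", "max_interp_s", "alpha")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        nyquist = self.sampling_rate / 2.0
        for name in ("cutoff_fix_hz", "cutoff_sac_hz"):
            if getattr(self, name) >= nyquist:
                raise ValueError(f"{name} must be below the Nyquist rate ({nyquist} Hz)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def process_recordings(recordings, layout: AOILayout, config: PipelineConfig) -> pd.DataFrame:
    """Detect events and compute metrics for a batch of recordings.

    ``recordings`` is an iterable of GazeRecording (trial metadata in
    .meta).  Returns the wide study table: one row per participant and
    phase, one column per metric.
    """
    per_cell = {}
    n_trials = 0
    for rec in recordings:
        fixations, saccades = detect_events(
            rec,
            dispersion_deg=config.dispersion_deg,
            min_dur_s=config.min_fix_dur_s,
            k=config.accel_k,
            cutoff_fix_hz=config.cutoff_fix_hz,
            cutoff_sac_hz=config.cutoff_sac_hz,
            max_interp=config.max_interp_s,
            reconcile=config.reconcile,
        )
        fixations = assign_aois(fixations, layout)
        tm = compute_trial_metrics(fixations, saccades, layout, recording=rec)
        key = (rec.meta.participant, rec.meta.group, rec.meta.pool, rec.meta.phase)
        per_cell.setdefault(key, []).append(tm)
        n_trials += 1
        log.info("trial %s/%s: %d fixations, %d saccades",
                 rec.meta.participant, rec.meta.trial_id, len(fixations), len(saccades))
    log.info("processed %d trials over %d participant-phases", n_trials, len(per_cell))
    rows = []
    for (participant, group, pool, phase), trials in per_cell.items():
        agg = aggregate_participant(trials)
        rows.append({"participant": participant, "group": group,
                     "pool": pool, "phase": phase, **agg})
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    gaze_paths: Optional[list] = None,
    recordings: Optional[list] = None,
    layout: Optional[AOILayout] = None,
    trial_meta: Optional[dict] = None,
    out_dir=None,
):
    """Execute preprocess -> detect -> metrics -> aggregate -> stats.

    Inputs are either gaze CSV paths or in-memory recordings.  Returns
    (study_table, results, report_text); when ``out_dir`` is given the
    metrics CSV, results JSON and text report are also written there.
    """
    if recordings is None:
        if not gaze_paths:
            raise ValueError("run_pipeline needs gaze_paths or recordings")
        recordings = []
        for p in gaze_paths:
            meta = (trial_meta or {}).get(str(p))
            rec = gio.read_gaze_csv(p, rate=config.sampling_rate, meta=meta)
            recordings.append(rec)
    layout = layout or default_room_layout()

    table = process_recordings(recordings, layout, config)
    results = analyze_study(table, covariate=config.covariate,
                            alpha=config.alpha, posthoc_band=config.posthoc_band)
    text, payload = report(results)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gio.write_metrics_csv(table, out_dir / "metrics.csv")
        import json

        (out_dir / "stats.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        (out_dir / "stats.txt").write_text(text)
    return table, results, text
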