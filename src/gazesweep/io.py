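"""CSV dialects for gaze traces, events, and study metric tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FixationEvent, GazeRecording, SaccadeEvent, TrialMeta

__all__ = [
    "read_gaze_csv",
    "write_gaze_csv",
    "write_events_csv",
    "read_events_csv",
    "write_metrics_csv",
    "read_metrics_csv",
]

GAZE_COLUMNS = ["t_s", "az_deg", "el_deg", "valid", "trial_id"]


def write_gaze_csv(recording: GazeRecording, path) -> None:
    df = pd.DataFrame({
        "t_s": recording.t,
        "az_deg": recording.az,
        "el_deg": recording.el,
        "valid": recording.valid.astype(int),
        "trial_id": recording.meta.trial_id,
    })
    df.to_csv(path, index=False)


def read_gaze_csv(path, rate: float = None, meta: TrialMeta = None) -> GazeRecording:
    """Read one trial's gaze trace.

    Rows with non-finite position are flagged invalid rather than
    dropped, so the sample count is preserved.  The sampling rate is
    inferred from the median time step unless given.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns and c != "trial_id"]
    if missing:
        raise ValueError(f"gaze CSV schema error: missing column(s) {', '.join(missing)}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("gaze CSV data error: t_s must be strictly increasing")
    az = df["az_deg"].to_numpy(dtype=float)
    el = df["el_deg"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy().astype(bool)
    valid &= np.isfinite(az) & np.isfinite(el)
    az = np.where(np.isfinite(az), az, 0.0)
    el = np.where(np.isfinite(el), el, 0.0)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 120.0
    if meta is None:
        trial_id = str(df["trial_id"].iloc[0]) if "trial_id" in df.columns and len(df) else "T00"
        meta = TrialMeta(trial_id=trial_id)
    return GazeRecording(t=t, az=az, el=el, valid=valid, rate=rate, meta=meta)


def write_events_csv(fixations, saccades, path) -> None:
    rows = []
    for fx in fixations:
        rows.append({"type": "fixation", "onset_s": fx.onset, "offset_s": fx.offset,
                     "duration_s": fx.duration, "az_deg": fx.az, "el_deg": fx.el,
                     "r_x_deg": np.nan, "r_y_deg": np.nan, "theta_deg": np.nan,
                     "aoi_id": fx.aoi_id})
    for sc in saccades:
        rows.append({"type": "saccade", "onset_s": sc.onset, "offset_s": sc.offset,
                     "duration_s": sc.duration, "az_deg": np.nan, "el_deg": np.nan,
                     "r_x_deg": sc.r_x, "r_y_deg": sc.r_y, "theta_deg": sc.theta,
                     "aoi_id": None})
    df = pd.DataFrame(rows).sort_values("onset_s", kind="stable")
    df.to_csv(path, index=False)


def read_events_csv(path):
    df = pd.read_csv(path)
    fixations, saccades = [], []
    for _, r in df.iterrows():
        if r["type"] == "fixation":
            aoi = r.get("aoi_id")
            if pd.isna(aoi):
                aoi = None
            fixations.append(FixationEvent(onset=r["onset_s"], offset=r["offset_s"],
                                           az=r["az_deg"], el=r["el_deg"], aoi_id=aoi))
        else:
            saccades.append(SaccadeEvent(onset=r["onset_s"], offset=r["offset_s"],
                                         r_x=r["r_x_deg"], r_y=r["r_y_deg"]))
    return fixations, saccades


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    """Write a study table in tidy long format (one row per metric value)."""
    id_cols = [c for c in ("participant", "group", "pool", "phase") if c in df.columns]
    long = df.melt(id_vars=id_cols, var_name="metric", value_name="value")
    long.to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    """Read a tidy long metrics CSV back to the wide analysis layout."""
    long = pd.read_csv(path)
    id_cols = [c for c in ("participant", "group", "pool", "phase") if c in long.columns]
    wide = long.pivot_table(index=id_cols, columns="metric", values="value",
                            aggfunc="first").reset_index()
    wide.columns.name = None
    return wide
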