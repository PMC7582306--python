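"""CSV readers/writers and YAML configuration.

CSV is the canonical interchange format.  All files carry a header row,
UTF-8 text and '.' decimals; time stamps are seconds from session start
and all intervals are half-open [t, t + step).

Session streams: eeg.csv, gaze.csv, uav_logs.csv, clicks.csv,
ratings.csv, truth.csv, rois.csv, schedule.csv.
Derived outputs: eeg_index.csv, entropy.csv, task_index.csv,
clicks_binned.csv, phase_summary.csv, anova.csv, tukey.csv,
correlations.csv, correlation_summary.csv.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eeg import EEGRecording
from .errors import ConfigError, MissingStreamError
from .gaze import GazeStream, ROI, ROILayout
from .schedule import Phase, PhaseSchedule, WorkloadProfile
from .series import IndexSeries
from .synthetic import (
    ClickGenConfig,
    EEGGenConfig,
    GazeGenConfig,
    RatingsConfig,
    SessionBundle,
    SessionConfig,
    UAVGenConfig,
)
from .tasks import ClickLog, UAVLogSet
from .schedule import make_phase_schedule


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingStreamError(f"required file missing: {path.name}")
    return path


# --------------------------------------------------------------------------
# session streams


def write_eeg_csv(rec: EEGRecording, path: Path) -> None:
    df = pd.DataFrame({"t_s": rec.t_s})
    for i, ch in enumerate(rec.channels):
        df[ch] = rec.data[i]
    df.to_csv(path, index=False)


def read_eeg_csv(path: Path) -> EEGRecording:
    df = pd.read_csv(_require(Path(path)))
    t = df["t_s"].to_numpy()
    channels = tuple(c for c in df.columns if c != "t_s")
    data = df[list(channels)].to_numpy().T
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    return EEGRecording(float(round(fs, 6)), channels, data, t0_s=float(t[0]))


def write_gaze_csv(stream: GazeStream, path: Path) -> None:
    pd.DataFrame(
        {
            "t_s": stream.t_s,
            "left_x": stream.left_x, "left_y": stream.left_y,
            "left_valid": stream.left_valid.astype(int),
            "right_x": stream.right_x, "right_y": stream.right_y,
            "right_valid": stream.right_valid.astype(int),
            "blink": stream.blink.astype(int),
        }
    ).to_csv(path, index=False)


def read_gaze_csv(path: Path) -> GazeStream:
    df = pd.read_csv(_require(Path(path)))
    return GazeStream(
        df["t_s"].to_numpy(),
        df["left_x"].to_numpy(), df["left_y"].to_numpy(),
        df["left_valid"].to_numpy().astype(bool),
        df["right_x"].to_numpy(), df["right_y"].to_numpy(),
        df["right_valid"].to_numpy().astype(bool),
        df["blink"].to_numpy().astype(bool),
    )


def write_uav_logs_csv(logs: UAVLogSet, path: Path) -> None:
    df = logs.frame.copy()
    for col in ("autopilot_hold", "in_team", "sensors_active"):
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


def read_uav_logs_csv(path: Path) -> UAVLogSet:
    df = pd.read_csv(_require(Path(path)))
    for col in ("autopilot_hold", "in_team", "sensors_active"):
        df[col] = df[col].astype(bool)
    return UAVLogSet(df)


def write_clicks_csv(clicks: ClickLog, path: Path) -> None:
    pd.DataFrame({"t_s": clicks.t_s, "button": clicks.button}).to_csv(path, index=False)


def read_clicks_csv(path: Path) -> ClickLog:
    df = pd.read_csv(_require(Path(path)))
    return ClickLog(df["t_s"].to_numpy(), df["button"].to_numpy(dtype=object))


def write_ratings_csv(ratings: pd.DataFrame, path: Path) -> None:
    ratings.to_csv(path, index=False)


def read_ratings_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(_require(Path(path)))


def write_truth_csv(profile: WorkloadProfile, path: Path) -> None:
    pd.DataFrame({"t_s": profile.grid_s, "workload": profile.level}).to_csv(
        path, index=False
    )


def read_truth_csv(path: Path) -> WorkloadProfile:
    df = pd.read_csv(_require(Path(path)))
    return WorkloadProfile(df["t_s"].to_numpy(), df["workload"].to_numpy())


def write_rois_csv(layout: ROILayout, path: Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in layout.regions],
            "x_min": [r.x_min for r in layout.regions],
            "y_min": [r.y_min for r in layout.regions],
            "x_max": [r.x_max for r in layout.regions],
            "y_max": [r.y_max for r in layout.regions],
            "priority": np.arange(len(layout)),
        }
    ).to_csv(path, index=False)


def read_rois_csv(path: Path) -> ROILayout:
    df = pd.read_csv(_require(Path(path))).sort_values("priority", kind="stable")
    regions = tuple(
        ROI(str(r.id), float(r.x_min), float(r.y_min), float(r.x_max), float(r.y_max))
        for r in df.itertuples()
    )
    return ROILayout(regions)


def write_schedule_csv(schedule: PhaseSchedule, path: Path) -> None:
    pd.DataFrame(
        {
            "label": [p.label for p in schedule.phases],
            "start_s": [p.start_s for p in schedule.phases],
            "end_s": [p.end_s for p in schedule.phases],
        }
    ).to_csv(path, index=False)


def read_schedule_csv(path: Path) -> PhaseSchedule:
    df = pd.read_csv(_require(Path(path)))
    return PhaseSchedule(
        tuple(
            Phase(str(r.label), float(r.start_s), float(r.end_s))
            for r in df.itertuples()
        )
    )


def write_session_dir(bundle: SessionBundle, out_dir: Path) -> list[Path]:
    """Write all session streams plus the ground truth to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_eeg_csv(bundle.eeg, out / "eeg.csv")
    write_gaze_csv(bundle.gaze, out / "gaze.csv")
    write_uav_logs_csv(bundle.uav_logs, out / "uav_logs.csv")
    write_clicks_csv(bundle.clicks, out / "clicks.csv")
    write_ratings_csv(bundle.ratings, out / "ratings.csv")
    write_truth_csv(bundle.truth, out / "truth.csv")
    write_rois_csv(bundle.config.gaze.layout, out / "rois.csv")
    write_schedule_csv(bundle.schedule, out / "schedule.csv")
    return sorted(out.glob("*.csv"))


# --------------------------------------------------------------------------
# derived series


def write_series_csv(series: IndexSeries, path: Path, extra: dict | None = None) -> None:
    df = pd.DataFrame({"t_s": series.t_s, "value": series.values})
    if extra:
        for k, v in extra.items():
            df[k] = v
    df["flagged"] = series.flagged.astype(int)
    df.to_csv(path, index=False)


def read_series_csv(path: Path, step_s: float, label: str = "") -> IndexSeries:
    df = pd.read_csv(_require(Path(path)))
    return IndexSeries(
        df["t_s"].to_numpy(),
        df["value"].to_numpy(),
        step_s,
        label,
        df["flagged"].to_numpy().astype(bool),
    )


# --------------------------------------------------------------------------
# configuration


def _build(cls, payload: dict, key: str):
    try:
        return cls(**payload)
    except TypeError as exc:
        raise ConfigError(str(exc), key=key) from None


def session_config_from_dict(doc: dict) -> SessionConfig:
    """Build a SessionConfig from a plain (YAML/JSON) mapping.

    Recognized top-level keys: schedule (durations_s), levels,
    grid_step_s, eeg, gaze, uav, clicks, ratings.  Unknown keys raise a
    ConfigError naming the key.
    """
    doc = dict(doc or {})
    known = {"schedule", "levels", "grid_step_s", "eeg", "gaze", "uav", "clicks", "ratings"}
    for k in doc:
        if k not in known:
            raise ConfigError("unknown configuration key", key=k)
    kwargs: dict = {}
    if "schedule" in doc:
        sched = doc["schedule"]
        durations = sched.get("durations_s") if isinstance(sched, dict) else sched
        kwargs["schedule"] = make_phase_schedule(durations)
    if "levels" in doc:
        kwargs["levels"] = tuple(float(v) for v in doc["levels"])
    if "grid_step_s" in doc:
        kwargs["grid_step_s"] = float(doc["grid_step_s"])
    if "eeg" in doc:
        payload = dict(doc["eeg"])
        if "channels" in payload:
            payload["channels"] = tuple(payload["channels"])
        kwargs["eeg"] = _build(EEGGenConfig, payload, "eeg")
    if "gaze" in doc:
        payload = dict(doc["gaze"])
        if "layout" in payload:
            grid = payload.pop("layout")
            payload["layout"] = ROILayout.grid(int(grid["n_rows"]), int(grid["n_cols"]))
        kwargs["gaze"] = _build(GazeGenConfig, payload, "gaze")
    if "uav" in doc:
        payload = dict(doc["uav"])
        if "counts" in payload:
            payload["counts"] = tuple(int(c) for c in payload["counts"])
        kwargs["uav"] = _build(UAVGenConfig, payload, "uav")
    if "clicks" in doc:
        kwargs["clicks"] = _build(ClickGenConfig, dict(doc["clicks"]), "clicks")
    if "ratings" in doc:
        payload = dict(doc["ratings"])
        for k in ("mwl_means", "sa_means"):
            if k in payload:
                payload[k] = tuple(float(v) for v in payload[k])
        kwargs["ratings"] = _build(RatingsConfig, payload, "ratings")
    return SessionConfig(**kwargs)


def load_session_config(path: Path | None) -> SessionConfig:
    """Load a session config from YAML; None yields the defaults."""
    if path is None:
        return SessionConfig()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return session_config_from_dict(doc or {})
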