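"""Secondary-task index and controller-input counts.

The task index is a weighted count of pending system-maintenance tasks
read off each UAV's flight log.  Six categories are scored per UAV —
navigation accuracy, comm strength, fuel margin, autopilot hold, team
assignment and sensor activation — each contributing 0, 0.5 or 1 point,
for a per-UAV maximum of 6.  The session-level index is the sum over
all UAVs released so far.

Controller inputs (left and right mouse clicks) are counted in fixed
2-minute bins as a cheap task-based workload proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParameterError
from .series import IndexSeries

UAV_LOG_COLUMNS = (
    "t_s", "uav_id", "nav_acc_m", "comm_pct", "fuel_onboard",
    "fuel_needed", "autopilot_hold", "in_team", "sensors_active",
)


@dataclass(frozen=True)
class UAVLogRecord:
    """One UAV subsystem-state snapshot."""

    t_s: float
    uav_id: str
    nav_acc_m: float
    comm_pct: float
    fuel_onboard: float
    fuel_needed: float
    autopilot_hold: bool
    in_team: bool
    sensors_active: bool

    def __post_init__(self):
        if self.nav_acc_m < 0:
            raise ParameterError("nav_acc_m must be non-negative")
        if not 0 <= self.comm_pct <= 100:
            raise ParameterError("comm_pct must lie in [0, 100]")
        if self.fuel_onboard < 0 or self.fuel_needed < 0:
            raise ParameterError("fuel quantities must be non-negative")


@dataclass(frozen=True)
class PenaltyTable:
    """Thresholds and weights of the six penalty categories.

    Navigation: accuracy above ``nav_poor_m`` scores 1, between
    ``nav_excellent_m`` and ``nav_poor_m`` (both inclusive) 0.5, below 0.
    Comm: strength below ``comm_poor_pct`` scores 1, up to
    ``comm_excellent_pct`` (inclusive) 0.5, above 0.
    Fuel: the safety margin r = fuel_onboard / fuel_needed scores 1 when
    r < ``fuel_critical_ratio``, 0.5 when below ``fuel_low_ratio`` and 0
    otherwise; fuel_needed = 0 counts as an infinite (adequate) margin.
    Autopilot hold, missing team assignment and no active sensors each
    score ``full_penalty``.
    """

    nav_excellent_m: float = 10.0
    nav_poor_m: float = 25.0
    comm_poor_pct: float = 50.0
    comm_excellent_pct: float = 70.0
    fuel_critical_ratio: float = 1.5
    fuel_low_ratio: float = 2.0
    full_penalty: float = 1.0
    half_penalty: float = 0.5

    @property
    def max_per_uav(self) -> float:
        return 6 * self.full_penalty


DEFAULT_PENALTY_TABLE = PenaltyTable()


def _penalty_components(
    nav_acc_m, comm_pct, fuel_onboard, fuel_needed,
    autopilot_hold, in_team, sensors_active,
    table: PenaltyTable = DEFAULT_PENALTY_TABLE,
) -> np.ndarray:
    """Vectorized per-record penalty; all arguments broadcastable arrays."""
    nav = np.asarray(nav_acc_m, dtype=float)
    comm = np.asarray(comm_pct, dtype=float)
    ob = np.asarray(fuel_onboard, dtype=float)
    need = np.asarray(fuel_needed, dtype=float)
    hold = np.asarray(autopilot_hold, dtype=bool)
    team = np.asarray(in_team, dtype=bool)
    sens = np.asarray(sensors_active, dtype=bool)

    full, half = table.full_penalty, table.half_penalty
    p_nav = np.where(
        nav > table.nav_poor_m, full, np.where(nav >= table.nav_excellent_m, half, 0.0)
    )
    p_comm = np.where(
        comm < table.comm_poor_pct,
        full,
        np.where(comm <= table.comm_excellent_pct, half, 0.0),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        margin = np.where(need > 0, ob / np.where(need > 0, need, 1.0), np.inf)
    p_fuel = np.where(
        margin < table.fuel_critical_ratio,
        full,
        np.where(margin < table.fuel_low_ratio, half, 0.0),
    )
    p_hold = np.where(hold, full, 0.0)
    p_team = np.where(team, 0.0, full)
    p_sens = np.where(sens, 0.0, full)
    return p_nav + p_comm + p_fuel + p_hold + p_team + p_sens


def uav_penalty(rec: UAVLogRecord, table: PenaltyTable = DEFAULT_PENALTY_TABLE) -> float:
    """Pending-secondary-task score of one flight-log record, in [0, 6]."""
    return float(
        _penalty_components(
            rec.nav_acc_m, rec.comm_pct, rec.fuel_onboard, rec.fuel_needed,
            rec.autopilot_hold, rec.in_team, rec.sensors_active, table,
        )
    )


@dataclass
class UAVLogSet:
    """All UAVs' log records of one session, as a tidy frame.

    Columns follow :data:`UAV_LOG_COLUMNS`; rows need not be sorted.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in UAV_LOG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ParameterError(f"uav log frame missing columns: {missing}")
        self.frame = self.frame.sort_values(["uav_id", "t_s"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_records(cls, records: Iterable[UAVLogRecord]) -> "UAVLogSet":
        rows = [
            {c: getattr(r, c) for c in UAV_LOG_COLUMNS} for r in records
        ]
        return cls(pd.DataFrame(rows, columns=UAV_LOG_COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def uav_ids(self) -> list[str]:
        return sorted(self.frame["uav_id"].unique())


def task_index_series(
    logs: UAVLogSet,
    table: PenaltyTable = DEFAULT_PENALTY_TABLE,
    step_s: float = 5.0,
    span: tuple[float, float] | None = None,
) -> IndexSeries:
    """Fleet-level pending-task score on a uniform grid.

    At each grid time the score of every UAV is taken from its latest
    record at or before that time (last observation carried forward) and
    summed; a UAV contributes nothing before its first record (release).
    ``span`` defaults to the logs' own extent.
    """
    if len(logs) == 0:
        raise ParameterError("empty UAV log set")
    df = logs.frame
    if span is None:
        span = (float(df["t_s"].min()), float(df["t_s"].max()) + step_s)
    grid = np.arange(span[0], span[1] - 1e-9, step_s)
    total = np.zeros(grid.size)
    pen_all = _penalty_components(
        df["nav_acc_m"].to_numpy(), df["comm_pct"].to_numpy(),
        df["fuel_onboard"].to_numpy(), df["fuel_needed"].to_numpy(),
        df["autopilot_hold"].to_numpy(), df["in_team"].to_numpy(),
        df["sensors_active"].to_numpy(), table,
    )
    for _, grp_idx in df.groupby("uav_id").groups.items():
        t = df.loc[grp_idx, "t_s"].to_numpy()
        pen = pen_all[np.asarray(grp_idx)]
        pos = np.searchsorted(t, grid + 1e-9, side="right") - 1
        released = pos >= 0
        total[released] += pen[np.clip(pos, 0, None)][released]
    return IndexSeries(grid, total, step_s, "task_index")


@dataclass
class ClickLog:
    """Mouse-click event log (left/right buttons)."""

    t_s: np.ndarray
    button: np.ndarray

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.button = np.asarray(self.button, dtype=object)
        if self.t_s.size != self.button.size:
            raise ParameterError("t_s and button length mismatch")
        if self.t_s.size > 1 and (np.diff(self.t_s) < 0).any():
            raise ParameterError("click timestamps must be non-decreasing")

    def __len__(self) -> int:
        return self.t_s.size


def click_count_series(
    clicks: ClickLog,
    bin_s: float = 120.0,
    span: tuple[float, float] | None = None,
) -> IndexSeries:
    """Controller-input counts in half-open bins [t, t + bin_s).

    Both buttons are counted together.  ``span`` defaults to [0, last
    click + bin); pass the schedule span to get the full session.
    """
    if bin_s <= 0:
        raise ParameterError("bin_s must be positive")
    if span is None:
        end = (float(clicks.t_s.max()) + bin_s) if len(clicks) else bin_s
        span = (0.0, end)
    edges = np.arange(span[0], span[1] + bin_s - 1e-9, bin_s)
    counts, _ = np.histogram(clicks.t_s, bins=edges)
    return IndexSeries(edges[:-1], counts.astype(float), bin_s, "control_input")
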