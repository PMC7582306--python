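"""Session phase schedule and the latent workload profile.

A session consists of five contiguous phases: a pre-mission rest, three
back-to-back mission phases of increasing difficulty, and a post-mission
rest.  The latent workload profile is the (unobserved) driver used by the
synthetic generators and kept as ground truth for recovery tests; by
default it is piecewise constant, one level per phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, ScheduleError

PHASE_LABELS = ("PreRest", "Phase1", "Phase2", "Phase3", "PostRest")
MISSION_PHASES = ("Phase1", "Phase2", "Phase3")

#: Default phase durations in seconds: 5-min rest, three 10-min mission
#: phases, 5-min rest.
DEFAULT_DURATIONS_S = (300.0, 600.0, 600.0, 600.0, 300.0)


@dataclass(frozen=True)
class Phase:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseSchedule:
    """An ordered, contiguous, non-overlapping set of labelled phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self):
        labels = [p.label for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ScheduleError("phase labels must be unique", key="schedule")
        prev_end = None
        for p in self.phases:
            if not p.end_s > p.start_s:
                raise ScheduleError(
                    f"phase {p.label!r} has non-positive duration", key="schedule"
                )
            if prev_end is not None and not np.isclose(p.start_s, prev_end):
                raise ScheduleError(
                    f"phase {p.label!r} does not start where the previous ends",
                    key="schedule",
                )
            prev_end = p.end_s

    @property
    def start_s(self) -> float:
        return self.phases[0].start_s

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s

    @property
    def span_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.phases)

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)

    def label_at(self, t_s):
        """Phase label for each time stamp (None outside the span).

        Stamps on a boundary belong to the later phase (half-open
        [start, end) convention); the final end point belongs to the last
        phase so that the session end stamp is not orphaned.
        """
        t = np.asarray(t_s, dtype=float)
        starts = np.array([p.start_s for p in self.phases])
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.empty(t.shape, dtype=object)
        out[...] = None
        inside = (t >= self.start_s) & (t <= self.end_s)
        idx = np.clip(idx, 0, len(self.phases) - 1)
        lab = np.array([p.label for p in self.phases], dtype=object)
        out[inside] = lab[idx[inside]]
        return out if out.ndim else out.item()


def make_phase_schedule(durations_s: Sequence[float] = DEFAULT_DURATIONS_S) -> PhaseSchedule:
    """Build the canonical five-phase schedule starting at t = 0.

    Parameters
    ----------
    durations_s : sequence of 5 positive floats
        Durations of PreRest, Phase1, Phase2, Phase3, PostRest in seconds.
    """
    durations = tuple(float(d) for d in durations_s)
    if len(durations) != len(PHASE_LABELS):
        raise ScheduleError(
            f"expected {len(PHASE_LABELS)} durations, got {len(durations)}",
            key="schedule",
        )
    if any(d <= 0 for d in durations):
        raise ScheduleError("all durations must be positive", key="schedule")
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    phases = tuple(
        Phase(label, float(edges[i]), float(edges[i + 1]))
        for i, label in enumerate(PHASE_LABELS)
    )
    return PhaseSchedule(phases)


@dataclass(frozen=True)
class WorkloadProfile:
    """Latent workload level in [0, 1] on a uniform time grid."""

    grid_s: np.ndarray
    level: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid_s, dtype=float)
        lev = np.asarray(self.level, dtype=float)
        object.__setattr__(self, "grid_s", grid)
        object.__setattr__(self, "level", lev)
        if grid.shape != lev.shape:
            raise ConfigError("grid and level must have equal length", key="profile")
        if lev.size and (lev.min() < 0.0 or lev.max() > 1.0):
            raise ConfigError("workload levels must lie in [0, 1]", key="profile")

    def level_at(self, t_s):
        """Zero-order-hold interpolation of the profile at arbitrary times."""
        t = np.asarray(t_s, dtype=float)
        idx = np.clip(np.searchsorted(self.grid_s, t, side="right") - 1, 0, None)
        return self.level[idx]


def generate_workload_profile(
    schedule: PhaseSchedule,
    levels: Sequence[float],
    grid_step_s: float = 5.0,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> WorkloadProfile:
    """Piecewise-constant latent workload, one level per phase.

    ``noise_sd`` adds seeded Gaussian jitter per grid point (clipped back
    into [0, 1]); the default of 0 keeps the profile exactly
    piecewise constant, matching the phase-level analysis.
    """
    levels = tuple(float(v) for v in levels)
    if len(levels) != len(schedule.phases):
        raise ConfigError(
            f"expected {len(schedule.phases)} levels, got {len(levels)}", key="levels"
        )
    if any(v < 0.0 or v > 1.0 for v in levels):
        raise ConfigError("levels must lie in [0, 1]", key="levels")
    if grid_step_s <= 0:
        raise ConfigError("grid_step_s must be positive", key="grid_step_s")
    grid = np.arange(schedule.start_s, schedule.end_s, grid_step_s)
    starts = np.array([p.start_s for p in schedule.phases])
    idx = np.clip(np.searchsorted(starts, grid, side="right") - 1, 0, None)
    lev = np.asarray(levels, dtype=float)[idx]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        lev = np.clip(lev + rng.normal(0.0, noise_sd, lev.shape), 0.0, 1.0)
    return WorkloadProfile(grid, lev)
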