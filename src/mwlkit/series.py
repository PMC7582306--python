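"""Uniformly gridded scalar time series.

Every derived workload measure (EEG index, visual entropy, task index,
binned click counts, fused measures) is carried as an :class:`IndexSeries`:
a uniform time grid, one scalar per stamp, and a per-stamp validity flag.
Flagged points hold NaN-or-whatever and are excluded from downstream
statistics unless an operation explicitly replaces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, ParameterError


@dataclass
class IndexSeries:
    """Scalar time series on a uniform grid.

    Parameters
    ----------
    t_s : array
        Window/bin start stamps in seconds from session start.
    values : array
        One scalar per stamp.
    step_s : float
        Grid step in seconds.
    label : str
        Human-readable measure name, carried through the pipeline.
    flagged : bool array, optional
        True marks invalid points; defaults to ``~isfinite(values)``.
    """

    t_s: np.ndarray
    values: np.ndarray
    step_s: float
    label: str = ""
    flagged: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_s.shape != self.values.shape:
            raise ParameterError("t_s and values must have equal length")
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.values)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool) | ~np.isfinite(
                self.values
            )
        if self.flagged.shape != self.values.shape:
            raise ParameterError("flagged must match values in length")
        if self.step_s <= 0:
            raise ParameterError("step_s must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def valid(self) -> np.ndarray:
        return ~self.flagged

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def with_values(self, values, flagged=None) -> "IndexSeries":
        return replace(self, values=np.asarray(values, dtype=float), flagged=flagged)

    def restrict(self, start_s: float, end_s: float) -> "IndexSeries":
        """Sub-series with stamps in the half-open window [start_s, end_s)."""
        m = (self.t_s >= start_s) & (self.t_s < end_s)
        return IndexSeries(
            self.t_s[m], self.values[m], self.step_s, self.label, self.flagged[m]
        )

    def mean(self) -> float:
        """Mean over valid points (NaN if none)."""
        v = self.valid_values
        return float(np.mean(v)) if v.size else float("nan")


def resample_locf(series: IndexSeries, grid_s: np.ndarray, step_s: float) -> IndexSeries:
    """Resample a step-valued series onto ``grid_s`` by carrying the last
    observation forward.  Grid points before the first stamp are flagged.
    """
    grid = np.asarray(grid_s, dtype=float)
    idx = np.searchsorted(series.t_s, grid + 1e-9, side="right") - 1
    before = idx < 0
    idx = np.clip(idx, 0, None)
    values = series.values[idx]
    flagged = series.flagged[idx] | before
    values = np.where(before, np.nan, values)
    return IndexSeries(grid, values, step_s, series.label, flagged)


def common_grid(a: IndexSeries, b: IndexSeries, step_s: float) -> np.ndarray:
    """Uniform grid covering the overlap of two series' spans.

    The grid is anchored at multiples of ``step_s`` so identical inputs map
    onto themselves.  Raises if the spans do not overlap.
    """
    start = max(a.t_s[0], b.t_s[0])
    end = min(a.t_s[-1] + a.step_s, b.t_s[-1] + b.step_s)
    if end <= start:
        raise AlignmentError("series spans do not overlap")
    start = np.ceil(start / step_s - 1e-9) * step_s
    return np.arange(start, end - 1e-9, step_s)
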