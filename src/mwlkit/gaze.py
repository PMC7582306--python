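"""Gaze-transition visual entropy.

Binocular gaze samples are reduced to a monocular sequence (midpoint of
the valid eyes), mapped onto rectangular regions of interest (ROIs),
collapsed into dwell-to-dwell transition events, and summarized per
window by the conditional entropy of the transition matrix:

    H = - sum_i p(X_i) sum_j p(Y_ij | X_i) log2 p(Y_ij | X_i)

where p(X_i) is the empirical probability of dwelling in ROI i (row
mass over total) and p(Y_ij | X_i) the conditional probability of the
next dwell.  High H means disordered scanning, which accompanies high
mental workload; a strictly cyclic scan gives H = 0.

Transitions are computed on dwells, not raw samples: consecutive
same-ROI samples merge, so self-transitions are structurally zero and
the measure does not depend on the tracker's sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigError, ParameterError
from .series import IndexSeries


@dataclass
class GazeStream:
    """Timestamped binocular screen-coordinate samples.

    Coordinates are normalized to the unit square; per-eye validity
    flags mark tracker dropout.  Coordinates of an invalid eye are
    ignored (conventionally NaN).
    """

    t_s: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    left_valid: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    right_valid: np.ndarray
    blink: np.ndarray | None = None

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        n = self.t_s.size
        for name in ("left_x", "left_y", "right_x", "right_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ParameterError(f"{name} length mismatch")
            setattr(self, name, arr)
        for name in ("left_valid", "right_valid"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.size != n:
                raise ParameterError(f"{name} length mismatch")
            setattr(self, name, arr)
        if self.blink is None:
            self.blink = np.zeros(n, dtype=bool)
        else:
            self.blink = np.asarray(self.blink, dtype=bool)
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ParameterError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t_s.size


class MonocularGaze(NamedTuple):
    """Combined one-point-per-stamp gaze sequence."""

    t_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray


def combine_eyes(stream: GazeStream) -> MonocularGaze:
    """Reduce binocular samples to a single gaze point per stamp.

    Both eyes valid: midpoint.  One eye valid: that eye's coordinates.
    Neither valid: the sample is marked invalid and excluded downstream.
    """
    both = stream.left_valid & stream.right_valid
    left_only = stream.left_valid & ~stream.right_valid
    right_only = stream.right_valid & ~stream.left_valid
    x = np.full(len(stream), np.nan)
    y = np.full(len(stream), np.nan)
    x[both] = 0.5 * (stream.left_x[both] + stream.right_x[both])
    y[both] = 0.5 * (stream.left_y[both] + stream.right_y[both])
    x[left_only] = stream.left_x[left_only]
    y[left_only] = stream.left_y[left_only]
    x[right_only] = stream.right_x[right_only]
    y[right_only] = stream.right_y[right_only]
    valid = stream.left_valid | stream.right_valid
    return MonocularGaze(stream.t_s, x, y, valid)


@dataclass(frozen=True)
class ROI:
    id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ConfigError(f"ROI {self.id!r} rectangle is degenerate", key="roi")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class ROILayout:
    """Ordered set of rectangular ROIs; list order is priority order.

    Membership uses half-open rectangles [x_min, x_max) x [y_min, y_max);
    a point on a shared edge belongs to the earlier-listed region.
    """

    regions: tuple[ROI, ...]

    def __post_init__(self):
        if not self.regions:
            raise ConfigError("ROI layout must contain at least one region", key="rois")
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ConfigError("ROI ids must be unique", key="rois")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    @classmethod
    def grid(cls, n_rows: int = 2, n_cols: int = 3, prefix: str = "uav") -> "ROILayout":
        """Regular grid of ROIs tiling the unit square (row-major ids)."""
        regions = []
        for r in range(n_rows):
            for c in range(n_cols):
                regions.append(
                    ROI(
                        f"{prefix}{r * n_cols + c + 1}",
                        c / n_cols,
                        r / n_rows,
                        (c + 1) / n_cols,
                        (r + 1) / n_rows,
                    )
                )
        return cls(tuple(regions))

    def assign(self, x, y) -> np.ndarray:
        """Vectorized ROI index for each point (-1 if outside all)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, -1, dtype=int)
        # reverse priority order so earlier regions overwrite later ones
        for i in range(len(self.regions) - 1, -1, -1):
            r = self.regions[i]
            inside = (x >= r.x_min) & (x < r.x_max) & (y >= r.y_min) & (y < r.y_max)
            out[inside] = i
        return out


def assign_roi(sample: tuple[float, float], layout: ROILayout) -> str | None:
    """ROI id containing a single (x, y) point, or None if outside all."""
    idx = int(layout.assign(np.array([sample[0]]), np.array([sample[1]]))[0])
    return None if idx < 0 else layout.regions[idx].id


class TransitionEvents(NamedTuple):
    t_s: np.ndarray  # onset time of each transition
    from_idx: np.ndarray
    to_idx: np.ndarray


def collapse_to_transitions(
    t_s: np.ndarray,
    roi_idx: np.ndarray,
    valid: np.ndarray | None = None,
    gap_max_s: float = 1.0,
) -> TransitionEvents:
    """Collapse a sampled ROI sequence into dwell-change events.

    Consecutive identical ROIs merge into one dwell.  Invalid or off-ROI
    samples form gaps: a dwell continues across a gap no longer than
    ``gap_max_s``; a longer gap restarts the sequence without emitting a
    transition across it.
    """
    t = np.asarray(t_s, dtype=float)
    roi = np.asarray(roi_idx, dtype=int)
    keep = roi >= 0
    if valid is not None:
        keep &= np.asarray(valid, dtype=bool)
    t, roi = t[keep], roi[keep]
    if t.size < 2:
        return TransitionEvents(np.empty(0), np.empty(0, int), np.empty(0, int))
    changed = roi[1:] != roi[:-1]
    bridged = np.diff(t) <= gap_max_s
    emit = changed & bridged
    return TransitionEvents(t[1:][emit], roi[:-1][emit], roi[1:][emit])


@dataclass(frozen=True)
class TransitionMatrix:
    """ROI-to-ROI transition counts; diagonal is structurally zero."""

    roi_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        n = len(self.roi_ids)
        if counts.shape != (n, n):
            raise ParameterError("counts must be square and match roi_ids")
        if (counts < 0).any():
            raise ParameterError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_events(
        cls, events: TransitionEvents, roi_ids: Sequence[str]
    ) -> "TransitionMatrix":
        n = len(roi_ids)
        counts = np.zeros((n, n), dtype=int)
        np.add.at(counts, (events.from_idx, events.to_idx), 1)
        return cls(tuple(roi_ids), counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def visual_entropy(matrix: TransitionMatrix) -> float:
    """Conditional (visual) entropy of a transition matrix, in bits.

    Rows are weighted by their empirical prior mass; zero-probability
    cells and empty rows contribute nothing.  An empty matrix (no
    transitions) has no defined entropy and yields NaN, which downstream
    windows treat as a flagged value.
    """
    counts = np.asarray(matrix.counts, dtype=float)
    total = counts.sum()
    if total < 1:
        return float("nan")
    row_sums = counts.sum(axis=1)
    p_x = row_sums / total
    h = 0.0
    for i in range(counts.shape[0]):
        if row_sums[i] == 0:
            continue
        p_cond = counts[i] / row_sums[i]
        nz = p_cond > 0
        h -= p_x[i] * np.sum(p_cond[nz] * np.log2(p_cond[nz]))
    return float(max(h, 0.0))


@dataclass
class EntropyResult:
    """Windowed visual entropy plus the per-window transition counts."""

    series: IndexSeries
    n_transitions: np.ndarray


def entropy_series(
    stream: GazeStream,
    layout: ROILayout,
    window_s: float = 60.0,
    step_s: float = 5.0,
    gap_max_s: float = 1.0,
    min_transitions: int = 5,
) -> EntropyResult:
    """Sliding-window visual entropy of a gaze stream.

    A window [t, t + window_s) covers the transition events whose onset
    lies inside it; windows with fewer than ``min_transitions`` events
    are flagged invalid.  Stamps are window starts every ``step_s``.
    """
    if window_s < step_s:
        raise ParameterError("window_s must be at least step_s")
    mono = combine_eyes(stream)
    roi_idx = layout.assign(mono.x, mono.y)
    roi_idx = np.where(mono.valid, roi_idx, -1)
    events = collapse_to_transitions(mono.t_s, roi_idx, gap_max_s=gap_max_s)
    t0, t_end = stream.t_s[0], stream.t_s[-1]
    if t_end - t0 < window_s:  # single shrunk window over whatever exists
        starts = np.array([t0])
    else:
        starts = np.arange(t0, t_end - window_s + 1e-9, step_s)
    n = len(layout)
    values = np.full(starts.size, np.nan)
    n_trans = np.zeros(starts.size, dtype=int)
    lo = np.searchsorted(events.t_s, starts)
    hi = np.searchsorted(events.t_s, starts + window_s)
    for k in range(starts.size):
        sl = slice(lo[k], hi[k])
        n_trans[k] = hi[k] - lo[k]
        if n_trans[k] < min_transitions:
            continue
        counts = np.zeros((n, n), dtype=int)
        np.add.at(counts, (events.from_idx[sl], events.to_idx[sl]), 1)
        values[k] = visual_entropy(TransitionMatrix(layout.ids, counts))
    series = IndexSeries(starts, values, step_s, "visual_entropy")
    return EntropyResult(series, n_trans)


# ---------------------------------------------------------------------------
# Markov scanpath helpers shared by the synthetic generator and tests.


def cyclic_transition_matrix(n: int, randomness: float) -> np.ndarray:
    """Row-stochastic scanpath kernel: cycle with uniform contamination.

    Each row puts probability ``1 - randomness`` on the next ROI in a
    fixed cycle and spreads ``randomness`` uniformly over the remaining
    n - 2 states (self-transitions excluded).  ``randomness`` = 0 is a
    deterministic cyclic scan (entropy 0); at (n-2)/(n-1) the row is
    uniform over all n - 1 targets (entropy log2(n-1)).
    """
    if n < 3:
        raise ParameterError("need at least 3 ROIs for a contaminated cycle")
    if not 0 <= randomness <= (n - 2) / (n - 1):
        raise ParameterError("randomness outside [0, (n-2)/(n-1)]")
    P = np.zeros((n, n))
    for i in range(n):
        nxt = (i + 1) % n
        P[i, nxt] = 1.0 - randomness
        others = [j for j in range(n) if j not in (i, nxt)]
        P[i, others] = randomness / (n - 2)
    return P


def markov_conditional_entropy(P: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Analytic conditional entropy (bits) of a row-stochastic kernel.

    Rows are weighted by ``weights`` (default: the stationary
    distribution of P).  This is the population value the windowed
    empirical entropy converges to for a stationary scanpath.
    """
    P = np.asarray(P, dtype=float)
    if weights is None:
        evals, evecs = np.linalg.eig(P.T)
        k = int(np.argmin(np.abs(evals - 1.0)))
        w = np.real(evecs[:, k])
        weights = w / w.sum()
    h = 0.0
    for i in range(P.shape[0]):
        nz = P[i] > 0
        h -= weights[i] * np.sum(P[i, nz] * np.log2(P[i, nz]))
    return float(h)
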