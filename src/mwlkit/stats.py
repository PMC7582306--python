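"""Normalization, fusion and phase-level statistics.

This module carries the statistical back half of the pipeline: min-max
normalization of the derived time series, alignment onto a common 5-s
grid, weighted physiological/objective fusion, the Pearson correlation
of feature pairs (per participant, then mean +/- SD across
participants), and the phase-level one-way ANOVA with Tukey HSD
post-hoc comparisons on z-scored per-phase means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, DegenerateDataError, ParameterError
from .schedule import PhaseSchedule
from .series import IndexSeries, common_grid, resample_locf


def minmax_normalize(series: IndexSeries) -> IndexSeries:
    """Rescale valid points to [0, 1] by (v - min) / (max - min).

    Flagged points are excluded from the min/max and stay flagged.  A
    constant series has no defined scaling and raises.
    """
    v = series.valid_values
    if v.size < 2 or np.isclose(v.min(), v.max()):
        raise DegenerateDataError(
            f"series {series.label!r} is constant; min-max scaling undefined"
        )
    lo, hi = v.min(), v.max()
    out = (series.values - lo) / (hi - lo)
    return IndexSeries(series.t_s, out, series.step_s, series.label, series.flagged.copy())


def align_series(
    a: IndexSeries, b: IndexSeries, step_s: float = 5.0
) -> tuple[IndexSeries, IndexSeries]:
    """Resample two series onto a common ``step_s`` grid over their overlap.

    A series already on the target grid is taken as-is (restricted to the
    overlap); a coarser step-valued series (task index, click bins) is
    expanded by last-observation-carried-forward.  Grid points where
    either series is flagged are dropped from both outputs.
    """
    grid = common_grid(a, b, step_s)

    def on_grid(s: IndexSeries) -> IndexSeries:
        if np.isclose(s.step_s, step_s):
            idx = np.searchsorted(s.t_s, grid - 1e-9)
            idx = np.clip(idx, 0, len(s) - 1)
            if not np.allclose(s.t_s[idx], grid, atol=1e-6):
                raise AlignmentError(
                    f"series {s.label!r} grid does not contain the common grid"
                )
            return IndexSeries(grid, s.values[idx], step_s, s.label, s.flagged[idx])
        return resample_locf(s, grid, step_s)

    aa, bb = on_grid(a), on_grid(b)
    keep = aa.valid & bb.valid
    return (
        IndexSeries(aa.t_s[keep], aa.values[keep], step_s, aa.label),
        IndexSeries(bb.t_s[keep], bb.values[keep], step_s, bb.label),
    )


@dataclass(frozen=True)
class FusionWeights:
    """Convex weights of a two-measure fusion (w_a + w_b = 1)."""

    w_a: float
    w_b: float

    def __post_init__(self):
        if not (0 <= self.w_a <= 1 and 0 <= self.w_b <= 1):
            raise ParameterError("fusion weights must lie in [0, 1]")
        if not np.isclose(self.w_a + self.w_b, 1.0):
            raise ParameterError("fusion weights must sum to 1")


#: The three weight sets explored for the fused measures.
WEIGHT_SETS = {
    "50/50": FusionWeights(0.5, 0.5),
    "70/30": FusionWeights(0.7, 0.3),
    "30/70": FusionWeights(0.3, 0.7),
}


def fuse_series(a: IndexSeries, b: IndexSeries, w: FusionWeights, label: str = "fused") -> IndexSeries:
    """Pointwise weighted sum w_a * a + w_b * b of two aligned series.

    Inputs are expected min-max normalized and on the same grid; with
    convex weights the fused values then stay within [0, 1].
    """
    if len(a) != len(b) or not np.allclose(a.t_s, b.t_s):
        raise AlignmentError("fuse_series requires series on an identical grid")
    vals = w.w_a * a.values + w.w_b * b.values
    return IndexSeries(a.t_s, vals, a.step_s, label, a.flagged | b.flagged)


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient.

        CC = (n Σxy − Σx Σy) / sqrt[(n Σx² − (Σx)²)(n Σy² − (Σy)²)]

    Requires at least 3 paired points and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 paired points")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise DegenerateDataError("correlation undefined for constant input")
    cc = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    return float(np.clip(cc, -1.0, 1.0))


@dataclass
class PhaseSummary:
    """Per-phase means of one participant's measure, z-scored across phases."""

    participant: str
    measure: str
    phases: tuple[str, ...]
    raw_means: np.ndarray
    z_means: np.ndarray


def zscore_phase_means(
    series: IndexSeries,
    schedule: PhaseSchedule,
    phases: Sequence[str] | None = None,
    participant: str = "p1",
) -> PhaseSummary:
    """Per-phase means of valid points, z-normalized across the phases.

    Centering/scaling uses the sample SD (ddof=1), so means (1, 2, 3)
    map to (-1, 0, 1).  If all phase means coincide the z-scores are
    returned as zeros with a warning.
    """
    labels = tuple(phases) if phases is not None else schedule.labels
    means = []
    for lab in labels:
        p = schedule.phase(lab)
        sub = series.restrict(p.start_s, p.end_s)
        v = sub.valid_values
        if v.size == 0:
            raise DegenerateDataError(
                f"phase {lab!r} contains no valid points of {series.label!r}"
            )
        means.append(v.mean())
    means = np.asarray(means)
    sd = means.std(ddof=1)
    if sd == 0:
        warnings.warn(
            f"all phase means of {series.label!r} equal; z-scores set to 0",
            stacklevel=2,
        )
        z = np.zeros_like(means)
    else:
        z = (means - means.mean()) / sd
    return PhaseSummary(participant, series.label, labels, means, z)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: np.ndarray
    group_se: np.ndarray
    ms_within: float
    group_sizes: np.ndarray


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sum-of-squares decomposition.

    F = MS_between / MS_within with df (k-1, N-k); the p-value comes from
    the F distribution.  The per-group standard error uses the pooled
    within-group mean square, sqrt(MSW / n_i).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ParameterError("need at least 2 groups of at least 2 values")
    k = len(arrs)
    n_i = np.array([a.size for a in arrs])
    N = int(n_i.sum())
    grand = np.concatenate(arrs).mean()
    means = np.array([a.mean() for a in arrs])
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    dfb, dfw = k - 1, N - k
    msw = ssw / dfw
    if msw == 0:
        raise DegenerateDataError("zero within-group variance everywhere")
    F = (ssb / dfb) / msw
    p = float(sps.f.sf(F, dfb, dfw))
    se = np.sqrt(msw / n_i)
    return AnovaResult(float(F), dfb, dfw, p, means, se, msw, n_i)


@dataclass
class TukeyComparison:
    group_a: int
    group_b: int
    mean_diff: float
    p_adj: float
    significant: bool


@dataclass
class TukeyResult:
    comparisons: list[TukeyComparison]
    alpha: float

    def significant_pairs(self) -> list[tuple[int, int]]:
        return [(c.group_a, c.group_b) for c in self.comparisons if c.significant]


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey(-Kramer) HSD pairwise comparisons using the pooled MSW.

    For each pair the studentized-range statistic
    q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) is referred to the
    studentized-range distribution with k groups and N - k df.
    """
    res = oneway_anova(groups)
    k = len(res.group_means)
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = res.group_means[j] - res.group_means[i]
            se = np.sqrt(
                res.ms_within / 2.0 * (1.0 / res.group_sizes[i] + 1.0 / res.group_sizes[j])
            )
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, res.df_within))
            comparisons.append(TukeyComparison(i, j, float(diff), p_adj, p_adj < alpha))
    return TukeyResult(comparisons, alpha)


@dataclass
class CorrelationSummary:
    pair: tuple[str, str]
    per_participant: dict[str, float]
    mean: float
    sd: float  # sample SD across participants; NaN for a single participant


def correlation_table(
    features: Mapping[str, Mapping[str, np.ndarray]],
) -> list[CorrelationSummary]:
    """Pairwise Pearson CCs per participant, aggregated across participants.

    ``features`` maps participant id -> {feature label -> aligned value
    array}; all arrays of one participant must be paired (equal length).
    A participant missing a feature is omitted from the affected pairs
    with a warning.  The cross-participant SD uses the sample (n-1)
    convention and is NaN when only one participant contributes.
    """
    labels: list[str] = []
    for feats in features.values():
        for lab in feats:
            if lab not in labels:
                labels.append(lab)
    out = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            per = {}
            for pid, feats in features.items():
                if la not in feats or lb not in feats:
                    warnings.warn(
                        f"participant {pid!r} missing {la!r} or {lb!r}; omitted",
                        stacklevel=2,
                    )
                    continue
                a = np.asarray(feats[la], dtype=float)
                b = np.asarray(feats[lb], dtype=float)
                m = np.isfinite(a) & np.isfinite(b)  # pairwise deletion of invalid spans
                if m.sum() < 3:
                    warnings.warn(
                        f"participant {pid!r}: fewer than 3 paired points for "
                        f"({la!r}, {lb!r}); omitted",
                        stacklevel=2,
                    )
                    continue
                per[pid] = pearson_cc(a[m], b[m])
            ccs = np.array(list(per.values()))
            mean = float(ccs.mean()) if ccs.size else float("nan")
            sd = float(ccs.std(ddof=1)) if ccs.size > 1 else float("nan")
            out.append(CorrelationSummary((la, lb), per, mean, sd))
    return out


def correlation_summary_frame(summaries: Sequence[CorrelationSummary]) -> pd.DataFrame:
    rows = [
        {"feature_a": s.pair[0], "feature_b": s.pair[1], "mean": s.mean, "sd": s.sd}
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "mean", "sd"])
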