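"""Model/Results surface of the workload analysis.

Two levels mirror the study design:

* :class:`WorkloadSessionModel` — one participant's streams.  ``fit()``
  runs the full measurement pipeline (EEG index, visual entropy, task
  index, click counts), places everything on a common 5-s grid,
  min-max normalizes, forms the fused physiological and objective
  measures, and returns a :class:`SessionResults` carrying the series,
  per-phase means and the participant's pairwise correlations.
* :class:`WorkloadStudy` — several sessions (participants).  ``fit()``
  z-scores each participant's per-phase means, runs the one-way ANOVA
  and Tukey HSD across phases for every measure, and aggregates the
  feature-pair correlations as mean +/- SD across participants,
  returning a :class:`StudyResults`.

Both results objects expose ``summary()``; plotting and synthetic-data
construction hang off the models/results.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eeg import EEGRecording, compute_eeg_index_series
from .errors import MWLError, MissingStreamError
from .gaze import GazeStream, ROILayout, entropy_series
from .schedule import MISSION_PHASES, PHASE_LABELS, PhaseSchedule
from .series import IndexSeries, resample_locf
from .stats import (
    AnovaResult,
    FusionWeights,
    TukeyResult,
    WEIGHT_SETS,
    correlation_summary_frame,
    correlation_table,
    fuse_series,
    minmax_normalize,
    oneway_anova,
    tukey_hsd,
    zscore_phase_means,
)
from .synthetic import SessionBundle, SessionConfig, generate_session
from .tasks import (
    ClickLog,
    DEFAULT_PENALTY_TABLE,
    PenaltyTable,
    UAVLogSet,
    click_count_series,
    task_index_series,
)

#: Feature labels in canonical (report) order.
FEATURES = (
    "eeg_index", "visual_entropy", "task_index", "control_input",
    "fused_physio", "fused_objective",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Stage parameters of the analysis pipeline.

    Defaults follow the measurement protocol: 0.5-30 Hz EEG bandpass,
    5-s index windows, 3-SD outlier replacement, 60-s smoothing, 60-s
    entropy windows, 2-min click bins and 50/50 fusion weights.
    """

    step_s: float = 5.0
    eeg_low_hz: float = 0.5
    eeg_high_hz: float = 30.0
    eeg_win_s: float = 5.0
    k_sd: float = 3.0
    smooth_s: float = 60.0
    entropy_window_s: float = 60.0
    gap_max_s: float = 1.0
    min_transitions: int = 5
    click_bin_s: float = 120.0
    penalty_table: PenaltyTable = field(default_factory=PenaltyTable)
    physio_weights: FusionWeights = field(default_factory=lambda: WEIGHT_SETS["50/50"])
    objective_weights: FusionWeights = field(default_factory=lambda: WEIGHT_SETS["50/50"])
    anova_phases: str = "mission"  # 'mission' (Phase1-3) or 'all' (five phases)

    def with_weights(self, w_eeg: float, w_entropy: float) -> "AnalysisConfig":
        return replace(self, physio_weights=FusionWeights(w_eeg, w_entropy))


def _series_to_grid(series: IndexSeries, grid: np.ndarray, step_s: float) -> IndexSeries:
    """Place a series onto the session grid: native match or LOCF."""
    if np.isclose(series.step_s, step_s):
        idx = np.searchsorted(series.t_s, grid - 1e-9)
        idx_c = np.clip(idx, 0, len(series) - 1)
        on = np.abs(series.t_s[idx_c] - grid) < 1e-6
        values = np.where(on, series.values[idx_c], np.nan)
        flagged = ~on | series.flagged[idx_c]
        return IndexSeries(grid, values, step_s, series.label, flagged)
    return resample_locf(series, grid, step_s)


@dataclass
class SessionResults:
    """Fitted measures of one participant's session."""

    participant: str
    schedule: PhaseSchedule
    config: AnalysisConfig
    series: dict[str, IndexSeries]          # raw derived series per measure
    aligned: pd.DataFrame                   # normalized features on the 5-s grid
    phase_means: pd.DataFrame               # measure x phase raw means
    correlations: pd.DataFrame              # feature pair -> cc (this participant)
    n_eeg_outliers: int
    ratings: pd.DataFrame | None = None
    eeg_replaced: np.ndarray | None = None      # windows substituted as outliers
    entropy_n_transitions: np.ndarray | None = None

    def phase_anova(
        self, phases: Sequence[str] = MISSION_PHASES
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Phase ANOVA + Tukey per measure, using this session's window
        values per phase as the groups.

        Within one session the window values are autocorrelated, so the
        nominal p-values overstate significance; use this as a design
        check on synthetic data, not as cross-participant inference
        (that lives in :class:`WorkloadStudy`).
        """
        anova_rows, tukey_rows = [], []
        for name, s in self.series.items():
            groups = []
            for lab in phases:
                p = self.schedule.phase(lab)
                groups.append(s.restrict(p.start_s, p.end_s).valid_values)
            if any(len(g) < 2 for g in groups):
                continue
            res = oneway_anova(groups)
            anova_rows.append(
                {"measure": name, "F": res.F, "df1": res.df_between,
                 "df2": res.df_within, "p": res.p}
            )
            for c in tukey_hsd(groups).comparisons:
                tukey_rows.append(
                    {"measure": name, "group_a": phases[c.group_a],
                     "group_b": phases[c.group_b], "mean_diff": c.mean_diff,
                     "p_adj": c.p_adj, "significant": c.significant}
                )
        return (
            pd.DataFrame(anova_rows, columns=["measure", "F", "df1", "df2", "p"]),
            pd.DataFrame(
                tukey_rows,
                columns=["measure", "group_a", "group_b", "mean_diff", "p_adj",
                         "significant"],
            ),
        )

    def feature_arrays(self) -> dict[str, np.ndarray]:
        """Aligned feature columns (NaN where flagged) for correlation."""
        return {f: self.aligned[f].to_numpy() for f in FEATURES if f in self.aligned}

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write(f"Workload session results — participant {self.participant}\n")
        buf.write(f"EEG index windows replaced as outliers: {self.n_eeg_outliers}\n\n")
        buf.write("Per-phase means (raw scale):\n")
        buf.write(self.phase_means.to_string(float_format=lambda v: f"{v:.3f}"))
        buf.write("\n\nPairwise Pearson correlations (aligned, normalized):\n")
        buf.write(self.correlations.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        buf.write("\n")
        return buf.getvalue()

    def plot_overlay(self, ax=None, features=("task_index", "visual_entropy", "eeg_index")):
        """Overlay of normalized measures against time (one axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        t = self.aligned.index.to_numpy()
        for f in features:
            ax.plot(t, self.aligned[f].to_numpy(), label=f)
        for p in self.schedule.phases[1:]:
            ax.axvline(p.start_s, color="0.8", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized value")
        ax.set_ylim(-0.05, 1.05)
        ax.legend(loc="upper left", fontsize="small")
        return ax


class WorkloadSessionModel:
    """One participant's session, ready to be fitted.

    Parameters
    ----------
    eeg, gaze, uav_logs, clicks
        The four measured streams.  Any of ``gaze``/``clicks`` may be
        None in partial mode; the EEG recording and UAV logs are
        mandatory for a fit to make sense, but a missing stream simply
        drops its dependent features from the results.
    schedule : PhaseSchedule
        The session's phase timing.
    layout : ROILayout
        Screen regions used as the gaze transition states.
    """

    def __init__(
        self,
        eeg: EEGRecording | None,
        gaze: GazeStream | None,
        uav_logs: UAVLogSet | None,
        clicks: ClickLog | None,
        schedule: PhaseSchedule,
        layout: ROILayout | None = None,
        ratings: pd.DataFrame | None = None,
        participant: str = "p1",
        config: AnalysisConfig | None = None,
    ):
        if eeg is None and gaze is None and uav_logs is None:
            raise MissingStreamError("no input streams provided")
        self.eeg = eeg
        self.gaze = gaze
        self.uav_logs = uav_logs
        self.clicks = clicks
        self.schedule = schedule
        self.layout = layout
        self.ratings = ratings
        self.participant = participant
        self.config = config or AnalysisConfig()

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_bundle(
        cls,
        bundle: SessionBundle,
        config: AnalysisConfig | None = None,
        participant: str = "p1",
    ) -> "WorkloadSessionModel":
        return cls(
            bundle.eeg, bundle.gaze, bundle.uav_logs, bundle.clicks,
            bundle.schedule, bundle.config.gaze.layout, bundle.ratings,
            participant, config,
        )

    @classmethod
    def from_synthetic(
        cls,
        seed: int,
        session_config: SessionConfig | None = None,
        config: AnalysisConfig | None = None,
        participant: str | None = None,
    ) -> "WorkloadSessionModel":
        bundle = generate_session(session_config or SessionConfig(), seed)
        return cls.from_bundle(
            bundle, config, participant or f"seed{seed}"
        )

    @classmethod
    def from_csv_dir(
        cls,
        path,
        config: AnalysisConfig | None = None,
        participant: str = "p1",
        partial: bool = False,
    ) -> "WorkloadSessionModel":
        """Load a session from the canonical CSV directory layout.

        With ``partial=True`` a missing stream file is tolerated and its
        dependent measures are dropped; otherwise it raises naming the
        missing file.
        """
        from pathlib import Path

        from . import io as mio

        p = Path(path)
        schedule = mio.read_schedule_csv(p / "schedule.csv")
        layout = mio.read_rois_csv(p / "rois.csv") if (p / "rois.csv").exists() else None

        def maybe(reader, name):
            try:
                return reader(p / name)
            except MissingStreamError:
                if partial:
                    return None
                raise

        eeg = maybe(mio.read_eeg_csv, "eeg.csv")
        gaze = maybe(mio.read_gaze_csv, "gaze.csv")
        logs = maybe(mio.read_uav_logs_csv, "uav_logs.csv")
        clicks = maybe(mio.read_clicks_csv, "clicks.csv")
        ratings = (
            mio.read_ratings_csv(p / "ratings.csv")
            if (p / "ratings.csv").exists()
            else None
        )
        return cls(eeg, gaze, logs, clicks, schedule, layout, ratings, participant, config)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> SessionResults:
        cfg = self.config
        span = (self.schedule.start_s, self.schedule.end_s)
        series: dict[str, IndexSeries] = {}
        n_outliers = 0
        eeg_replaced = None
        entropy_ntrans = None
        if self.eeg is not None:
            eeg_res = compute_eeg_index_series(
                self.eeg,
                low_hz=cfg.eeg_low_hz, high_hz=cfg.eeg_high_hz,
                win_s=cfg.eeg_win_s, k_sd=cfg.k_sd, smooth_s=cfg.smooth_s,
            )
            series["eeg_index"] = eeg_res.series
            n_outliers = eeg_res.n_replaced
            eeg_replaced = eeg_res.replaced
        if self.gaze is not None:
            if self.layout is None:
                raise MissingStreamError("gaze supplied without an ROI layout (rois.csv)")
            ent = entropy_series(
                self.gaze, self.layout,
                window_s=cfg.entropy_window_s, step_s=cfg.step_s,
                gap_max_s=cfg.gap_max_s, min_transitions=cfg.min_transitions,
            )
            series["visual_entropy"] = ent.series
            entropy_ntrans = ent.n_transitions
        if self.uav_logs is not None:
            series["task_index"] = task_index_series(
                self.uav_logs, cfg.penalty_table, cfg.step_s, span
            )
        if self.clicks is not None:
            series["control_input"] = click_count_series(
                self.clicks, cfg.click_bin_s, span
            )

        grid = np.arange(span[0], span[1] - 1e-9, cfg.step_s)
        aligned = pd.DataFrame(index=pd.Index(grid, name="t_s"))
        normed: dict[str, IndexSeries] = {}
        for name, s in series.items():
            on_grid = _series_to_grid(s, grid, cfg.step_s)
            normed[name] = minmax_normalize(on_grid)
            aligned[name] = np.where(normed[name].valid, normed[name].values, np.nan)
        if "eeg_index" in normed and "visual_entropy" in normed:
            fused = fuse_series(
                normed["eeg_index"], normed["visual_entropy"],
                cfg.physio_weights, label="fused_physio",
            )
            normed["fused_physio"] = fused
            aligned["fused_physio"] = np.where(fused.valid, fused.values, np.nan)
        if "task_index" in normed and "control_input" in normed:
            fused = fuse_series(
                normed["task_index"], normed["control_input"],
                cfg.objective_weights, label="fused_objective",
            )
            normed["fused_objective"] = fused
            aligned["fused_objective"] = np.where(fused.valid, fused.values, np.nan)

        phase_rows = {}
        for name, s in series.items():
            row = {}
            for lab in PHASE_LABELS:
                ph = self.schedule.phase(lab)
                row[lab] = s.restrict(ph.start_s, ph.end_s).mean()
            phase_rows[name] = row
        phase_means = pd.DataFrame(phase_rows).T.reindex(columns=list(PHASE_LABELS))

        cc_rows = []
        cols = [f for f in FEATURES if f in aligned.columns]
        for i, fa in enumerate(cols):
            for fb in cols[i + 1 :]:
                a = aligned[fa].to_numpy()
                b = aligned[fb].to_numpy()
                m = np.isfinite(a) & np.isfinite(b)
                from .stats import pearson_cc

                cc = pearson_cc(a[m], b[m]) if m.sum() >= 3 else float("nan")
                cc_rows.append({"feature_a": fa, "feature_b": fb, "cc": cc})
        correlations = pd.DataFrame(cc_rows, columns=["feature_a", "feature_b", "cc"])

        return SessionResults(
            self.participant, self.schedule, cfg, series, aligned,
            phase_means, correlations, n_outliers, self.ratings,
            eeg_replaced, entropy_ntrans,
        )


@dataclass
class MeasureAnova:
    measure: str
    phases: tuple[str, ...]
    anova: AnovaResult
    tukey: TukeyResult


@dataclass
class StudyResults:
    """Cross-participant phase statistics and correlation aggregation."""

    sessions: list[SessionResults]
    anovas: dict[str, MeasureAnova]
    phase_summaries: pd.DataFrame  # participant, measure, phase, raw_mean, z_mean
    correlation_summary: pd.DataFrame
    correlations: pd.DataFrame     # participant-level pair CCs

    @property
    def anova_table(self) -> pd.DataFrame:
        rows = []
        for name, ma in self.anovas.items():
            rows.append(
                {
                    "measure": name,
                    "F": ma.anova.F,
                    "df1": ma.anova.df_between,
                    "df2": ma.anova.df_within,
                    "p": ma.anova.p,
                }
            )
        return pd.DataFrame(rows, columns=["measure", "F", "df1", "df2", "p"])

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write(f"Workload study results — {len(self.sessions)} participants\n\n")
        buf.write("One-way ANOVA across phases:\n")
        buf.write(
            self.anova_table.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            )
        )
        buf.write("\n\nTukey HSD significant pairs (alpha = 0.05):\n")
        for name, ma in self.anovas.items():
            pairs = [
                f"{ma.phases[c.group_a]}–{ma.phases[c.group_b]}"
                for c in ma.tukey.comparisons
                if c.significant
            ]
            buf.write(f"  {name}: {', '.join(pairs) if pairs else '(none)'}\n")
        buf.write("\nFeature-pair correlations, mean ± SD across participants:\n")
        df = self.correlation_summary
        for row in df.itertuples():
            sd = f"{row.sd:.2f}" if np.isfinite(row.sd) else "n/a"
            buf.write(
                f"  {row.feature_a} vs {row.feature_b}: {row.mean:.3f} ± {sd}\n"
            )
        return buf.getvalue()


class WorkloadStudy:
    """A collection of participants' sessions analysed together."""

    def __init__(
        self,
        models: Sequence[WorkloadSessionModel],
        config: AnalysisConfig | None = None,
    ):
        if not models:
            raise MWLError("study needs at least one session")
        self.models = list(models)
        self.config = config or (models[0].config if models else AnalysisConfig())

    @classmethod
    def from_synthetic(
        cls,
        n_participants: int,
        seed: int,
        session_config: SessionConfig | None = None,
        config: AnalysisConfig | None = None,
    ) -> "WorkloadStudy":
        """Simulate ``n_participants`` independent sessions from one seed."""
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_participants)]
        models = [
            WorkloadSessionModel.from_synthetic(
                s, session_config, config, participant=f"p{i + 1}"
            )
            for i, s in enumerate(seeds)
        ]
        return cls(models, config)

    def fit(self) -> StudyResults:
        results = [m.fit() for m in self.models]
        schedule = results[0].schedule
        mission = list(MISSION_PHASES)
        all_phases = list(PHASE_LABELS)

        # per-participant z-scored phase means per measure
        z_rows = []
        measures = [m for m in ("task_index", "control_input", "visual_entropy", "eeg_index")
                    if all(m in r.series for r in results)]
        grid = results[0].aligned.index.to_numpy()
        step = self.config.step_s
        for r in results:
            for m in measures:
                # coarse bins (clicks) are spread onto the common grid first so
                # a phase mean weights each bin by its overlap with the phase
                on_grid = _series_to_grid(r.series[m], grid, step)
                summ = zscore_phase_means(
                    on_grid, schedule, all_phases, participant=r.participant
                )
                for ph, raw, z in zip(summ.phases, summ.raw_means, summ.z_means):
                    z_rows.append(
                        {
                            "participant": r.participant, "measure": m,
                            "phase": ph, "raw_mean": raw, "z_mean": z,
                        }
                    )
            if r.ratings is not None:
                for row in r.ratings.itertuples():
                    z_rows.append(
                        {
                            "participant": r.participant, "measure": "subjective_mwl",
                            "phase": row.phase, "raw_mean": row.mwl, "z_mean": np.nan,
                        }
                    )
                    z_rows.append(
                        {
                            "participant": r.participant, "measure": "subjective_sa",
                            "phase": row.phase, "raw_mean": row.sa, "z_mean": np.nan,
                        }
                    )
        phase_summaries = pd.DataFrame(
            z_rows, columns=["participant", "measure", "phase", "raw_mean", "z_mean"]
        )

        def groups_for(measure: str, phases: list[str], column: str):
            sub = phase_summaries[phase_summaries["measure"] == measure]
            out = []
            for ph in phases:
                vals = sub[sub["phase"] == ph][column].to_numpy()
                out.append(vals)
            return out

        anovas: dict[str, MeasureAnova] = {}
        if len(results) >= 2:
            if any(r.ratings is not None for r in results):
                for name in ("subjective_mwl", "subjective_sa"):
                    g = groups_for(name, mission, "raw_mean")
                    if all(len(v) >= 2 for v in g):
                        anovas[name] = MeasureAnova(
                            name, tuple(mission), oneway_anova(g), tukey_hsd(g)
                        )
            for m in measures:
                g = groups_for(m, mission, "z_mean")
                anovas[m] = MeasureAnova(m, tuple(mission), oneway_anova(g), tukey_hsd(g))
            if "eeg_index" in measures:
                g = groups_for("eeg_index", all_phases, "z_mean")
                anovas["eeg_index_all_phases"] = MeasureAnova(
                    "eeg_index_all_phases", tuple(all_phases), oneway_anova(g), tukey_hsd(g)
                )

        features: Mapping[str, Mapping[str, np.ndarray]] = {
            r.participant: r.feature_arrays() for r in results
        }
        summaries = correlation_table(features)
        corr_summary = correlation_summary_frame(summaries)
        corr_rows = []
        for s in summaries:
            for pid, cc in s.per_participant.items():
                corr_rows.append(
                    {
                        "feature_a": s.pair[0], "feature_b": s.pair[1],
                        "participant": pid, "cc": cc,
                    }
                )
        correlations = pd.DataFrame(
            corr_rows, columns=["feature_a", "feature_b", "participant", "cc"]
        )
        return StudyResults(results, anovas, phase_summaries, corr_summary, correlations)
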