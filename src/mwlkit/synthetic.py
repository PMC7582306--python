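"""Synthetic one-to-many UAV session generator.

Generates complete sessions — multi-channel EEG, binocular gaze, UAV
flight logs, mouse clicks and per-phase subjective ratings — whose
statistical structure carries a shared latent workload profile, kept as
ground truth so the analysis pipeline can be tested for recovery
without any recorded data.

Encoding of workload in each stream:

* EEG: 1/f^beta background plus white noise on all 16 channels of the
  10-20 montage; a theta-band (6 Hz) component on F4/C4 whose amplitude
  increases linearly with workload and an alpha-band (10 Hz) component
  on O1/O2 whose amplitude decreases linearly, matching the frontal
  theta rise / occipital alpha suppression seen under mental load.
* Gaze: a Markov scanpath over ROI centers whose transition rows move
  from a deterministic cycle towards uniformity as workload grows, so
  the visual entropy of the scan rises with workload.  Tracker dropout
  is generated in contiguous bursts (both eyes invalid), emulating a
  participant drifting out of camera range.
* UAV logs: per-category degrade/repair processes whose degrade hazard
  grows with workload; more UAVs are released at each mission phase.
* Clicks: an inhomogeneous Poisson process whose rate grows linearly
  with workload.

Every generator is a pure function of (config, seed); the master seed
is split into per-stream children so adding a stream never perturbs
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eeg import CHANNELS_1020, EEGRecording
from .errors import ConfigError
from .gaze import GazeStream, ROILayout, cyclic_transition_matrix
from .schedule import (
    MISSION_PHASES,
    PhaseSchedule,
    WorkloadProfile,
    generate_workload_profile,
    make_phase_schedule,
)
from .tasks import ClickLog, UAVLogSet

__all__ = [
    "EEGGenConfig", "GazeGenConfig", "UAVGenConfig", "ClickGenConfig",
    "RatingsConfig", "SessionConfig", "SessionBundle",
    "generate_eeg", "generate_gaze", "generate_uav_logs",
    "generate_clicks", "generate_ratings", "generate_session",
]


@dataclass(frozen=True)
class EEGGenConfig:
    """EEG stream parameters (amplitudes in microvolts)."""

    fs: float = 128.0
    channels: tuple[str, ...] = CHANNELS_1020
    theta_hz: float = 6.0
    alpha_hz: float = 10.0
    theta_base: float = 1.0          # theta amplitude at zero workload
    theta_gain: float = 1.0          # amplitude increase per workload unit
    alpha_base: float = 4.0          # alpha amplitude at zero workload
    alpha_suppression: float = 1.5   # amplitude decrease per workload unit
    noise_amp: float = 1.0           # RMS of the 1/f^beta background
    noise_exponent: float = 1.0      # beta of the background spectrum
    white_amp: float = 0.3           # RMS of additive white noise
    amp_mod_sd: float = 0.12         # fractional slow waxing/waning of each rhythm
    amp_mod_tau_s: float = 45.0      # correlation time of the amplitude drift
    artifact_rate_per_min: float = 0.1
    artifact_amp: float = 150.0

    def __post_init__(self):
        if self.fs < 64:
            raise ConfigError("eeg sampling rate must be >= 64 Hz", key="eeg.fs")
        for ch in ("F4", "C4", "O1", "O2"):
            if ch not in self.channels:
                raise ConfigError(f"required channel {ch} missing", key="eeg.channels")
        if self.alpha_base - self.alpha_suppression <= 0:
            raise ConfigError(
                "alpha amplitude must stay positive at full workload",
                key="eeg.alpha_suppression",
            )


@dataclass(frozen=True)
class GazeGenConfig:
    """Gaze stream parameters; coordinates live on the unit square."""

    fs: float = 60.0
    layout: ROILayout = field(default_factory=lambda: ROILayout.grid(2, 3))
    dwell_mean_s: float = 0.5
    randomness_base: float = 0.05    # row contamination at zero workload
    randomness_gain: float = 0.6     # contamination increase per workload unit
    jitter_sd: float = 0.02
    dropout_fraction: float = 0.02
    dropout_burst_mean_s: float = 0.2
    single_eye_dropout: float = 0.01

    def __post_init__(self):
        if self.fs < 10:
            raise ConfigError("gaze sampling rate must be >= 10 Hz", key="gaze.fs")
        if len(self.layout) < 3:
            raise ConfigError("gaze layout needs >= 3 ROIs", key="gaze.layout")
        if not 0 <= self.dropout_fraction < 1:
            raise ConfigError("dropout_fraction must lie in [0, 1)", key="gaze.dropout_fraction")

    def randomness_at(self, workload: np.ndarray) -> np.ndarray:
        """Row contamination for a workload level, clipped to the valid range."""
        n = len(self.layout)
        eps = self.randomness_base + self.randomness_gain * np.asarray(workload)
        return np.clip(eps, 0.0, (n - 2) / (n - 1))


@dataclass(frozen=True)
class UAVGenConfig:
    """Fleet size per phase and subsystem degradation dynamics."""

    counts: tuple[int, ...] = (0, 3, 6, 9, 9)
    log_step_s: float = 5.0
    base_event_rate_per_min: float = 0.3    # degrade hazard per UAV-category
    event_rate_gain_per_min: float = 0.3    # hazard increase per workload unit
    repair_mean_s: float = 45.0
    partial_prob: float = 0.5               # P(half-penalty severity) for graded categories

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ConfigError("uav counts must be non-negative", key="uav.counts")
        if any(b > a for a, b in zip(self.counts[1:], self.counts[:-1])):
            raise ConfigError("uav counts must be non-decreasing", key="uav.counts")
        if self.base_event_rate_per_min < 0 or self.event_rate_gain_per_min < 0:
            raise ConfigError("event rates must be non-negative", key="uav.rates")


@dataclass(frozen=True)
class ClickGenConfig:
    base_rate_hz: float = 0.1
    rate_gain_hz: float = 0.7

    def __post_init__(self):
        if self.base_rate_hz < 0 or self.rate_gain_hz < 0:
            raise ConfigError("click rates must be non-negative", key="clicks")


@dataclass(frozen=True)
class RatingsConfig:
    """Per-mission-phase subjective rating distributions (0-10 scales)."""

    mwl_means: tuple[float, ...] = (2.9, 5.9, 7.8)
    sa_means: tuple[float, ...] = (9.6, 6.2, 4.0)
    noise_sd: float = 0.5


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to generate one synthetic session."""

    schedule: PhaseSchedule = field(default_factory=make_phase_schedule)
    levels: tuple[float, ...] = (0.05, 0.2, 0.55, 0.9, 0.15)
    grid_step_s: float = 5.0
    eeg: EEGGenConfig = field(default_factory=EEGGenConfig)
    gaze: GazeGenConfig = field(default_factory=GazeGenConfig)
    uav: UAVGenConfig = field(default_factory=UAVGenConfig)
    clicks: ClickGenConfig = field(default_factory=ClickGenConfig)
    ratings: RatingsConfig = field(default_factory=RatingsConfig)

    def with_levels(self, levels) -> "SessionConfig":
        return replace(self, levels=tuple(levels))


@dataclass
class SessionBundle:
    """All streams of one synthetic participant plus the ground truth."""

    schedule: PhaseSchedule
    truth: WorkloadProfile
    eeg: EEGRecording
    gaze: GazeStream
    uav_logs: UAVLogSet
    clicks: ClickLog
    ratings: pd.DataFrame  # columns: phase, mwl, sa
    config: SessionConfig
    seed: int


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _ou_modulation(
    rng: np.random.Generator, t: np.ndarray, sd: float, tau_s: float
) -> np.ndarray:
    """Slow mean-1 multiplicative drift: 1 + an Ornstein-Uhlenbeck process.

    Simulated on a coarse 1-s grid and held piecewise constant; models the
    spontaneous waxing/waning of a rhythm's amplitude that is unrelated to
    workload.  Clipped at zero so amplitudes stay non-negative.
    """
    if sd <= 0:
        return np.ones_like(t)
    step = 1.0
    grid = np.arange(t[0], t[-1] + step, step)
    a = np.exp(-step / tau_s)
    x = np.empty(grid.size)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), grid.size - 1)
    for k in range(1, grid.size):
        x[k] = a * x[k - 1] + innov[k - 1]
    idx = np.clip(np.searchsorted(grid, t, side="right") - 1, 0, None)
    return np.maximum(1.0 + x[idx], 0.0)


def generate_eeg(
    profile: WorkloadProfile,
    cfg: EEGGenConfig,
    seed: int | np.random.SeedSequence,
) -> EEGRecording:
    """Synthesize the multi-channel EEG recording over the profile span.

    Each rhythm's amplitude is the workload-driven level times a shared
    slow stochastic modulation (waxing/waning), so the derived index
    carries realistic drift that simple time-averaging cannot remove.
    """
    rng = np.random.default_rng(seed)
    span = profile.grid_s[-1] + (profile.grid_s[1] - profile.grid_s[0]) - profile.grid_s[0]
    n = int(round(span * cfg.fs))
    t = profile.grid_s[0] + np.arange(n) / cfg.fs
    w = profile.level_at(t)
    theta_mod = _ou_modulation(rng, t, cfg.amp_mod_sd, cfg.amp_mod_tau_s)
    alpha_mod = _ou_modulation(rng, t, cfg.amp_mod_sd, cfg.amp_mod_tau_s)
    data = np.zeros((len(cfg.channels), n))
    for i, ch in enumerate(cfg.channels):
        row = np.zeros(n)
        if cfg.noise_amp > 0:
            row += cfg.noise_amp * _pink_noise(rng, n, cfg.fs, cfg.noise_exponent)
        if cfg.white_amp > 0:
            row += cfg.white_amp * rng.standard_normal(n)
        if ch in ("F4", "C4"):
            amp = (cfg.theta_base + cfg.theta_gain * w) * theta_mod
            row += amp * np.sin(2 * np.pi * cfg.theta_hz * t + rng.uniform(0, 2 * np.pi))
        if ch in ("O1", "O2"):
            amp = np.maximum(cfg.alpha_base - cfg.alpha_suppression * w, 0.0) * alpha_mod
            row += amp * np.sin(2 * np.pi * cfg.alpha_hz * t + rng.uniform(0, 2 * np.pi))
        data[i] = row
    # sparse large-amplitude artifact bursts (blink/movement-like spikes)
    if cfg.artifact_rate_per_min > 0 and cfg.artifact_amp > 0:
        n_art = rng.poisson(cfg.artifact_rate_per_min * span / 60.0)
        width = 0.1  # seconds
        for _ in range(n_art):
            t_art = rng.uniform(t[0], t[-1])
            pulse = cfg.artifact_amp * np.exp(-0.5 * ((t - t_art) / width) ** 2)
            data += rng.choice([-1.0, 1.0]) * pulse[None, :]
    return EEGRecording(cfg.fs, cfg.channels, data, t0_s=float(t[0]))


def _alternating_runs(
    rng: np.random.Generator, n: int, frac: float, burst_mean: int
) -> np.ndarray:
    """Boolean mask with stationary True fraction ``frac`` in geometric bursts."""
    if frac <= 0:
        return np.zeros(n, dtype=bool)
    p_exit = 1.0 / max(burst_mean, 1)
    p_enter = frac * p_exit / (1.0 - frac)
    mask = np.zeros(n, dtype=bool)
    pos = 0
    state = rng.random() < frac
    while pos < n:
        p = p_exit if state else p_enter
        run = rng.geometric(min(max(p, 1e-12), 1.0))
        mask[pos : pos + run] = state
        pos += run
        state = not state
    return mask


def generate_gaze(
    profile: WorkloadProfile,
    cfg: GazeGenConfig,
    seed: int | np.random.SeedSequence,
) -> GazeStream:
    """Markov-scanpath gaze stream with workload-dependent randomness."""
    rng = np.random.default_rng(seed)
    layout = cfg.layout
    n_roi = len(layout)
    step = profile.grid_s[1] - profile.grid_s[0]
    t0, t_end = profile.grid_s[0], profile.grid_s[-1] + step
    n = int(round((t_end - t0) * cfg.fs))
    t = t0 + np.arange(n) / cfg.fs

    # dwell-by-dwell scanpath
    states = np.empty(n, dtype=int)
    pos = 0
    state = int(rng.integers(n_roi))
    min_dwell = 1.0 / cfg.fs
    while pos < n:
        dwell = max(rng.exponential(cfg.dwell_mean_s), min_dwell)
        run = max(int(round(dwell * cfg.fs)), 1)
        states[pos : pos + run] = state
        t_switch = t0 + min(pos + run, n - 1) / cfg.fs
        eps = float(cfg.randomness_at(profile.level_at(t_switch)))
        P = cyclic_transition_matrix(n_roi, eps)
        state = int(rng.choice(n_roi, p=P[state]))
        pos += run

    centers = np.array([r.center for r in layout.regions])
    x = centers[states, 0] + rng.normal(0, cfg.jitter_sd, n)
    y = centers[states, 1] + rng.normal(0, cfg.jitter_sd, n)
    x = np.clip(x, 0.0, 1.0 - 1e-9)
    y = np.clip(y, 0.0, 1.0 - 1e-9)

    burst_mean = max(int(round(cfg.dropout_burst_mean_s * cfg.fs)), 1)
    shared_invalid = _alternating_runs(rng, n, cfg.dropout_fraction, burst_mean)
    left_valid = ~shared_invalid & (rng.random(n) >= cfg.single_eye_dropout)
    right_valid = ~shared_invalid & (rng.random(n) >= cfg.single_eye_dropout)

    disparity = 0.003
    left_x = np.where(left_valid, x + rng.normal(0, disparity, n), np.nan)
    left_y = np.where(left_valid, y + rng.normal(0, disparity, n), np.nan)
    right_x = np.where(right_valid, x + rng.normal(0, disparity, n), np.nan)
    right_y = np.where(right_valid, y + rng.normal(0, disparity, n), np.nan)
    return GazeStream(
        t, left_x, left_y, left_valid, right_x, right_y, right_valid,
        blink=shared_invalid,
    )


# graded categories take a half/full severity; binary ones are always full
_GRADED = ("nav", "comm", "fuel")
_BINARY = ("hold", "team", "sensors")
_CATEGORIES = _GRADED + _BINARY

_NOMINAL = {
    "nav_acc_m": 6.0, "comm_pct": 85.0, "fuel_onboard": 300.0, "fuel_needed": 100.0,
}
_DEGRADED = {
    # category -> (partial, full) field values
    "nav": ("nav_acc_m", 15.0, 30.0),
    "comm": ("comm_pct", 60.0, 40.0),
    "fuel": ("fuel_onboard", 170.0, 120.0),
}


def generate_uav_logs(
    schedule: PhaseSchedule,
    cfg: UAVGenConfig,
    seed: int | np.random.SeedSequence,
    profile: WorkloadProfile | None = None,
) -> UAVLogSet:
    """Per-UAV subsystem state logs with workload-driven degradation.

    UAVs are released at phase starts according to ``cfg.counts``; each
    of the six penalty categories degrades with a hazard of
    ``base + gain * workload`` events per UAV-minute and self-repairs
    after an exponential time (the operator fixing the pending task).
    """
    if len(cfg.counts) != len(schedule.phases):
        raise ConfigError(
            f"expected {len(schedule.phases)} uav counts", key="uav.counts"
        )
    rng = np.random.default_rng(seed)
    n_uav = max(cfg.counts)
    if n_uav == 0:
        raise ConfigError("at least one UAV must be released", key="uav.counts")
    release = np.full(n_uav, np.inf)
    for phase, count in zip(schedule.phases, cfg.counts):
        for u in range(count):
            release[u] = min(release[u], phase.start_s)
    grid = np.arange(schedule.start_s, schedule.end_s, cfg.log_step_s)
    dt = cfg.log_step_s
    # state per uav per category: 0 nominal, 1 partial, 2 full
    state = np.zeros((n_uav, len(_CATEGORIES)), dtype=int)
    rows = {c: [] for c in ("t_s", "uav_id", "nav_acc_m", "comm_pct", "fuel_onboard",
                            "fuel_needed", "autopilot_hold", "in_team", "sensors_active")}
    p_repair = 1.0 - np.exp(-dt / cfg.repair_mean_s)
    for tk in grid:
        w = float(profile.level_at(tk)) if profile is not None else 0.0
        rate_per_s = (cfg.base_event_rate_per_min + cfg.event_rate_gain_per_min * w) / 60.0
        p_degrade = 1.0 - np.exp(-rate_per_s * dt)
        active = release <= tk
        u_draw = rng.random((n_uav, len(_CATEGORIES)))
        sev_draw = rng.random((n_uav, len(_CATEGORIES)))
        for u in range(n_uav):
            if not active[u]:
                continue
            for c in range(len(_CATEGORIES)):
                if state[u, c] == 0:
                    if u_draw[u, c] < p_degrade:
                        partial = (
                            _CATEGORIES[c] in _GRADED and sev_draw[u, c] < cfg.partial_prob
                        )
                        state[u, c] = 1 if partial else 2
                elif u_draw[u, c] < p_repair:
                    state[u, c] = 0
            rows["t_s"].append(float(tk))
            rows["uav_id"].append(f"uav{u + 1:02d}")
            vals = dict(_NOMINAL)
            for name in _GRADED:
                fldname, partial_v, full_v = _DEGRADED[name]
                s = state[u, _CATEGORIES.index(name)]
                if s == 1:
                    vals[fldname] = partial_v
                elif s == 2:
                    vals[fldname] = full_v
            rows["nav_acc_m"].append(vals["nav_acc_m"])
            rows["comm_pct"].append(vals["comm_pct"])
            rows["fuel_onboard"].append(vals["fuel_onboard"])
            rows["fuel_needed"].append(vals["fuel_needed"])
            rows["autopilot_hold"].append(state[u, _CATEGORIES.index("hold")] > 0)
            rows["in_team"].append(state[u, _CATEGORIES.index("team")] == 0)
            rows["sensors_active"].append(state[u, _CATEGORIES.index("sensors")] == 0)
    return UAVLogSet(pd.DataFrame(rows))


def generate_clicks(
    profile: WorkloadProfile,
    cfg: ClickGenConfig,
    seed: int | np.random.SeedSequence,
) -> ClickLog:
    """Inhomogeneous Poisson clicks with rate = base + gain * workload."""
    rng = np.random.default_rng(seed)
    step = profile.grid_s[1] - profile.grid_s[0] if profile.grid_s.size > 1 else 1.0
    t0, t_end = profile.grid_s[0], profile.grid_s[-1] + step
    rate_max = cfg.base_rate_hz + cfg.rate_gain_hz * float(profile.level.max(initial=0.0))
    if rate_max <= 0:
        return ClickLog(np.empty(0), np.empty(0, dtype=object))
    n_cand = rng.poisson(rate_max * (t_end - t0))
    t_cand = np.sort(rng.uniform(t0, t_end, n_cand))
    rate = cfg.base_rate_hz + cfg.rate_gain_hz * profile.level_at(t_cand)
    keep = rng.random(n_cand) < rate / rate_max
    t_click = t_cand[keep]
    buttons = rng.choice(np.array(["left", "right"], dtype=object), t_click.size, p=[0.7, 0.3])
    return ClickLog(t_click, buttons)


def generate_ratings(
    cfg: RatingsConfig, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Subjective workload / situational-awareness ratings per mission phase."""
    rng = np.random.default_rng(seed)
    mwl = np.clip(np.asarray(cfg.mwl_means) + rng.normal(0, cfg.noise_sd, 3), 0, 10)
    sa = np.clip(np.asarray(cfg.sa_means) + rng.normal(0, cfg.noise_sd, 3), 0, 10)
    return pd.DataFrame({"phase": list(MISSION_PHASES), "mwl": mwl, "sa": sa})


def generate_session(config: SessionConfig, seed: int) -> SessionBundle:
    """Generate one complete session; deterministic given (config, seed).

    The master seed is split into fixed-order per-stream children
    (eeg, gaze, uav, clicks, ratings) so streams are independent and
    individually reproducible.
    """
    ss = np.random.SeedSequence(seed)
    eeg_ss, gaze_ss, uav_ss, click_ss, rating_ss = ss.spawn(5)
    profile = generate_workload_profile(
        config.schedule, config.levels, config.grid_step_s
    )
    eeg = generate_eeg(profile, config.eeg, eeg_ss)
    gaze = generate_gaze(profile, config.gaze, gaze_ss)
    uav_logs = generate_uav_logs(config.schedule, config.uav, uav_ss, profile)
    clicks = generate_clicks(profile, config.clicks, click_ss)
    ratings = generate_ratings(config.ratings, rating_ss)
    return SessionBundle(
        config.schedule, profile, eeg, gaze, uav_logs, clicks, ratings, config, seed
    )
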