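"""EEG workload index.

The index is the ratio of average frontal/central theta-band power
(electrodes F4 and C4, 4-7 Hz) to average occipital alpha-band power
(electrodes O1 and O2, 8-12 Hz), computed on consecutive 5-s windows:

    index = mean(theta_F4, theta_C4) / mean(alpha_O1, alpha_O2)

Processing chain: 0.5-30 Hz zero-phase bandpass -> non-overlapping 5-s
windows -> linear detrend -> Welch PSD -> band integration -> ratio ->
3-SD outlier replacement -> zero-phase moving-average smoothing.

Theta power at frontal/central sites rises with mental workload while
occipital alpha power falls, so the ratio rises monotonically with
workload on both counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .errors import DegenerateDataError, MissingChannelError, ParameterError
from .series import IndexSeries

#: The 16-electrode montage of the 10-20 system used by the synthetic
#: generator; only F4, C4, O1 and O2 enter the index.
CHANNELS_1020 = (
    "F4", "Fz", "F3", "FC1", "FC2", "C3", "C4", "CP1",
    "CP2", "T7", "T8", "P3", "Pz", "P4", "O1", "O2",
)

THETA_CHANNELS = ("F4", "C4")
ALPHA_CHANNELS = ("O1", "O2")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with integration limits in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ParameterError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"[{self.low_hz}, {self.high_hz}]"
            )


THETA = BandDefinition("theta", 4.0, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)


@dataclass
class EEGRecording:
    """Multi-channel voltage time series (microvolts).

    ``data`` has shape (n_channels, n_samples); channel order matches
    ``channels``.
    """

    fs: float
    channels: tuple[str, ...]
    data: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channels = tuple(self.channels)
        if self.data.shape[0] != len(self.channels):
            raise ParameterError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows"
            )
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise MissingChannelError(f"channel {label!r} not in recording") from None

    def require_channels(self, labels: Sequence[str]) -> None:
        missing = [c for c in labels if c not in self.channels]
        if missing:
            raise MissingChannelError(f"missing channels: {missing}")


def bandpass_filter(
    rec: EEGRecording, low_hz: float = 0.5, high_hz: float = 30.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth bandpass, length preserving.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    band-limited copy has no phase distortion.
    """
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ParameterError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(rec.fs, rec.channels, filtered, rec.t0_s)


def segment_windows(rec: EEGRecording, win_s: float = 5.0):
    """Split into non-overlapping contiguous windows of ``win_s`` seconds.

    Returns ``(starts_s, windows)`` where ``windows`` has shape
    (n_windows, n_channels, samples_per_window).  A trailing remainder
    shorter than one window is discarded; a recording shorter than one
    window yields zero windows.
    """
    if win_s <= 0:
        raise ParameterError("win_s must be positive")
    nper = int(round(win_s * rec.fs))
    n_win = rec.n_samples // nper
    starts = rec.t0_s + np.arange(n_win) * win_s
    trimmed = rec.data[:, : n_win * nper]
    windows = trimmed.reshape(len(rec.channels), n_win, nper).transpose(1, 0, 2)
    return starts, windows


def band_power(
    window: np.ndarray,
    fs: float,
    band: BandDefinition,
    seg_s: float = 1.0,
) -> np.ndarray:
    """Band power (microvolt^2) of one or many single-channel windows.

    The window is linearly detrended, its PSD estimated by Welch's method
    (Hann-tapered ``seg_s``-second sub-windows, 50% overlap) and the PSD
    integrated over the band by the trapezoidal rule.  Vectorized over
    leading axes; the last axis is time.
    """
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < 2 * fs:
        raise ParameterError("window must be at least 2 s long")
    detrended = signal.detrend(window, axis=-1, type="linear")
    nperseg = int(round(seg_s * fs))
    freqs, psd = signal.welch(
        detrended,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        axis=-1,
    )
    m = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    power = np.trapezoid(psd[..., m], freqs[m], axis=-1)
    return power if power.ndim else float(power)


def eeg_index_window(
    theta_powers: Mapping[str, float], alpha_powers: Mapping[str, float]
) -> float:
    """Workload index for one window from per-channel band powers.

    Returns NaN when the occipital alpha denominator is not strictly
    positive; such windows are flagged and later treated as outliers.
    """
    for ch in THETA_CHANNELS:
        if ch not in theta_powers:
            raise MissingChannelError(f"theta power for {ch!r} missing")
    for ch in ALPHA_CHANNELS:
        if ch not in alpha_powers:
            raise MissingChannelError(f"alpha power for {ch!r} missing")
    num = np.mean([theta_powers[ch] for ch in THETA_CHANNELS])
    den = np.mean([alpha_powers[ch] for ch in ALPHA_CHANNELS])
    if not np.isfinite(den) or den <= 0 or not np.isfinite(num):
        return float("nan")
    return float(num / den)


@dataclass
class OutlierResult:
    series: IndexSeries
    n_replaced: int
    replaced: np.ndarray  # bool mask over the series


def reject_outliers(series: IndexSeries, k_sd: float = 3.0) -> OutlierResult:
    """Replace points beyond ``k_sd`` standard deviations from the mean.

    A single pass: mean and (sample) SD are computed over all valid
    points; points strictly beyond mean +/- k*SD — and any already
    flagged/invalid point — are replaced by the mean of the retained
    points.  The returned series is fully valid (no flags); the mask of
    replaced points and their count are reported alongside.
    """
    if len(series) == 0:
        raise DegenerateDataError("cannot reject outliers on an empty series")
    vals = series.values
    valid = series.valid
    if not valid.any():
        raise DegenerateDataError("series has no valid points")
    m = vals[valid].mean()
    sd = vals[valid].std(ddof=1) if valid.sum() > 1 else 0.0
    outlier = valid & (np.abs(vals - m) > k_sd * sd) if sd > 0 else np.zeros_like(valid)
    replaced = outlier | ~valid
    keep = ~replaced
    if not keep.any():
        raise DegenerateDataError("all points flagged as outliers")
    fill = vals[keep].mean()
    out = vals.copy()
    out[replaced] = fill
    cleaned = IndexSeries(
        series.t_s, out, series.step_s, series.label, np.zeros_like(replaced)
    )
    return OutlierResult(cleaned, int(replaced.sum()), replaced)


def smooth_index(series: IndexSeries, window_s: float = 60.0) -> IndexSeries:
    """Zero-phase moving average; edges use shrinking windows.

    Implemented as a 'same'-mode convolution with a flat kernel,
    normalized by the number of valid points actually under the kernel,
    so the series keeps its length and a constant series is unchanged.
    Flagged points carry zero weight and stay flagged.
    """
    if window_s < series.step_s:
        raise ParameterError("window_s must be at least one grid step")
    n = max(1, int(round(window_s / series.step_s)))
    n = min(n, len(series))  # a kernel longer than the series collapses to it
    kernel = np.ones(n)
    w = series.valid.astype(float)
    v = np.where(series.valid, series.values, 0.0)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(w, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return IndexSeries(
        series.t_s, out, series.step_s, series.label, series.flagged.copy()
    )


@dataclass
class EEGIndexResult:
    """Output of the full EEG index chain.

    ``series`` is the smoothed index; ``raw`` is the per-window index
    before outlier replacement and smoothing; ``replaced`` marks windows
    whose value was substituted by the non-outlier mean.
    """

    series: IndexSeries
    raw: IndexSeries
    n_replaced: int
    replaced: np.ndarray


def compute_eeg_index_series(
    rec: EEGRecording,
    theta: BandDefinition = THETA,
    alpha: BandDefinition = ALPHA,
    low_hz: float = 0.5,
    high_hz: float = 30.0,
    win_s: float = 5.0,
    k_sd: float = 3.0,
    smooth_s: float = 60.0,
) -> EEGIndexResult:
    """Full chain from raw recording to smoothed 5-s workload index."""
    rec.require_channels(THETA_CHANNELS + ALPHA_CHANNELS)
    filtered = bandpass_filter(rec, low_hz, high_hz)
    starts, windows = segment_windows(filtered, win_s)
    if len(starts) == 0:
        raise ParameterError("recording shorter than one analysis window")
    ch_idx = {c: filtered.channels.index(c) for c in THETA_CHANNELS + ALPHA_CHANNELS}
    theta_p = {
        c: band_power(windows[:, ch_idx[c], :], rec.fs, theta) for c in THETA_CHANNELS
    }
    alpha_p = {
        c: band_power(windows[:, ch_idx[c], :], rec.fs, alpha) for c in ALPHA_CHANNELS
    }
    num = 0.5 * (theta_p["F4"] + theta_p["C4"])
    den = 0.5 * (alpha_p["O1"] + alpha_p["O2"])
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / den, np.nan)
    raw = IndexSeries(starts, vals, win_s, "eeg_index")
    rejected = reject_outliers(raw, k_sd=k_sd)
    smoothed = smooth_index(rejected.series, smooth_s)
    return EEGIndexResult(smoothed, raw, rejected.n_replaced, rejected.replaced)
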