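"""Classical neural F0-encoding metrics on averaged responses.

F0 contours are extracted with the short-time autocorrelation method
(40-ms windows, 30-ms overlap by default): within each window, F0 is the
reciprocal of the lag of the highest normalized autocorrelation peak
inside the F0 search range, refined by parabolic interpolation.  From the
contours follow the three reported quantities: stimulus-response F0
correlation (Pearson's r between contours), F0-strength (mean normalized
autocorrelation peak across windows), and the RMS signal-to-noise ratio of
the averaged response relative to its pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import TrialEpochSet

__all__ = [
    "F0Contour",
    "extract_f0",
    "f0_tracking_r",
    "f0_strength",
    "snr",
    "f0_report",
]


@dataclass
class F0Contour:
    """Windowed F0 estimates with their autocorrelation peak heights."""

    times_ms: np.ndarray
    f0_hz: np.ndarray
    peak_autocorr: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        self.peak_autocorr = np.asarray(self.peak_autocorr, dtype=float)
        if not (self.times_ms.size == self.f0_hz.size == self.peak_autocorr.size):
            raise ValueError("contour fields must have equal lengths")

    def __len__(self) -> int:
        return int(self.f0_hz.size)


def _parabolic(y_m1: float, y_0: float, y_p1: float) -> tuple[float, float]:
    """Vertex offset (in samples, within [-0.5, 0.5]) and height."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom == 0:
        return 0.0, y_0
    d = 0.5 * (y_m1 - y_p1) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return d, y_0 - 0.25 * (y_m1 - y_p1) * d


def extract_f0(
    signal: np.ndarray,
    fs: float,
    window_ms: float = 40.0,
    overlap_ms: float = 30.0,
    f0_range_hz: tuple[float, float] = (80.0, 120.0),
) -> F0Contour:
    """Sliding-window autocorrelation F0 track of a 1-D signal."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("extract_f0 expects a 1-D signal")
    win = int(round(window_ms * fs / 1000.0))
    hop = int(round((window_ms - overlap_ms) * fs / 1000.0))
    if hop < 1:
        raise ValueError("overlap_ms must be smaller than window_ms")
    if win > x.size:
        raise ValueError(
            f"{window_ms}-ms window longer than the {1000 * x.size / fs:.1f}-ms signal"
        )
    lo_hz, hi_hz = f0_range_hz
    if not (0 < lo_hz < hi_hz):
        raise ValueError("f0_range_hz must satisfy 0 < low < high")
    lag_min = int(np.floor(fs / hi_hz))
    lag_max = int(np.ceil(fs / lo_hz))
    if lag_max >= win:
        raise ValueError(
            f"F0 search floor {lo_hz} Hz needs lags up to {lag_max} samples, "
            f"exceeding the {win}-sample window"
        )
    n_win = (x.size - win) // hop + 1
    lags = np.arange(max(1, lag_min - 1), lag_max + 2)
    times, f0s, peaks = [], [], []
    for w in range(n_win):
        seg = x[w * hop : w * hop + win]
        seg = seg - seg.mean()
        if not np.any(seg):
            times.append(1000.0 * w * hop / fs)
            f0s.append(np.nan)
            peaks.append(0.0)
            continue
        # normalized cross-correlation of the window with its lagged self,
        # so a perfectly periodic window peaks at 1 regardless of lag
        ac = np.empty(lags.size)
        for li, lag in enumerate(lags):
            a, b = seg[:-lag], seg[lag:]
            denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
            ac[li] = np.dot(a, b) / denom if denom > 0 else 0.0
        inner = slice(1, ac.size - 1)
        k = int(np.argmax(ac[inner])) + 1
        d, height = _parabolic(ac[k - 1], ac[k], ac[k + 1])
        times.append(1000.0 * w * hop / fs)
        f0s.append(fs / (lags[k] + d))
        peaks.append(float(np.clip(height, 0.0, 1.0)))
    return F0Contour(
        times_ms=np.array(times), f0_hz=np.array(f0s), peak_autocorr=np.array(peaks)
    )


def f0_tracking_r(
    stim_contour: F0Contour,
    resp_contour: F0Contour,
    latency_windows: int = 0,
) -> float:
    """Pearson correlation between stimulus and response F0 contours.

    ``latency_windows`` shifts the response contour backwards by that many
    windows before comparison (coarse latency compensation; default none).
    """
    a = stim_contour.f0_hz
    b = resp_contour.f0_hz
    if latency_windows > 0:
        b = b[latency_windows:]
    n = min(a.size, b.size)
    if latency_windows == 0 and a.size != b.size:
        raise ValueError(
            f"contour lengths differ ({a.size} vs {b.size}); align window grids"
        )
    a, b = a[:n], b[:n]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("need at least two aligned finite F0 estimates")
    tol = 1e-9
    if np.std(a[ok]) <= tol * max(1.0, np.abs(a[ok]).max()) or np.std(
        b[ok]
    ) <= tol * max(1.0, np.abs(b[ok]).max()):
        raise ValueError("F0 contour has zero variance; correlation undefined")
    return float(stats.pearsonr(a[ok], b[ok]).statistic)


def f0_strength(contour: F0Contour) -> float:
    """Mean normalized autocorrelation peak across sliding windows."""
    if len(contour) == 0:
        raise ValueError("empty contour")
    return float(np.mean(contour.peak_autocorr))


def snr(
    avg_epoch: np.ndarray,
    fs: float,
    onset_index: int,
    prestim_ms: float = 50.0,
    response_ms: float = 250.0,
) -> float:
    """RMS(response window) / RMS(pre-stimulus baseline) of one average."""
    x = np.asarray(avg_epoch, dtype=np.float64)
    n_pre = int(round(prestim_ms * fs / 1000.0))
    n_resp = int(round(response_ms * fs / 1000.0))
    if onset_index < n_pre:
        raise ValueError(
            f"epoch provides {onset_index} pre-onset samples; {n_pre} required"
        )
    if onset_index + n_resp > x.size:
        raise ValueError("epoch shorter than the requested response window")
    pre = x[onset_index - n_pre : onset_index]
    resp = x[onset_index : onset_index + n_resp]
    pre_rms = float(np.sqrt(np.mean(pre**2)))
    if pre_rms == 0:
        raise ValueError("pre-stimulus RMS is zero; SNR undefined")
    return float(np.sqrt(np.mean(resp**2)) / pre_rms)


def f0_report(
    epochs: TrialEpochSet,
    stimulus_samples: np.ndarray,
    *,
    max_trials: int = 1500,
    window_ms: float = 40.0,
    overlap_ms: float = 30.0,
    f0_range_hz: tuple[float, float] = (80.0, 120.0),
    latency_windows: int = 0,
) -> dict:
    """Per subject/session F0-encoding summary on an averaged response.

    Averages up to ``max_trials`` artifact-free trials (in recorded order),
    then computes stimulus-response F0 correlation, F0-strength, and RMS
    SNR.
    """
    n = min(epochs.n_trials, max_trials)
    avg = np.asarray(epochs.epochs[:n], dtype=np.float64).mean(axis=0)
    fs = epochs.sample_rate_hz
    resp = avg[epochs.t0_index :]
    stim_contour = extract_f0(
        np.asarray(stimulus_samples, dtype=float), fs, window_ms, overlap_ms, f0_range_hz
    )
    resp_contour = extract_f0(resp, fs, window_ms, overlap_ms, f0_range_hz)
    return {
        "infant_id": epochs.infant_id,
        "session": epochs.session,
        "n_trials_averaged": int(n),
        "stimulus_response_r": f0_tracking_r(
            stim_contour, resp_contour, latency_windows=latency_windows
        ),
        "f0_strength": f0_strength(resp_contour),
        "snr": snr(
            avg,
            fs,
            epochs.t0_index,
            prestim_ms=min(epochs.prestim_ms, 50.0),
            response_ms=1000.0 * resp.size / fs,
        ),
    }
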