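"""From raw epochs to HMM-ready spectral slice sequences.

Stages, in pipeline order: baseline-referenced artifact rejection,
polarity-balanced moving-window sub-averaging, Hann-windowed short-time FFT
slicing with dB conversion, and frequency-band channel extraction.
A zero-phase band-pass utility is provided for visualization and for
preconditioning the classical F0 metrics; it is never part of the HMM path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .containers import SliceSequence, TrialEpochSet

__all__ = [
    "SubAverageConfig",
    "SliceConfig",
    "reject_artifacts",
    "subaverage",
    "slice_spectra",
    "extract_band",
    "bandpass_filter",
    "default_band_grid",
]

logger = logging.getLogger(__name__)

#: Default spectral band retained for the recognition features, Hz.
DEFAULT_BAND_HZ = (80.0, 980.0)


@dataclass(frozen=True)
class SubAverageConfig:
    """Moving-window sub-averaging parameters.

    ``window_step_trials`` defaults to 2 so each window shift swaps in one
    full polarity pair, keeping even-sized windows exactly balanced.
    """

    averaging_size: int = 50
    window_step_trials: int = 2

    def __post_init__(self) -> None:
        if self.averaging_size < 1:
            raise ValueError("averaging_size must be >= 1")
        if self.window_step_trials < 1:
            raise ValueError("window_step_trials must be >= 1")


@dataclass(frozen=True)
class SliceConfig:
    """Short-time FFT slicing parameters (20-ms slices, 15-ms overlap)."""

    slice_ms: float = 20.0
    overlap_ms: float = 15.0
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    pad_to_pow2: bool = True
    db_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.slice_ms <= 0:
            raise ValueError("slice_ms must be positive")
        if not (0 <= self.overlap_ms < self.slice_ms):
            raise ValueError("overlap_ms must satisfy 0 <= overlap < slice_ms")
        low, high = self.band_hz
        if not (0 <= low < high):
            raise ValueError("band_hz must satisfy 0 <= low < high")

    @property
    def hop_ms(self) -> float:
        return self.slice_ms - self.overlap_ms


def reject_artifacts(
    epochs: TrialEpochSet,
    threshold_uv: float = 40.0,
    baseline_ms: float = 50.0,
    use_global_baseline: bool = False,
) -> TrialEpochSet:
    """Drop trials with post-onset excursions beyond the amplitude criterion.

    A trial is retained when every post-onset sample lies strictly within
    ``threshold_uv`` microvolts of the mean amplitude of its own
    ``baseline_ms`` pre-stimulus segment (or of the grand baseline mean when
    ``use_global_baseline``).  Trial order and polarity labels are
    preserved; the number of rejected trials is recorded in ``meta``.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    if epochs.prestim_ms < baseline_ms:
        raise ValueError(
            f"epochs carry only {epochs.prestim_ms} ms of baseline; "
            f"{baseline_ms} ms required"
        )
    base = epochs.baseline(baseline_ms).mean(axis=1)
    if use_global_baseline:
        base = np.full_like(base, base.mean())
    dev = np.abs(epochs.post_onset() - base[:, None]).max(axis=1)
    keep = np.flatnonzero(dev < threshold_uv)
    if keep.size == 0:
        raise ValueError("artifact rejection removed every trial")
    n_rej = epochs.n_trials - keep.size
    logger.info(
        "artifact rejection %s/%s: rejected %d of %d trials",
        epochs.infant_id,
        epochs.session,
        n_rej,
        epochs.n_trials,
    )
    return epochs.subset(
        keep, n_rejected=n_rej, rejection_threshold_uv=float(threshold_uv)
    )


def _balanced_order(polarity: np.ndarray) -> np.ndarray:
    """Trial ordering that alternates polarity (+, -, +, -, ...).

    Trials of each polarity keep their relative order; any unpaired surplus
    of one polarity is dropped so every even-sized window is exactly
    balanced.
    """
    pos = np.flatnonzero(polarity > 0)
    neg = np.flatnonzero(polarity < 0)
    n = min(pos.size, neg.size)
    order = np.empty(2 * n, dtype=np.int64)
    order[0::2] = pos[:n]
    order[1::2] = neg[:n]
    return order


def subaverage(epochs: TrialEpochSet, cfg: SubAverageConfig) -> TrialEpochSet:
    """Moving-window sub-averages trading trial count for SNR.

    With ``averaging_size == 1`` the input trials are returned unchanged.
    Larger windows average over a polarity-interleaved trial ordering, so
    even sizes combine equal counts of each polarity and odd sizes differ
    by at most one trial — both polarities always contribute, which is what
    attenuates the polarity-following (cochlear-microphonic-like) component.
    """
    size, step = cfg.averaging_size, cfg.window_step_trials
    if size == 1:
        return epochs.subset(np.arange(epochs.n_trials))
    n_pos = int(np.sum(epochs.polarity > 0))
    n_neg = int(np.sum(epochs.polarity < 0))
    if min(n_pos, n_neg) == 0:
        raise ValueError(
            "sub-averaging windows must mix both stimulus polarities, but all "
            "retained trials share one polarity; supply alternating-polarity "
            "trials or use averaging_size=1"
        )
    order = _balanced_order(epochs.polarity)
    if order.size < size:
        raise ValueError(
            f"averaging_size={size} needs at least {size} polarity-balanced "
            f"trials, only {order.size} available"
        )
    x = epochs.epochs[order]
    starts = np.arange(0, order.size - size + 1, step)
    csum = np.cumsum(np.asarray(x, dtype=np.float64), axis=0)
    csum = np.vstack([np.zeros((1, x.shape[1])), csum])
    avg = (csum[starts + size] - csum[starts]) / size
    return TrialEpochSet(
        epochs=avg,
        sample_rate_hz=epochs.sample_rate_hz,
        t0_index=epochs.t0_index,
        prestim_ms=epochs.prestim_ms,
        polarity=np.zeros(starts.size, dtype=np.int8),
        infant_id=epochs.infant_id,
        session=epochs.session,
        meta={
            **epochs.meta,
            "averaging_size": size,
            "window_step_trials": step,
            "window_source_trials": [
                order[s : s + size].tolist() for s in starts
            ],
        },
    )


def _slice_geometry(n_samples: int, fs: float, cfg: SliceConfig):
    win = int(round(cfg.slice_ms * fs / 1000.0))
    hop = int(round(cfg.hop_ms * fs / 1000.0))
    if win > n_samples:
        raise ValueError(
            f"slice of {cfg.slice_ms} ms ({win} samples) longer than the "
            f"{n_samples}-sample response window"
        )
    n_slices = (n_samples - win) // hop + 1
    nfft = win
    if cfg.pad_to_pow2:
        nfft = int(2 ** np.ceil(np.log2(win)))
    return win, hop, n_slices, nfft


def _band_mask(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    mask = (freqs >= low) & (freqs < high)
    if not np.any(mask):
        raise ValueError(
            f"band [{low}, {high}) Hz selects no bins from axis "
            f"[{freqs.min():.1f}, {freqs.max():.1f}] Hz"
        )
    return mask


def stft_slices(
    responses: np.ndarray, fs: float, cfg: SliceConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched slicing: (n_resp, n_samples) -> (n_resp, n_slices, n_bins) dB.

    Hann-tapered slices are zero-padded to the next power of two for a
    stable bin grid; magnitudes become 20*log10(|X| + db_floor) and only
    bins inside ``cfg.band_hz`` are retained.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=np.float64))
    n_samples = responses.shape[1]
    win, hop, n_slices, nfft = _slice_geometry(n_samples, fs, cfg)
    idx = np.arange(win)[None, :] + hop * np.arange(n_slices)[:, None]
    frames = responses[:, idx] * sps.windows.hann(win, sym=False)
    spec = np.abs(np.fft.rfft(frames, n=nfft, axis=-1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mask = _band_mask(freqs, *cfg.band_hz)
    db = 20.0 * np.log10(spec[..., mask] + cfg.db_floor)
    times_ms = 1000.0 * hop * np.arange(n_slices) / fs
    return db, times_ms, freqs[mask]


def slice_spectra(
    avg_epoch: np.ndarray, fs: float, cfg: SliceConfig | None = None, **labels
) -> SliceSequence:
    """Slice a single averaged response into a dB spectral slice sequence."""
    if cfg is None:
        cfg = SliceConfig()
    x = np.asarray(avg_epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("slice_spectra expects a single 1-D response vector")
    db, times_ms, freqs = stft_slices(x[None, :], fs, cfg)
    return SliceSequence(
        slices=db[0], times_ms=times_ms, bin_freqs_hz=freqs, labels=labels
    )


def extract_band(seq: SliceSequence, low_hz: float, high_hz: float) -> SliceSequence:
    """Restrict a slice sequence to bins with low <= f < high."""
    mask = _band_mask(seq.bin_freqs_hz, low_hz, high_hz)
    return SliceSequence(
        slices=seq.slices[:, mask],
        times_ms=seq.times_ms,
        bin_freqs_hz=seq.bin_freqs_hz[mask],
        labels={**seq.labels, "band_hz": (float(low_hz), float(high_hz))},
    )


def default_band_grid(
    low_hz: float = 80.0, high_hz: float = 980.0, step_hz: float = 100.0
) -> list[tuple[float, float]]:
    """The standard 100-Hz frequency channels from 80 to 980 Hz."""
    edges = np.arange(low_hz, high_hz + step_hz / 2, step_hz)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def bandpass_filter(
    epochs: TrialEpochSet, low_hz: float, high_hz: float, order: int = 4
) -> TrialEpochSet:
    """Zero-phase Butterworth band-pass of every trial (plots / F0 metrics)."""
    nyq = epochs.sample_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=epochs.sample_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, np.asarray(epochs.epochs, dtype=np.float64), axis=1)
    return replace(
        epochs,
        epochs=filtered,
        meta={**epochs.meta, "bandpass_hz": (float(low_hz), float(high_hz))},
    )
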