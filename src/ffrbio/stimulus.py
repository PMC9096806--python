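"""Source-filter synthesis of the evoking vowel stimulus.

The stimulus is a synthesized high-front vowel with a low-dipping
fundamental-frequency (F0) contour.  The instantaneous F0 follows a smooth
half-cosine trajectory through three anchors (onset, dip, offset; default
105-89-110 Hz) and drives a sawtooth glottal source, which is shaped by
second-order resonators at the formant frequencies (default 330 and
2500 Hz).  The per-sample F0 trajectory is returned alongside the waveform
as ground truth for pitch-tracking code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["StimulusSpec", "StimulusWaveform", "synthesize_stimulus", "F0_PRESETS"]

#: Published F0 anchor triplets (onset, dip, offset) in Hz.  The default
#: preset is used throughout; the alternate parameterization is kept as an
#: explicitly selectable variant.
F0_PRESETS: dict[str, tuple[float, float, float]] = {
    "default": (105.0, 89.0, 110.0),
    "alternate": (101.0, 87.0, 107.0),
}


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the synthesized vowel.

    ``level_db_spl`` is presentation-level metadata only; the waveform is
    returned in arbitrary units normalized to unit peak amplitude.
    """

    duration_ms: float = 250.0
    sample_rate_hz: float = 20000.0
    f0_anchors_hz: tuple[float, float, float] = F0_PRESETS["default"]
    formant_freqs_hz: tuple[float, ...] = (330.0, 2500.0)
    formant_bandwidths_hz: tuple[float, ...] = (80.0, 150.0)
    level_db_spl: float = 75.0
    ramp_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        nyq = self.sample_rate_hz / 2.0
        onset, dip, offset = self.f0_anchors_hz
        for f in (*self.f0_anchors_hz, *self.formant_freqs_hz):
            if f <= 0 or f >= nyq:
                raise ValueError(f"frequency {f} Hz outside (0, Nyquist={nyq})")
        if not (dip <= onset and dip <= offset):
            raise ValueError("F0 dip anchor must not exceed the onset and offset anchors")
        if len(self.formant_bandwidths_hz) != len(self.formant_freqs_hz):
            raise ValueError("one bandwidth per formant required")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate_hz / 1000.0))


@dataclass
class StimulusWaveform:
    """Synthesized stimulus with its ground-truth F0 trajectory."""

    samples: np.ndarray
    sample_rate_hz: float
    f0_trajectory_hz: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.f0_trajectory_hz = np.asarray(self.f0_trajectory_hz, dtype=float)
        if self.samples.shape != self.f0_trajectory_hz.shape:
            raise ValueError("f0 trajectory must have one value per sample")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate_hz


def _half_cosine(a: float, b: float, n: int) -> np.ndarray:
    """Smooth monotone ramp from ``a`` to ``b`` over ``n`` samples."""
    u = np.linspace(0.0, 1.0, n)
    return a + (b - a) * (1.0 - np.cos(np.pi * u)) / 2.0


def f0_trajectory(spec: StimulusSpec) -> np.ndarray:
    """Per-sample F0 through (onset, dip, offset); the dip sits at midpoint."""
    n = spec.n_samples
    onset, dip, offset = spec.f0_anchors_hz
    mid = n // 2
    down = _half_cosine(onset, dip, mid + 1)
    up = _half_cosine(dip, offset, n - mid)
    return np.concatenate([down[:-1], up])


def harmonic_source(f0_hz: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Harmonic-rich sawtooth source following an instantaneous F0 track."""
    phase = 2.0 * np.pi * np.cumsum(f0_hz) / sample_rate_hz
    return sps.sawtooth(phase)


def _resonator_coeffs(freq_hz: float, bw_hz: float, fs: float):
    r = np.exp(-np.pi * bw_hz / fs)
    theta = 2.0 * np.pi * freq_hz / fs
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    # unity gain at the resonance frequency
    w, h = sps.freqz([1.0], a, worN=[theta])
    return np.array([1.0 / np.abs(h[0])]), a


def synthesize_stimulus(spec: StimulusSpec | None = None) -> StimulusWaveform:
    """Synthesize the vowel and return it with its F0 ground truth.

    The glottal source is a sawtooth whose phase integrates the half-cosine
    F0 trajectory; formants are imposed by a cascade of two-pole resonators.
    Raised-cosine onset/offset ramps avoid spectral splatter.  The waveform
    is normalized to unit peak amplitude (arbitrary units).
    """
    if spec is None:
        spec = StimulusSpec()
    fs = spec.sample_rate_hz
    f0 = f0_trajectory(spec)
    x = harmonic_source(f0, fs)
    for freq, bw in zip(spec.formant_freqs_hz, spec.formant_bandwidths_hz):
        b, a = _resonator_coeffs(freq, bw, fs)
        x = sps.lfilter(b, a, x)
    n_ramp = int(round(spec.ramp_ms * fs / 1000.0))
    if n_ramp > 0:
        ramp = (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp)) / 2.0
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    x = x / np.max(np.abs(x))
    return StimulusWaveform(samples=x, sample_rate_hz=fs, f0_trajectory_hz=f0)
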