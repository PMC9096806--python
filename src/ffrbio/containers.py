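"""Core in-memory containers shared across the pipeline.

A :class:`TrialEpochSet` holds labeled single-trial epochs in microvolts with
the time convention t = 0 at stimulus onset: the baseline occupies
[-prestim_ms, 0) and the response window starts at ``t0_index``.
:class:`SliceSequence` holds the short-time spectral representation of one
(sub-averaged) response, and :class:`EmissionSequence` the discrete symbols
obtained by vector quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TrialEpochSet", "SliceSequence", "EmissionSequence"]


@dataclass
class TrialEpochSet:
    """Labeled single-trial EEG epochs for one subject in one session.

    Parameters
    ----------
    epochs : ndarray of shape (n_trials, n_samples)
        Epoch matrix in microvolts, covering [-prestim_ms, duration].
    sample_rate_hz : float
        Sampling rate.
    t0_index : int
        Sample index of stimulus onset within each epoch row.
    prestim_ms : float
        Duration of the pre-stimulus baseline segment.
    polarity : ndarray of shape (n_trials,)
        Stimulus polarity per trial, +1 or -1.  Sub-averaged pseudo-trials
        that pool both polarities carry polarity 0.
    infant_id, session : str
        Subject and session labels.
    meta : dict
        Free-form provenance (seeds, rejection log, ...).
    """

    epochs: np.ndarray
    sample_rate_hz: float
    t0_index: int
    prestim_ms: float
    polarity: np.ndarray
    infant_id: str
    session: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs))
        self.polarity = np.asarray(self.polarity)
        if self.epochs.shape[0] != self.polarity.shape[0]:
            raise ValueError(
                f"polarity length {self.polarity.shape[0]} does not match "
                f"n_trials {self.epochs.shape[0]}"
            )
        if self.epochs.shape[0] < 1:
            raise ValueError("TrialEpochSet needs at least one trial")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]

    def post_onset(self) -> np.ndarray:
        """View of the response window (t >= 0)."""
        return self.epochs[:, self.t0_index :]

    def baseline(self, baseline_ms: float | None = None) -> np.ndarray:
        """View of the last ``baseline_ms`` of the pre-stimulus segment."""
        if baseline_ms is None:
            baseline_ms = self.prestim_ms
        n = int(round(baseline_ms * self.sample_rate_hz / 1000.0))
        if n > self.t0_index:
            raise ValueError(
                f"epoch has only {self.t0_index} pre-stimulus samples, "
                f"{n} requested"
            )
        return self.epochs[:, self.t0_index - n : self.t0_index]

    def subset(self, idx, **meta) -> "TrialEpochSet":
        """New set with trials ``idx`` (order preserved as given)."""
        idx = np.asarray(idx)
        return replace(
            self,
            epochs=self.epochs[idx],
            polarity=self.polarity[idx],
            meta={**self.meta, **meta},
        )


@dataclass
class SliceSequence:
    """Ordered short-time FFT magnitude slices (dB) for one response.

    ``slices`` has shape (n_slices, n_bins); ``bin_freqs_hz`` gives the
    retained frequency axis and ``times_ms`` the slice onset times relative
    to stimulus onset.
    """

    slices: np.ndarray
    times_ms: np.ndarray
    bin_freqs_hz: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.atleast_2d(np.asarray(self.slices, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.bin_freqs_hz = np.asarray(self.bin_freqs_hz, dtype=float)
        if self.slices.shape[0] != self.times_ms.shape[0]:
            raise ValueError("times_ms length does not match slice count")
        if self.slices.shape[1] != self.bin_freqs_hz.shape[0]:
            raise ValueError("bin_freqs_hz length does not match slice width")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def n_bins(self) -> int:
        return self.slices.shape[1]


@dataclass
class EmissionSequence:
    """Discrete emission symbols for one quantized slice sequence."""

    symbols: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1:
            raise ValueError("symbols must be one-dimensional")
        if self.symbols.size == 0:
            raise ValueError("emission sequence is empty")
        if np.any(self.symbols < 0):
            raise ValueError("emission symbols must be nonnegative")

    def __len__(self) -> int:
        return int(self.symbols.size)
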