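"""Persistence: cohort containers (HDF5), WAV stimulus, CSV/JSON artifacts.

The cohort container is a single HDF5 file with one ``<infant>/<session>``
group per epoch set (datasets ``epochs`` and ``polarity``; scalar metadata
as attributes).  A plain ``.npy`` + JSON fallback layout is available for
environments without HDF5 tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .containers import TrialEpochSet
from .stimulus import StimulusWaveform

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_cohort_npy",
    "load_cohort_npy",
    "export_stimulus_wav",
    "export_f0_csv",
]


def save_cohort(path: str | Path, cohort: list[TrialEpochSet]) -> Path:
    """Write epoch sets to one HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for ts in cohort:
            g = f.create_group(f"{ts.infant_id}/{ts.session}")
            g.create_dataset("epochs", data=ts.epochs, compression="gzip", compression_opts=4)
            g.create_dataset("polarity", data=ts.polarity.astype(np.int8))
            g.attrs["sample_rate_hz"] = float(ts.sample_rate_hz)
            g.attrs["t0_index"] = int(ts.t0_index)
            g.attrs["prestim_ms"] = float(ts.prestim_ms)
            g.attrs["meta_json"] = json.dumps(ts.meta, default=str)
    return path


def load_cohort(path: str | Path) -> list[TrialEpochSet]:
    """Read every epoch set from an HDF5 container (subject-major order)."""
    cohort = []
    with h5py.File(path, "r") as f:
        for infant_id in f:
            for session in f[infant_id]:
                g = f[infant_id][session]
                cohort.append(
                    TrialEpochSet(
                        epochs=g["epochs"][...],
                        sample_rate_hz=float(g.attrs["sample_rate_hz"]),
                        t0_index=int(g.attrs["t0_index"]),
                        prestim_ms=float(g.attrs["prestim_ms"]),
                        polarity=g["polarity"][...],
                        infant_id=infant_id,
                        session=session,
                        meta=json.loads(g.attrs.get("meta_json", "{}")),
                    )
                )
    return cohort


def save_cohort_npy(directory: str | Path, cohort: list[TrialEpochSet]) -> Path:
    """Fallback layout: <dir>/<infant>_<session>.npy + sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ts in cohort:
        stem = f"{ts.infant_id}_{ts.session}"
        np.save(directory / f"{stem}.npy", ts.epochs)
        meta = {
            "sample_rate_hz": float(ts.sample_rate_hz),
            "t0_index": int(ts.t0_index),
            "prestim_ms": float(ts.prestim_ms),
            "polarity": ts.polarity.astype(int).tolist(),
            "infant_id": ts.infant_id,
            "session": ts.session,
            "meta": ts.meta,
        }
        (directory / f"{stem}.json").write_text(json.dumps(meta, default=str))
    return directory


def load_cohort_npy(directory: str | Path) -> list[TrialEpochSet]:
    directory = Path(directory)
    cohort = []
    for meta_path in sorted(directory.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        epochs = np.load(meta_path.with_suffix(".npy"))
        cohort.append(
            TrialEpochSet(
                epochs=epochs,
                sample_rate_hz=meta["sample_rate_hz"],
                t0_index=meta["t0_index"],
                prestim_ms=meta["prestim_ms"],
                polarity=np.asarray(meta["polarity"], dtype=np.int8),
                infant_id=meta["infant_id"],
                session=meta["session"],
                meta=meta.get("meta", {}),
            )
        )
    return cohort


def export_stimulus_wav(path: str | Path, stimulus: StimulusWaveform) -> Path:
    """Write the stimulus as a mono float32 WAV at its native rate."""
    path = Path(path)
    x = np.asarray(stimulus.samples, dtype=np.float32)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    wavfile.write(path, int(round(stimulus.sample_rate_hz)), x)
    return path


def export_f0_csv(path: str | Path, stimulus: StimulusWaveform) -> Path:
    """Ground-truth per-sample F0 trajectory as (time_ms, f0_hz) CSV."""
    path = Path(path)
    t_ms = 1000.0 * np.arange(stimulus.n_samples) / stimulus.sample_rate_hz
    pd.DataFrame({"time_ms": t_ms, "f0_hz": stimulus.f0_trajectory_hz}).to_csv(
        path, index=False
    )
    return path
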