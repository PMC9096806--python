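import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ffrbio
from ffrbio.cohort import CohortDesign, ResponseModel, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stimulus():
    return ffrbio.synthesize_stimulus()


@pytest.fixture(scope="session")
def strong_cohort():
    """Small one-session cohort with strong signatures and mild noise.

    Used wherever recognition is expected to clearly succeed.
    """
    design = CohortDesign(
        n_trials=160,
        noise_sd_uv=2.0,
        base_signature_strength_uv=0.8,
        maturation_factor=1.0,
        response_model=ResponseModel(artifact_rate=0.0),
    )
    return generate_cohort(
        n_infants=3, sessions=("s1",), design=design, master_seed=42
    )


def make_epochs(
    epochs,
    fs=20000.0,
    prestim_ms=50.0,
    polarity=None,
    infant_id="infantXX",
    session="7mo",
):
    """Hand-built TrialEpochSet around a raw (n_trials, n_samples) array."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_pre = int(round(prestim_ms * fs / 1000.0))
    if polarity is None:
        polarity = np.where(np.arange(epochs.shape[0]) % 2 == 0, 1, -1)
    return ffrbio.TrialEpochSet(
        epochs=epochs,
        sample_rate_hz=fs,
        t0_index=n_pre,
        prestim_ms=prestim_ms,
        polarity=np.asarray(polarity, dtype=np.int8),
        infant_id=infant_id,
        session=session,
    )
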