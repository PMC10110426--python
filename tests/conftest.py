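import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ckcnet as ck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_recording():
    """Standard synthetic recording: C3/C4 response, jitter SD 1 rad."""
    return ck.generate_scalp_recording(ck.SynthScalpConfig(duration=125.0, seed=1))


def _first_n_epochs(epochs, n):
    epochs.data = epochs.data[:n]
    epochs.kept_trigger_indices = epochs.kept_trigger_indices[:n]
    return epochs


@pytest.fixture(scope="session")
def csd_epochs(default_recording):
    """First 100 CSD-transformed epochs of the standard recording."""
    rec = ck.filter_and_resample(default_recording)
    return _first_n_epochs(ck.csd(ck.epoch(rec)), 100)


@pytest.fixture(scope="session")
def uncoupled_pair_phases():
    """Narrowband phases of one uncoupled 2-parcel recording (60 s)."""
    parcels = ck.generate_parcel_signals(
        ck.SynthParcelConfig(n_parcels=2, duration=60.0, seed=5)
    )
    from ckcnet.connectivity import narrowband_phase

    return narrowband_phase(parcels)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
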