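import numpy as np
import pytest

from patchkin.gating_sim import (
    AcquisitionConfig,
    two_state_scheme,
    wt_like_scheme,
)


@pytest.fixture
def two_state():
    return two_state_scheme(k_co=100.0, k_oc=100.0)


@pytest.fixture
def wt_scheme():
    return wt_like_scheme()


@pytest.fixture
def fast_config():
    """Short, coarse acquisition for quick simulation tests."""
    return AcquisitionConfig(
        sampling_rate=10_000.0,
        filter_cutoff=2_000.0,
        sweep_duration=1.0,
        protocol_voltages=(80.0, 100.0, 120.0, 140.0),
        noise_sd=0.5,
        n_channels=1,
        seed=7,
    )


def batch_se(values: np.ndarray) -> float:
    """Standard error of a mean from batch means."""
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))
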