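import numpy as np
import pytest

from wplinet.io_preproc import BANDS, MultichannelRecording
from wplinet.synthetic_data import BandEffect, CohortConfig, CouplingSpec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_recording(rng):
    """Short broadband random recording: 6 channels, 250 Hz, 10 s."""
    return MultichannelRecording(
        data=rng.standard_normal((6, 2500)),
        fs=250.0,
        channel_names=[f"CH{i}" for i in range(6)],
    )


@pytest.fixture
def alpha_coupled_pair():
    """A single strongly coupled channel pair (alpha band, quarter-cycle lag)."""
    return CouplingSpec(pair=(0, 1), band=BANDS["alpha"], lag=np.pi / 2, strength=1.0)


@pytest.fixture
def tiny_cohort_config():
    """Very small cohort for fast pipeline tests: 8 channels, 125 Hz, 24 s."""
    return CohortConfig(
        n_group_a=3,
        n_group_b=3,
        n_channels=8,
        fs=125.0,
        duration=24.0,
        seed=7,
    )


@pytest.fixture
def null_band_effects():
    """Coupling present but identical in both groups (no group effect)."""
    return [BandEffect("alpha", 0.4, 0.4, pairs=((0, 1), (2, 3)))]
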