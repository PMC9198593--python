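import numpy as np
import pytest

from speechtrf import (
    CohortConfig,
    KernelParams,
    StimulusConfig,
    generate_cohort,
)

SMALL_CHANNELS = ("C3", "CP3", "CPz", "Pz")


@pytest.fixture(scope="session")
def short_stim() -> StimulusConfig:
    """One minute of stimulus: enough sentences for a stable TRF."""
    return StimulusConfig(duration_s=60.0)


@pytest.fixture(scope="session")
def kernel() -> KernelParams:
    return KernelParams()


@pytest.fixture(scope="session")
def small_cohort_cfg() -> CohortConfig:
    """3 subjects x 6 conditions x 4 channels, moderate noise."""
    return CohortConfig(
        n_subjects=3, n_channels=len(SMALL_CHANNELS),
        channel_names=SMALL_CHANNELS, noise_sd=6.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_cfg, kernel):
    stim = StimulusConfig(duration_s=45.0)
    return generate_cohort(small_cohort_cfg, stim, kernel)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
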