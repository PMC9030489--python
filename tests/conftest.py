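import numpy as np
import pytest

import swaylab as sl


@pytest.fixture(scope="session")
def tiny_config() -> sl.StudyConfig:
    """Minimal-footprint study for structural and I/O tests."""
    return sl.StudyConfig(
        n_subjects=2,
        n_repetitions=1,
        trial_duration=2.0,
        acc_rate=60.0,
        cop_rate=40.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config) -> sl.StudyDataset:
    return sl.simulate_study(tiny_config)


@pytest.fixture(scope="session")
def default_study() -> sl.StudyDataset:
    """Default-condition study at full trial length/rate, 15 subjects.

    Shared by the detection-pattern and classification suites.
    """
    return sl.simulate_study(sl.StudyConfig(n_subjects=15, seed=7))


@pytest.fixture(scope="session")
def default_measures(default_study):
    """Wide 43-measure table over all 8 sensors for the default study."""
    return sl.compute_study_measures(default_study)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
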