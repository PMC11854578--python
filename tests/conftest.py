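import numpy as np
import pandas as pd
import pytest

from eegsel.features import FeatureTable
from eegsel.montage import standard_montage
from eegsel.preprocess import PreprocessConfig, run_preprocess
from eegsel.synth import (
    CohortConfig,
    control_profile,
    default_profiles,
    generate_cohort,
    generate_recording,
)


@pytest.fixture(scope="session")
def montage32():
    return standard_montage()


@pytest.fixture(scope="session")
def control_recording(montage32):
    """10 s control recording at 512 Hz (fast to generate and filter)."""
    return generate_recording(
        control_profile(), duration_s=10, fs=512, montage=montage32, seed=7
    )


@pytest.fixture(scope="session")
def preprocessed_recording(control_recording):
    return run_preprocess(control_recording, PreprocessConfig())


@pytest.fixture(scope="session")
def tiny_cohort(montage32):
    """Small three-group cohort with default planted effects."""
    cfg = CohortConfig(
        group_sizes={"CONTROL": 4, "PSF": 4, "CTF": 4},
        duration_s=8,
        fs=256,
        seed=11,
        profiles=default_profiles(),
    )
    return generate_cohort(cfg, montage=montage32)


def make_random_table(
    n_subjects=24, n_features=10, n_informative=1, seed=0, labels=("A", "B")
) -> FeatureTable:
    """Random normalised table with the first ``n_informative`` features
    separating the two classes."""
    rng = np.random.default_rng(seed)
    y = np.array([labels[i % 2] for i in range(n_subjects)])
    X = rng.standard_normal((n_subjects, n_features))
    for j in range(n_informative):
        X[:, j] += np.where(y == labels[1], 2.5, -2.5)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    cols = [f"feat{j:02d}" for j in range(n_features)]
    idx = [f"sub-{i:03d}" for i in range(n_subjects)]
    return FeatureTable(
        data=pd.DataFrame(X, columns=cols, index=idx),
        labels=pd.Series(y, index=idx, name="group"),
    )


@pytest.fixture
def random_table():
    return make_random_table()
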