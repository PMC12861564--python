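import numpy as np
import pandas as pd
import pytest

from gliotype.io import FeatureTable, RunConfig
from gliotype.simulate import SimCohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """n=120, k=2, strong signal — shared by clustering tests."""
    spec = SimCohortSpec(n_samples=120, k_true=2, delta=3.0,
                         n_informative=20, n_noise=40, seed=314)
    t1, t2, clinical, labels = simulate_cohort(spec)
    return t1, t2, clinical, labels


@pytest.fixture(scope="session")
def small_config():
    """Kernel grids small enough for n~100 cohorts."""
    return RunConfig(seed=314, sigma_grid=(1.0, 1.5, 2.0),
                     knn_grid=(10, 15, 20))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_table(values, modality="T1CE", prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureTable(
        pd.DataFrame(values, index=[f"S{i:03d}" for i in range(n)],
                     columns=[f"{prefix}{j}" for j in range(p)]),
        modality,
    )
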