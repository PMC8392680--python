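import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sdm_entropy import OccurrenceDataset, reference_species

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_dataset(presence, predictors: dict, **kwargs) -> OccurrenceDataset:
    presence = np.asarray(presence)
    return OccurrenceDataset(
        cell_id=np.array([f"c{i}" for i in range(len(presence))]),
        presence=presence,
        predictors=pd.DataFrame(predictors),
        **kwargs,
    )


def random_dataset(rng: np.random.Generator, n: int = 400, k: int = 3) -> OccurrenceDataset:
    """Random logistic-truth dataset with both classes guaranteed."""
    X = rng.normal(size=(n, k))
    beta = rng.normal(scale=0.8, size=k)
    eta = rng.normal(scale=0.5) + X @ beta
    presence = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    if presence.sum() in (0, n):  # force both classes
        presence[0], presence[1] = 0, 1
    return make_dataset(presence, {f"v{j}": X[:, j] for j in range(k)})


@pytest.fixture(scope="session")
def bench_species() -> OccurrenceDataset:
    """Standard virtual species: 3 informative, 5 noise, 1 duplicate."""
    return reference_species(seed=7, n_cells=2000)
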