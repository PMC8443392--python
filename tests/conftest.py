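"""Shared fixtures: seeded RNGs, small dictionary pairs, and the trained system.

The session-scoped ``trained_dictionaries`` fixture trains the full-size
(256 x 256) FM / non-FM dictionary pair once on 1000 generated windows per
class and shares it across detector, pipeline, and system-level tests.
"""

import numpy as np
import pytest

from fmdetect.dictionary_learning import FeatureDictionary
from fmdetect.pipeline_cli import train_synthetic_dictionaries

#: Seed of the shared trained system (the package default).
TRAIN_SEED = 0


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def mean_free_orthonormal(m: int, n: int, seed: int) -> np.ndarray:
    """Random orthonormal atoms lying in the mean-free subspace of R^m."""
    g = np.random.default_rng(seed)
    A = g.normal(size=(m, n))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q[:, :n]


@pytest.fixture(scope="session")
def small_dictionary_pair():
    """A cheap (32 x 12) FM / non-FM pair of mean-free orthonormal atoms."""
    return (
        FeatureDictionary(mean_free_orthonormal(32, 12, seed=1), "FM"),
        FeatureDictionary(mean_free_orthonormal(32, 12, seed=2), "NON_FM"),
    )


@pytest.fixture(scope="session")
def trained_dictionaries():
    """Full-size dictionary pair trained on 1000 synthetic windows per class."""
    return train_synthetic_dictionaries(seed=TRAIN_SEED, n_per_class=1000, n_iter=30)
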