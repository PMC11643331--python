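import numpy as np
import pytest

from actionrsa.rdm import RDM, split_data_rdm
from actionrsa.synth import make_bundle, make_stimulus_set


@pytest.fixture(scope="session")
def stimulus_set():
    return make_stimulus_set()


@pytest.fixture(scope="session")
def small_stimulus_set():
    return make_stimulus_set(n_categories=4, n_exemplars=3)


@pytest.fixture(scope="session")
def bundle():
    """Moderate-noise synthetic study shared across tests."""
    return make_bundle(n_subjects=8, seed=7)


@pytest.fixture(scope="session")
def subject_rdms(bundle):
    return [
        split_data_rdm(bundle.patterns[(s, 0)], bundle.patterns[(s, 1)])
        for s in range(bundle.ground_truth.n_subjects)
    ]


def random_rdm(rng, m=8, ids=None) -> RDM:
    """A random symmetric zero-diagonal dissimilarity matrix for oracles."""
    mat = rng.random((m, m))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0.0)
    if ids is None:
        ids = [f"s{i}" for i in range(m)]
    return RDM(ids, mat)
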