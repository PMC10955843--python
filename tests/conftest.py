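import numpy as np
import pytest

import qcla


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study shared across tests: filtered cohort at the
    default size, its generator truth, and a semantic space trained on the
    synthetic reference corpus."""
    cohort, truth = qcla.generate_cohort(seed=101)
    kept = qcla.apply_control_filter(cohort)
    tokens = qcla.generate_reference_corpus(truth.config, seed=202)
    space = qcla.build_space(tokens, d=512)
    return kept, truth, space


@pytest.fixture(scope="session")
def kept876(study):
    return study[0]


@pytest.fixture(scope="session")
def truth876(study):
    return study[1]


@pytest.fixture(scope="session")
def space(study):
    return study[2]


@pytest.fixture
def tiny_space():
    """Hand-built orthonormal space over four words (exact geometry)."""
    vocab = ["alpha", "beta", "gamma", "delta"]
    return qcla.SemanticSpace(vocabulary=vocab, vectors=np.eye(4), dimensionality=4)
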