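import numpy as np
import pytest

from nirsnet import CohortSpec, GroundTruthSpec, NuisanceSpec


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort for unit tests: 4 subjects, 4 min at 25 Hz."""
    return CohortSpec(
        n_subjects=4,
        duration=240.0,
        truth=GroundTruthSpec(seed=7),
    )


@pytest.fixture(scope="session")
def default_spec():
    """The default study conditions: 15 subjects, 46 channels, 10 min, 25 Hz."""
    return CohortSpec()


@pytest.fixture(scope="session")
def default_model(default_spec):
    """Preprocessed default cohort (shared across tests; read-only)."""
    from nirsnet import ConnectomeModel

    return ConnectomeModel.from_synthetic(default_spec)


@pytest.fixture(scope="session")
def default_fit(default_model):
    """Fitted results without null ensembles (fast, shared)."""
    return default_model.fit(compute_nulls=False, seed=0)


def random_adjacency(n, p, seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T
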