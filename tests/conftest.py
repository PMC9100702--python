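import numpy as np
import pytest

from rbfgcn import SyntheticCohortConfig, generate_cohort, generate_worked_fixture


@pytest.fixture(scope="session")
def worked_cohort():
    """Tiny deterministic cohort (m=6, n=12) shared across module tests."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale default synthetic cohort (m=148, n=502)."""
    networks, _ = generate_cohort(SyntheticCohortConfig())
    return networks


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, m, density=0.7, scale=10.0):
    """Random symmetric nonnegative weighted adjacency with zero diagonal."""
    A = rng.random((m, m)) * scale
    A *= rng.random((m, m)) < density
    A = np.triu(A, k=1)
    return A + A.T
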