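import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from classnet import BinaryNetwork, Roster, SyntheticConfig, ValueNetwork, generate_classroom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def roster3():
    return Roster(("a", "b", "c"))


@pytest.fixture
def roster4():
    return Roster(("a", "b", "c", "d"))


@pytest.fixture(scope="session")
def default_classroom():
    """One synthetic classroom drawn under the default study conditions."""
    return generate_classroom(SyntheticConfig(seed=1))


def binary_net(roster: Roster, ties, directed: bool = True) -> BinaryNetwork:
    return BinaryNetwork(roster=roster, ties=np.asarray(ties), directed=directed)


def count_net(roster: Roster, counts) -> ValueNetwork:
    return ValueNetwork(roster=roster, values=np.asarray(counts), kind="count")


def rating_net(roster: Roster, ratings) -> ValueNetwork:
    return ValueNetwork(roster=roster, values=np.asarray(ratings), kind="rating")


def random_binary_matrix(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Random directed binary adjacency with zero diagonal, nondegenerate."""
    while True:
        m = (rng.random((n, n)) < p).astype(int)
        np.fill_diagonal(m, 0)
        off = m[~np.eye(n, dtype=bool)]
        if np.ptp(off) > 0:
            return m
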