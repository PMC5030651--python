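import numpy as np
import pytest

from phconnect.connectivity import DistanceMatrix
from phconnect.synthetic_cohort import RegionScheme, SimulationConfig, simulate_cohort


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """A random symmetric distance matrix with distinct labels A, B, C, ..."""
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    labels = tuple(chr(ord("A") + k) for k in range(n))
    return DistanceMatrix(region_labels=labels, d=d, metric_tag="one_minus_r")


def chain_distance_matrix() -> DistanceMatrix:
    """3 regions with d(A,B)=0.1, d(B,C)=0.2, d(A,C)=0.9."""
    d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.2], [0.9, 0.2, 0.0]])
    return DistanceMatrix(region_labels=("A", "B", "C"), d=d, metric_tag="one_minus_r")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def chain_dm() -> DistanceMatrix:
    return chain_distance_matrix()


@pytest.fixture(scope="session")
def default_table():
    """One deterministic default-geometry cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_scheme() -> RegionScheme:
    return RegionScheme(
        labels=("R_CP", "L_CP", "R_MOT", "L_MOT"),
        hemisphere=("R", "L", "R", "L"),
        module_id=("bg", "bg", "ctx", "ctx"),
    )
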