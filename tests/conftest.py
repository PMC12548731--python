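import numpy as np
import pytest

from hapshuffle import (
    DemographyParams,
    HaplotypeMatrix,
    make_classification_dataset,
    make_regression_dataset,
    simulate_neutral,
)


def random_matrix(
    rng: np.random.Generator,
    n_hap: int | None = None,
    width: int | None = None,
    n_seg: int | None = None,
    p: float | None = None,
) -> HaplotypeMatrix:
    """A random valid padded matrix (not genealogically structured)."""
    n_hap = n_hap or int(rng.integers(4, 21))
    width = width or int(rng.integers(10, 41))
    if n_seg is None:
        n_seg = int(rng.integers(2, width + 1))
    p = p if p is not None else float(rng.uniform(0.1, 0.5))
    data = np.zeros((n_hap, width), dtype=np.uint8)
    data[:, :n_seg] = rng.random((n_hap, n_seg)) < p
    positions = np.sort(rng.integers(0, 10**6, size=n_seg))
    return HaplotypeMatrix(data=data, n_seg=n_seg, positions=positions)


@pytest.fixture(scope="session")
def coalescent_matrix() -> HaplotypeMatrix:
    """One LD-rich simulated matrix (shared, treated as read-only)."""
    return simulate_neutral(16, DemographyParams(theta=8.0), 48, seed=3)


@pytest.fixture(scope="session")
def sweep_dataset():
    """The shipped seeded classification fixture (default study conditions)."""
    return make_classification_dataset(30, seed=11)


@pytest.fixture(scope="session")
def regression_dataset():
    """The shipped seeded regression fixture (default study conditions)."""
    return make_regression_dataset(100, seed=5)
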