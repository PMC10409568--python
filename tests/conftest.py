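import numpy as np
import pytest

from lesionkit import CohortSpec, Connectome, generate_connectome


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """Reduced 20-region cohort for fast structural tests."""
    return CohortSpec(n_subjects=3, n_regions=20, n_per_hemisphere=10,
                      n_modules=2, distance_decay=3.0, seed=11)


@pytest.fixture(scope="session")
def small_connectome(small_cohort_spec) -> Connectome:
    return generate_connectome(small_cohort_spec, 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_symmetric(rng: np.random.Generator, n: int, density: float = 0.6) -> np.ndarray:
    """Random symmetric non-negative zero-diagonal matrix."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    return w + w.T
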