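import numpy as np
import pytest

from biosig.cohort import CohortSpec, ModalitySpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-modality cohort with one strong planted feature."""
    spec = CohortSpec(
        n_nonconverter=60, n_converter=50, seed=42,
        modalities=(
            ModalitySpec("cognitive", 5, planted=((0, 1.2),),
                         block_correlation=0.0),
            ModalitySpec("lab", 10),
        ),
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_two_class_instance(rng, n_max=30, p_max=5):
    """A random small dataset with both classes present."""
    n = int(rng.integers(8, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    X = rng.standard_normal((n, p))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 1.0, -1.0
    return X, y
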