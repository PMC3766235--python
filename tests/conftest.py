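import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Deterministic 30-record cohort spanning all three stage groups."""
    from gfrval.cohort import CohortSpec, generate_cohort

    spec = CohortSpec(n=30, seed=7, scr_range=(0.64, 6.0), gfr_shift=0.9)
    return generate_cohort(spec)


def separated_training_set(rng, n_max=100, spread_range=(0.5, 2.0), sep_factor=0.4):
    """Random 1-D training set whose points are resolvable by the kernel:
    consecutive inputs at least sep_factor * spread apart."""
    n = int(rng.integers(1, n_max + 1))
    spread = float(rng.uniform(*spread_range))
    min_sep = sep_factor * spread
    gaps = rng.uniform(min_sep, 2.0 * min_sep, n)
    x = 0.3 + np.cumsum(gaps)
    y = rng.uniform(5.0, 150.0, n)
    return x, y, spread
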