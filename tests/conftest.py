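import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """30 blocks per class with default rhythm parameters."""
    from rrnet import simulate_cohort
    return simulate_cohort((30, 30, 30), duration=10.0, seed=202)


@pytest.fixture(scope="session")
def small_parts(small_cohort):
    from rrnet import split_parts
    return split_parts(small_cohort, n_parts=10, seed=5)


@pytest.fixture(scope="session")
def small_folds(small_parts):
    from rrnet import assemble_folds
    return assemble_folds(small_parts, window=100, n_perms=3, seed=5)
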