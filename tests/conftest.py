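import numpy as np
import pytest

import scfa_assoc as sa


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default study conditions."""
    return sa.generate(sa.CohortSpec(), seed=1)


@pytest.fixture(scope="session")
def encoded(default_cohort):
    """(CategoryScheme, IndicatorTable) for the default cohort."""
    return sa.encode_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def random_count_table(rng, shape=None):
    """A small strictly positive random count table (no zero margins)."""
    if shape is None:
        shape = (int(rng.integers(2, 7)), int(rng.integers(2, 7)))
    return rng.integers(1, 12, size=shape)
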