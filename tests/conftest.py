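import numpy as np
import pytest

from neogrowth.simulate import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-infant cohort, large enough for every stage to be non-degenerate."""
    spec = CohortSpec(
        n_infants=80,
        n_units=8,
        ga_counts=((30, 20), (31, 20), (32, 20), (33, 20)),
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (published sizes), generated once per session."""
    return generate_cohort(CohortSpec(seed=7))
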