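import numpy as np
import pytest

from csfstrat.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort with planted signal, shared across fast tests."""
    spec = CohortSpec(n_control=60, n_asymad=60, n_ad=60, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
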