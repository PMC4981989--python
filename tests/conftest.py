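import numpy as np
import pytest

from cnvgwas.simulate import simulate_multi_cohort_study, small_study_config

__all__ = ["small_study_config"]


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_multi_cohort_study(small_study_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
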