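import numpy as np
import pytest

from netpsych.datagen import asd_td_specs, generate_group_sample


@pytest.fixture(scope="session")
def study_specs():
    """The built-in two-group ground-truth specs (TD-like, ASD-like)."""
    return asd_td_specs()


@pytest.fixture(scope="session")
def td_table(study_specs):
    return generate_group_sample(study_specs[0], seed=41)


@pytest.fixture(scope="session")
def asd_table(study_specs):
    return generate_group_sample(study_specs[1], seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
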