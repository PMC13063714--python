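import numpy as np
import pytest

from ctcdx.cohort import GeneratorConfig, generate_cohort, separated_feature_specs


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort under the study conditions (228/170, 33 missing)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated synthetic cohort (group shifts of at least 2 SD)."""
    return generate_cohort(
        GeneratorConfig(seed=21, feature_specs=separated_feature_specs())
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
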