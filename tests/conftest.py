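import numpy as np
import pytest

from reliafc.synth import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A fast cohort: 6 patients / 8 controls, 180 time points."""
    fields = CohortConfig().to_dict()
    fields.update(
        {"n_patients": 6, "n_controls": 8, "n_timepoints": 180, "seed": 42}
    )
    fields.update(overrides)
    return CohortConfig(**fields)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
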