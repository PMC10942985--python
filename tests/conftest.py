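import numpy as np
import pytest

from histomark.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with a strong planted effect, shared across tests."""
    return generate_cohort(
        SyntheticCohortConfig(
            n_patients=12, tiles_per_slide=12, prevalence=0.5,
            effect_size=1.5, stain_jitter=0.5, seed=42,
        )
    )


@pytest.fixture(scope="session")
def null_cohort():
    """A null cohort: no morphology effect, no purity-label correlation."""
    return generate_cohort(
        SyntheticCohortConfig(
            n_patients=12, tiles_per_slide=12, prevalence=0.5,
            effect_size=0.0, stain_jitter=0.5, seed=43,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
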