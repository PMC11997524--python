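import numpy as np
import pytest

from cohort_subtyper.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient cohort, 3 subtypes, clear separation, no provider shift."""
    return generate_cohort(
        CohortConfig(
            n_patients=300,
            n_subtypes=3,
            embed_dim_tokens=64,
            provider_shift_scale=0.0,
            subtype_separation=5.0,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def shifted_cohort():
    """Cohort with a strong provider batch effect on note embeddings."""
    return generate_cohort(
        CohortConfig(
            n_patients=300,
            n_subtypes=3,
            embed_dim_tokens=64,
            provider_shift_scale=6.0,
            subtype_separation=4.0,
            seed=3,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
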