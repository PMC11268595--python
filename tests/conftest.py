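import numpy as np
import pandas as pd
import pytest

from fairdx import (CohortConfig, GroupFixture, ModalitySpec,
                    RateFixtureConfig, generate_cohort,
                    generate_prediction_fixture)


@pytest.fixture(scope="session")
def demo_cohort():
    """The built-in ~73-subject demo cohort (subjects + feature blocks)."""
    from fairdx import default_cohort_config
    return generate_cohort(default_cohort_config(seed=11))


@pytest.fixture(scope="session")
def gap_cohort_config():
    """Two equal gender groups whose feature separability differs sharply,
    so a trained classifier exhibits a large TPR/FPR disparity."""
    return CohortConfig(
        groups={"gender": [("female", 200), ("male", 200)]},
        base_rate={"gender": {"female": 0.5, "male": 0.5}},
        modalities=(ModalitySpec("sensor", 6, {"female": 2.5, "male": 0.6},
                                 noise_sd=1.0, attribute="gender"),),
        seed=101,
    )


@pytest.fixture
def two_group_fixture():
    """Exact-count prediction table: TPRs 0.9/0.8, FPRs 0.1/0.2."""
    cfg = RateFixtureConfig(groups=[
        GroupFixture("gstar", n_positive=10, n_negative=10, tpr=0.9, fpr=0.1),
        GroupFixture("g1", n_positive=10, n_negative=10, tpr=0.8, fpr=0.2),
    ], seed=5)
    return generate_prediction_fixture(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
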