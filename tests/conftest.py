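import numpy as np
import pytest

from rbdyn.config import (
    constant_hazard_cycling_config,
    reference_cycling_config,
    reference_decay_config,
    reference_model_params,
)
from rbdyn.synthetic import generate_cycling_cohort, generate_decay_cohort


@pytest.fixture(scope="session")
def wt_decay_cohort():
    """Reference WT induction-withdrawal cohort (200 cells/phase, 5% noise)."""
    return generate_decay_cohort(reference_decay_config(seed=101, n_cells=200))


@pytest.fixture(scope="session")
def noise_free_decay_cohort():
    config = reference_decay_config(seed=7, n_cells=20).with_(noise_cv=0.0, area_cv=0.0)
    return generate_decay_cohort(config)


@pytest.fixture(scope="session")
def cycling_cohort():
    """Cdk-low-style cohort with G1 length increasing in birth concentration."""
    return generate_cycling_cohort(reference_cycling_config(seed=202, n_cells=200))


@pytest.fixture(scope="session")
def null_hazard_cohort():
    return generate_cycling_cohort(constant_hazard_cycling_config(seed=303, n_cells=200))


@pytest.fixture(scope="session")
def reference_params():
    return reference_model_params()


@pytest.fixture(scope="session")
def reference_limit_cycle(reference_params):
    from rbdyn.model import burn_in_to_limit_cycle

    return burn_in_to_limit_cycle(reference_params)
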