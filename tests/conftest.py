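import numpy as np
import pytest

from drainknee import (
    ARMS,
    CLINICAL_SAMPLING_TIMES_H,
    MeasurementModel,
    generate_arm_fixtures,
    simulate_arm,
)


@pytest.fixture(scope="session")
def arm_results():
    """Reference simulation of each administration arm (shared; read-only)."""
    return {arm: simulate_arm(arm) for arm in ARMS}


@pytest.fixture(scope="session")
def sampling_times():
    return np.asarray(CLINICAL_SAMPLING_TIMES_H)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic measured dataset: assay noise switched off, LOD active."""
    return generate_arm_fixtures(
        n_replicates=1, seed=0, measurement=MeasurementModel(noise_sigma_log10=0.0)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The packaged synthetic dataset: 3 arms x 3 replicates, default noise."""
    return generate_arm_fixtures(seed=1234)
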