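import numpy as np
import pytest

from judoperf.synthetic import (
    ThrowPhaseParams,
    default_study_config,
    simulate_imu_repetition,
    simulate_study,
)


@pytest.fixture(scope="session")
def reference_params():
    """Throw-phase set-points at the reported hypoxia pre-training means."""
    return ThrowPhaseParams(
        t_offbalance=399.0, t_legext=898.0, t_impact=1172.0, t_horizontal=818.0,
        a_offbalance=6.4, a_legext=3.0, a_impact=26.4,
    )


@pytest.fixture(scope="session")
def noiseless_throw(reference_params):
    return simulate_imu_repetition(reference_params)


@pytest.fixture(scope="session")
def study_with_effects():
    """Default study conditions (n = 13/11, injected effects), fixed seed."""
    return simulate_study(default_study_config(seed=42))
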