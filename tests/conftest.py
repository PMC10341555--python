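import numpy as np
import pytest

from tugfall.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Ten community-like subjects, fixed seed, shared across tests."""
    return generate_cohort(CohortSpec.community(10, seed=1))


@pytest.fixture(scope="session")
def clean_subject():
    """One noise-free subject with deterministic gait parameters."""
    spec = CohortSpec.community(
        1,
        seed=0,
        noise_sd=0.0,
        cadence_sd=0.0,
        step_length_sd=0.0,
        phase_duration_sds={p: 0.0 for p in ("sist", "walk_out", "turn", "walk_back", "stsi")},
        fall_risk_fraction=0.0,
    )
    return generate_cohort(spec)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
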