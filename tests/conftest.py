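import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sc_attention.types import CohortSpec, RateKernelParams
from sc_attention import synthetic_data as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def expert_spec():
    return CohortSpec("expert", 1, 200, True, "change_locked")


@pytest.fixture(scope="session")
def expert_trials(expert_spec):
    return syn.simulate_trial_timeline(expert_spec, 11, session_id="fix")


@pytest.fixture(scope="session")
def default_params():
    return RateKernelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_lick_sessions(n_sessions, level, archetype, seed, trials_per_session=80):
    """Lick-only sessions (no spikes/eye) for classifier tests."""
    spec = CohortSpec(
        level, n_sessions, trials_per_session,
        has_no_change_trials=(level != "intermediate"),
        lick_archetype=archetype, units_per_session=0,
    )
    prefix = f"{level[:3]}_{archetype[:4]}"
    return [
        sd.record
        for sd in syn.simulate_cohort(spec, seed, session_prefix=prefix, with_eye=False)
    ]
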