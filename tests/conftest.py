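import numpy as np
import pytest

from gaitlen import GaitScenario, StrideRecord, generate_trace


def make_stride(
    F=1.0, a_max=12.0, a_min=8.0, a_mean=10.0, a_v=4.0, d_ref=None
) -> StrideRecord:
    """Hand-built stride record with consistent invariants."""
    duration = 1.0 / F
    return StrideRecord(
        start_idx=0, end_idx=10, duration=duration, F=F,
        a_max=a_max, a_min=a_min, a_r=a_max - a_min, a_mean=a_mean, a_v=a_v,
        d_ref=d_ref,
    )


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless 50-stride synthetic trial with ground truth."""
    scenario = GaitScenario(seed=11, n_strides=50, noise_sd=0.0, length_noise_sd=0.0)
    trace, truth = generate_trace(scenario)
    return scenario, trace, truth


@pytest.fixture(scope="session")
def noisy_trial():
    """Default-noise 100-stride trial."""
    scenario = GaitScenario(seed=12, n_strides=100)
    trace, truth = generate_trace(scenario)
    return scenario, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
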