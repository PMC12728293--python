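import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ectophys as ep

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_config() -> ep.TraceSimConfig:
    """Deterministic single-animal run: no noise, no bursts, no background."""
    return ep.TraceSimConfig(
        noise_sd=0.0,
        burst_rate=0.0,
        background_intercept=0.0,
        background_slope=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_trace(noiseless_config):
    return ep.simulate_do_trace(noiseless_config)


@pytest.fixture(scope="session")
def noisy_trace():
    cfg = ep.TraceSimConfig(noise_sd=0.3, burst_rate=0.5, seed=7)
    return ep.simulate_do_trace(cfg)


@pytest.fixture(scope="session")
def constant_uptake_trace():
    """Closed phases decline exactly linearly: EPOC amplitude negligible."""
    cfg = ep.TraceSimConfig(
        true_smr=0.38,
        true_mmr=0.38 * (1 + 1e-12),
        acclimation_elevation=0.0,
        noise_sd=0.0,
        burst_rate=0.0,
        background_intercept=0.0,
        background_slope=0.0,
        total_duration=6.0,
        seed=0,
    )
    trace, truth = ep.simulate_do_trace(cfg)
    return cfg, trace, truth


def rel_err(est: float, truth: float) -> float:
    return abs(est - truth) / truth
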