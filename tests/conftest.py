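import numpy as np
import pytest

from mmndecay.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """Degenerate generator: no sensor noise, no artifacts, no between-subject
    variability, latency pinned to 180 ms — the injected MMN is fully known."""
    return SimulationConfig(
        noise_sd_uv=0.0,
        artifact_rate=0.0,
        amp_sd_uv=0.0,
        decay_sd=0.0,
        latency_sd_ms=0.0,
        latency_mean_ms=180.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def noise_free_subject(noise_free_config):
    return simulate_cohort(noise_free_config, seed=1)[0]


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimulationConfig(seed=7), seed=7)


def windowed_mean_oracle(peak_uv: float, width_ms: float, half_window_ms: float = 20.0) -> float:
    """Independent closed form for the mean of a Gaussian bump over a window
    centred at its peak: A * (sigma * sqrt(2*pi) / W) * erf(W / (2*sigma*sqrt(2)))."""
    from scipy.special import erf

    w = 2 * half_window_ms
    return peak_uv * (width_ms * np.sqrt(2 * np.pi) / w) * erf(
        half_window_ms / (width_ms * np.sqrt(2))
    )
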