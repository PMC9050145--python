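import numpy as np
import pytest

from socsim import CircuitConfig, NeuropathyConfig, SoundStimulus

CONTROL = NeuropathyConfig()


@pytest.fixture(scope="session")
def control_stim() -> SoundStimulus:
    """The standard probe: 200 Hz, 50 dB SPL, 100 ms, ITD 0."""
    return SoundStimulus(200.0, 50.0, 100.0, 0.0)


@pytest.fixture(scope="session")
def small_config() -> CircuitConfig:
    """Scaled circuit for fast tests; periphery statistics are unchanged
    because bushy/MSO in-degrees draw from the full 300-fiber SGN pool."""
    return CircuitConfig(n_sbc=40, n_gbc=40, n_mso=40, n_trials=2)


@pytest.fixture(scope="session")
def tiny_config() -> CircuitConfig:
    return CircuitConfig(n_sbc=12, n_gbc=12, n_mso=12, n_trials=1, duration_ms=50.0)


def pooled_rate(result, population: str, window=None) -> float:
    """Mean per-cell rate of a population pooled over sides and trials."""
    from socsim.metrics import population_rate

    window = window or result.config.rate_window_ms
    rates = [
        population_rate(sts, window)
        for side in ("left", "right")
        for sts in result.trains(population, side)
    ]
    return float(np.mean(rates))
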