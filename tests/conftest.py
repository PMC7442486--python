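import numpy as np
import pytest

from driftpulse import make_preset, simulate_experiment


@pytest.fixture(scope="session")
def quiet_preset():
    """monkey_A with all stochastic ingredients switched off."""
    from dataclasses import replace
    p = make_preset("monkey_A", diffusion=0.0, noise_sd=0.0, fixation_sd=0.0,
                    baseline_drift=(0.0, 0.0))
    return replace(p, msac=replace(p.msac, rate=0.0))


@pytest.fixture(scope="session")
def small_experiment():
    """60+60 monkey_A trials shared across detection/alignment tests."""
    return simulate_experiment(make_preset("monkey_A"), 60,
                               ["black_flash", "none"], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
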