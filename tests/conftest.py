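import numpy as np
import pytest

from tfimpact.formats_io import Pwm
from tfimpact.pipeline import run_study
from tfimpact.synthetic import gen_chip_windows, random_pwm, simulate_study


@pytest.fixture(scope="session")
def toy_pwm() -> Pwm:
    """Width-2 motif preferring 'AG', uniform background, no pseudocount."""
    return Pwm("toy", [[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.7, 0.1]])


@pytest.fixture(scope="session")
def sharp_pwm() -> Pwm:
    return random_pwm(width=8, consensus_prob=0.85, seed=11, name="sharp")


@pytest.fixture(scope="session")
def chip_windows(sharp_pwm):
    """Noisy synthetic ChIP windows from the sharp motif (train, test)."""
    train, _ = gen_chip_windows(sharp_pwm, n_pos=120, n_neg=120, noise_sd=0.05, seed=21)
    test, _ = gen_chip_windows(sharp_pwm, n_pos=40, n_neg=40, noise_sd=0.05, seed=22)
    return train, test


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(seed=5)


@pytest.fixture(scope="session")
def tiny_run(tiny_study):
    return run_study(tiny_study, seed=5)
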