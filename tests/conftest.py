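import numpy as np
import pytest

from lnptitrate.scenarios import generate_titration_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def noiseless_hh_points():
    """Seven points exactly on the HH curve with pKa 7."""
    return generate_titration_table(7.0, 1.0, np.arange(4.0, 10.1, 1.0), 0.0, seed=0)


@pytest.fixture
def noisy_hh_points():
    """Nine noisy points around pKa 4.91 with sem 0.01 (fixed seed)."""
    return generate_titration_table(4.91, 1.0, np.arange(3.17, 11.18, 1.0), 0.01, seed=7)


@pytest.fixture
def noiseless_ghh_points():
    """Anti-cooperative (n = 0.5) noiseless table around pKa 6.5."""
    return generate_titration_table(6.5, 0.5, np.linspace(3.0, 10.0, 8), 0.0, seed=0)


def metropolis_lambda_sampler(bias, temperature, n_samples, seed, step=0.25):
    """Independent Metropolis chain sampling exp(-V_bias/RT): the oracle
    distribution for the lambda-histogram validation."""
    from lnptitrate._constants import rt_kj
    from lnptitrate.hamiltonian import eval_vbias

    rng = np.random.default_rng(seed)
    beta = 1.0 / rt_kj(temperature)
    x = 0.0
    ux = eval_vbias(x, bias)
    out = np.empty(n_samples)
    for i in range(n_samples):
        prop = x + rng.uniform(-step, step)
        up = eval_vbias(prop, bias)
        if np.log(rng.random()) < -beta * (up - ux):
            x, ux = prop, up
        out[i] = x
    return out
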