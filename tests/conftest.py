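import numpy as np
import pytest

from diurnalfit import ModelParams, SyntheticConfig, evaluate_response


@pytest.fixture
def unimodal_params() -> ModelParams:
    """A rise-then-fall curve peaking at 09:00."""
    return ModelParams(-2.0, 18.0, 3.0)


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1, noise_sigma_ln=0.0)


def make_series(params: ModelParams, times, sigma_ln: float = 0.0, rng=None):
    """Model-generated series with optional multiplicative lognormal noise."""
    t = np.asarray(times, dtype=float)
    clean = evaluate_response(params, t)
    if sigma_ln == 0.0:
        return t, np.asarray(clean)
    return t, clean * np.exp(rng.normal(0.0, sigma_ln, size=t.size))


def random_unimodal(rng, t_star_range=(1.0, 20.0)) -> ModelParams:
    """Random parameters with an interior peak inside the given hour range."""
    omega = -rng.uniform(0.5, 5.0)
    t_star = rng.uniform(*t_star_range)
    return ModelParams(omega, -omega * t_star, rng.uniform(-1.0, 4.0))
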