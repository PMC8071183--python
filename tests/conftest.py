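import numpy as np
import pytest

from girkfit.params import CascadeParams, LigandKinetics, fast_reporter_params


@pytest.fixture(scope="session")
def fast_params() -> CascadeParams:
    """Fast-reporter regime with recording noise."""
    return fast_reporter_params()


@pytest.fixture(scope="session")
def fast_noise_free() -> CascadeParams:
    """Fast-reporter regime without recording noise."""
    return fast_reporter_params(noise_sd=0.0)


@pytest.fixture(scope="session")
def da_wt() -> LigandKinetics:
    """Dopamine at the wild-type receptor (bundled reference truth)."""
    return LigandKinetics("DA", k_on=9.70e7, k_off=0.197, efficacy=1.0)


def pure_exponential_trace(tau, amplitude, offset, t_end, sample_rate=156.0,
                           noise_sd=0.0, seed=None, t_start=0.0):
    """Synthetic single-exponential decay as (time, values)."""
    t = np.arange(int(t_end * sample_rate) + 1) / sample_rate
    y = offset + amplitude * np.exp(-np.maximum(t - t_start, 0.0) / tau)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return t, y
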