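import numpy as np
import pytest

import natcont as ncp


@pytest.fixture(scope="session")
def small_study():
    """Noiseless 6-session synthetic study with a 10-neuron ground-truth pop."""
    cfg = ncp.SyntheticStudyConfig(n_sessions=6, session_duration=120.0,
                                   n_neurons=10, noise_sd=0.0, seed=42)
    sessions, truth = ncp.make_synthetic_study(cfg)
    return sessions, truth


@pytest.fixture(scope="session")
def fast_slow_pop():
    """20 neurons in the fast-adapt/slow-integrate regime."""
    return ncp.sample_population(20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def euler_ma(params, raster, dt_fine=1e-4):
    """Independent explicit-Euler oracle for the MA dynamics.

    Steps the ODEs at dt_fine with zero-order-hold inputs and returns the
    activity at the end of each raster bin (polarity applied).
    """
    up = int(round(raster.dt / dt_fine))
    n = len(raster)
    r = a_s = a_p = 0.0
    ti, ta = params.tau_int, params.tau_a
    finite = np.isfinite(ta)
    out = np.empty(n)
    for b in range(n):
        Is, Ip = raster.I_s[b], raster.I_p[b]
        for _ in range(up):
            drive = params.x_s * (1 - a_s) * Is + params.x_p * (1 - a_p) * Ip
            r += dt_fine * (-r + drive) / ti
            if finite:
                a_s += dt_fine * (-a_s + Is) / ta
                a_p += dt_fine * (-a_p + Ip) / ta
        out[b] = r
    return params.polarity * out
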