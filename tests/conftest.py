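import numpy as np
import pytest

from micromash import default_dataset, default_program


def rk4_final(G0, S0, a, d, t, n_steps=5000):
    """Independent fixed-step RK4 integration of the two-compartment system,
    vectorized over parameter draws. Used as the numeric oracle for the
    closed-form stage solution."""
    a = np.atleast_1d(np.asarray(a, float))
    d = np.atleast_1d(np.asarray(d, float))
    t = np.atleast_1d(np.asarray(t, float))
    G = np.broadcast_to(np.asarray(G0, float), a.shape).copy()
    S = np.broadcast_to(np.asarray(S0, float), a.shape).copy()
    h = t / n_steps

    def f(G, S):
        return -a * G, a * G - d * S

    for _ in range(n_steps):
        k1g, k1s = f(G, S)
        k2g, k2s = f(G + h / 2 * k1g, S + h / 2 * k1s)
        k3g, k3s = f(G + h / 2 * k2g, S + h / 2 * k2s)
        k4g, k4s = f(G + h * k3g, S + h * k3s)
        G = G + h / 6 * (k1g + 2 * k2g + 2 * k3g + k4g)
        S = S + h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
    return G, S


@pytest.fixture(scope="session")
def program():
    return default_program()


@pytest.fixture(scope="session")
def stock_dataset():
    """The default synthetic dataset at a fixed seed (noisy, triplicate)."""
    return default_dataset(seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default dataset with all noise switched off."""
    return default_dataset(seed=0, cv=0.0, run_scale_sd=0.0)
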