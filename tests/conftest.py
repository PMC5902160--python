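import numpy as np
import pytest

from stridemod.model import LocomotionSession
from stridemod.synthetic import SessionConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """A plain rest+run session (no stimuli), defaults, fixed seed."""
    return generate_session(
        SessionConfig(seed=11, n_strides=200, rest_epochs=[(10.0, 3.0)])
    )


@pytest.fixture(scope="session")
def default_results(default_session):
    return LocomotionSession.from_synthetic(default_session).fit()


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless, artifact-free session for exact-recovery checks."""
    return generate_session(
        SessionConfig(seed=7, n_strides=120, noise_sd_au=0.0, artifact_rate_hz=0.0)
    )


def mc_kuiper_null(n: int, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null distribution of the Kuiper V statistic (uniform)."""
    u = np.sort(rng.random((n_sim, n)), axis=1)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u, axis=1)
    d_minus = np.max(u - (i - 1) / n, axis=1)
    return d_plus + d_minus


def mc_rayleigh_null(n: int, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null distribution of the Rayleigh R statistic (uniform)."""
    theta = rng.uniform(0, 2 * np.pi, (n_sim, n))
    c = np.cos(theta).sum(axis=1)
    s = np.sin(theta).sum(axis=1)
    return np.hypot(c, s) / n
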