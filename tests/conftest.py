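import numpy as np
import pytest

from cardioergm.simulator import LatticeConfig, simulate


@pytest.fixture(scope="session")
def small_planar_series():
    """Fully coupled, defect-free 50x50 tissue: clean planar waves."""
    cfg = LatticeConfig(
        L=50, nu=1.0, n_dysfunctional=0, epsilon=0.0,
        tau_mean=20, tau_jitter=2, pacing_period=70, horizon=220, seed=5,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_noisy_series():
    """Weakly coupled small tissue with defects (wavebreak-prone)."""
    cfg = LatticeConfig(
        L=60, nu=0.1, n_dysfunctional=180, tau_mean=25, tau_jitter=3,
        pacing_period=80, horizon=400, seed=11,
    )
    return simulate(cfg)


def lagged_chain(seed, n=10, T=2000, auto=0.3, coupling=0.45):
    """Directed chain of AR(1) processes, each driven by its predecessor
    at lag 1; the ground truth for causal-recovery checks."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, T))
    eps = rng.standard_normal((n, T))
    for t in range(1, T):
        X[0, t] = auto * X[0, t - 1] + eps[0, t]
        for i in range(1, n):
            X[i, t] = auto * X[i, t - 1] + coupling * X[i - 1, t - 1] + eps[i, t]
    return X
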