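import numpy as np
import pytest

import cointnet as cn


@pytest.fixture(scope="session")
def rank2_system():
    """A p=6, r=2 cointegrated OU model and its discretization."""
    ou = cn.random_cointegrated_ou(6, 2, seed=1000)
    return ou, cn.discretize_ou(ou)


@pytest.fixture(scope="session")
def rank2_data(rank2_system):
    """Simulated trials from the rank-2 system (30 trials x 100 samples)."""
    _, var = rank2_system
    return cn.simulate_trials(var, 30, 100, seed=2)


@pytest.fixture(scope="session")
def zero_sum_data():
    """Common-average referenced trials from a p=6, r=2 model."""
    ou = cn.random_cointegrated_ou(6, 2, seed=5)
    var = cn.discretize_ou(ou)
    raw = cn.simulate_trials(var, 10, 120, seed=6)
    return cn.apply_common_average(raw)


@pytest.fixture(scope="session")
def stats_rank2(rank2_data):
    z = cn.center(rank2_data)
    return z, cn.sufficient_stats(z)


def class_dependent_dataset(seed, p=5, r=2, n_trials=80, n_samples=40,
                            same_model=False):
    """Trials whose dynamics depend on the (covariate-driven) outcome."""
    design = cn.make_task_design(
        {"duration_ms": [20, 40, 70, 110], "orientation_deg": [0, 45],
         "contrast": ["high", "low"]}, repetitions=5, seed=seed).iloc[:n_trials]
    design = design.reset_index(drop=True)
    coefs = {"intercept": 0.2,
             "duration_ms": {20: -0.8, 40: -0.2, 70: 0.3, 110: 0.8}}
    acc = cn.simulate_outcomes(design, coefs, seed=seed + 1)
    if acc.min() == acc.max():
        acc[0] = 1 - acc[0]
    var_a = cn.discretize_ou(cn.random_cointegrated_ou(p, r, seed=seed + 10))
    var_b = var_a if same_model else cn.discretize_ou(
        cn.random_cointegrated_ou(p, r, seed=seed + 11))
    ta = cn.simulate_trials(var_a, n_trials, n_samples, seed=seed + 2)
    tb = cn.simulate_trials(var_b, n_trials, n_samples, seed=seed + 3)
    vals = [ta.values[m] if acc[m] == 1 else tb.values[m]
            for m in range(n_trials)]
    data = cn.EpochedData(vals, ta.channel_labels, ta.delta, design)
    return data, acc, design


def random_streams(seed, n=200, p=3):
    """Plain random centered streams for algebraic identities."""
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal((n, p))
    z1 = rng.standard_normal((n, p))
    z0 -= z0.mean(axis=0)
    z1 -= z1.mean(axis=0)
    return cn.CenteredStreams(
        z0=z0, z1=z1, trial_index=np.zeros(n, dtype=int),
        mean_dx=np.zeros(p), mean_lag=np.zeros(p),
    )
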