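"""Shared fixtures: small simulated datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from sulapop import SimConfig, simulate_population


def make_glmm_data(rng, n_groups=300, n_obs=6, beta=(-1.0, 0.5), sigma=0.7):
    """One-covariate random-intercept Bernoulli dataset with known truth."""
    codes = np.repeat(np.arange(n_groups), n_obs)
    x = rng.normal(size=n_groups * n_obs)
    X = np.column_stack([np.ones(len(x)), x])
    u = rng.normal(0.0, sigma, n_groups)
    eta = X @ np.asarray(beta) + u[codes]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, X, codes


def simulate_cjs_histories(rng, n=500, T=10, phi=0.9, p=0.9, entry_spread=True):
    """Constant-rate CJS histories released across occasions."""
    dets = []
    for _ in range(n):
        f = rng.integers(0, T - 1) if entry_spread else 0
        d = np.zeros(T, dtype=np.int8)
        d[f] = 1
        for t in range(f, T - 1):
            if rng.random() >= phi:
                break
            if rng.random() < p:
                d[t + 1] = 1
        dets.append(d)
    det = np.array(dets)
    return det, np.zeros(n, dtype=int), np.full(n, 4)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced-size synthetic study shared by read-only tests."""
    cfg = SimConfig(seed=42, n_seasons=12, n_recruits_per_season=40,
                    failure_years={5: -4.0})
    return simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
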