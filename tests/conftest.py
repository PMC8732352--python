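import numpy as np
import pandas as pd
import pytest

from mbcrs.simulate import SimulationConfig, simulate_cohort


def small_config(seed=11, **overrides):
    """A fast cohort: 600 women, 4 estimators, 20 candidate CpGs."""
    base = dict(
        n_cohort=600, n_probes=80, n_causal_probes=4, n_estimators=4,
        n_causal_estimators=1, n_candidate_cpgs=20, probes_per_estimator=10,
        baseline_hazard=0.05, subcohort_fraction=0.25, seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    return simulate_cohort(small_config())


@pytest.fixture()
def survival_fixture():
    """A tiny weighted left-truncated survival dataset (n=60, p=3)."""
    rng = np.random.default_rng(5)
    n, p = 60, 3
    X = rng.normal(size=(n, p))
    beta = np.array([0.6, -0.4, 0.0])
    T = rng.exponential(1.0 / (0.15 * np.exp(X @ beta)))
    C = rng.exponential(6.0, n)
    stop = np.minimum(T, C) + 0.05
    event = (T <= C).astype(int)
    entry = stop * rng.uniform(0.0, 0.6, n)
    w = rng.uniform(0.5, 2.5, n)
    return X, entry, stop, event, w
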