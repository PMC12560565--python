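"""Shared fixtures: synthetic cohorts and small penalized-regression problems."""

import numpy as np
import pytest

from psapredict import default_trial_config, simulate_cohort


@pytest.fixture(scope="session")
def trial_cohort():
    """One trial-scale cohort (20 patients per arm) with known ground truth."""
    return simulate_cohort(default_trial_config(), seed=7)


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort (250/arm) for selection- and recovery-style checks."""
    return simulate_cohort(default_trial_config(n_per_arm=250), seed=11)


@pytest.fixture(scope="session")
def toy_logistic():
    """A small (n=12, p=3) binary problem for brute-force CV comparisons."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 3))
    y = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0, 1, 0], dtype=float)
    return X, y, ["a", "b", "c"]
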