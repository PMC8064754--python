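"""Shared fixtures: solved policies and simulated cohorts are expensive, so
they are session-scoped and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from attnddm import ModelParams, solve_policy
from attnddm.trial_simulator import generate_trial_design, simulate_cohort


@pytest.fixture(scope="session")
def bestfit_params() -> ModelParams:
    """The parameter profile that best mimics human behavior."""
    return ModelParams()


@pytest.fixture(scope="session")
def bestfit_policy(bestfit_params):
    return solve_policy(bestfit_params)


@pytest.fixture(scope="session")
def coarse_params() -> ModelParams:
    """Coarser lattice for tests that re-solve policies repeatedly."""
    return ModelParams(dt_grid=0.1, dt_sim=0.1, t_max=3.0, delta_step=0.1, delta_max=10.0)


@pytest.fixture(scope="session")
def small_cohort(bestfit_params, bestfit_policy):
    """8 participants x 320 trials at the best-fit profile."""
    design = generate_trial_design(0, 7, 5, 8)
    trials, fixations = simulate_cohort(design, bestfit_policy, bestfit_params, master_seed=123)
    return trials, fixations


@pytest.fixture(scope="session")
def full_cohort(bestfit_params, bestfit_policy):
    """The published protocol: 39 participants x 1280 trials."""
    design = generate_trial_design(0, 7, 20, 39)
    trials, fixations = simulate_cohort(design, bestfit_policy, bestfit_params, master_seed=2024)
    return trials, fixations


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
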