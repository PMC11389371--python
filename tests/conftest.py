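"""Shared fixtures: small profiles for unit tests and the (lazily built)
default synthetic cohort with full leave-one-out records for the
integration-level checks."""

from __future__ import annotations

import numpy as np
import pytest

import mbinterp as mi
from mbinterp.pipeline import DEFAULT_METHOD_PARAMS

COHORT_SEED = 1
SUBSAMPLE_SEED = 7


def make_profile(seed: int = 0, n_samples: int = 20, n_taxa: int = 8,
                 **cfg_kwargs) -> mi.LongitudinalProfile:
    """One small adult-regime synthetic profile for unit tests."""
    cfg = mi.SyntheticConfig(
        n_individuals=1,
        n_adult=1,
        n_taxa=n_taxa,
        n_samples_range=(n_samples, n_samples),
        seed=seed,
        **cfg_kwargs,
    )
    profiles, _ = mi.simulate_cohort(cfg)
    return profiles[0]


@pytest.fixture(scope="session")
def small_profile() -> mi.LongitudinalProfile:
    return make_profile(seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = mi.SyntheticConfig(
        n_individuals=6, n_adult=3, n_taxa=12, n_samples_range=(18, 24), seed=11
    )
    return mi.simulate_cohort(cfg)


def glv_oracle_system(seed: int = 42, n_taxa: int = 5, n_samples: int = 40):
    """A well-conditioned noise-free Lotka-Volterra test system.

    Oscillatory interactions (strong antisymmetric component) keep the
    trajectory exploring state space, so the regression design stays well
    conditioned and the estimators can be validated at tight tolerances.
    """
    rng = np.random.default_rng(seed)
    m = n_taxa
    R = rng.standard_normal((m, m))
    A = -0.25 * np.eye(m) + 0.3 * (R - R.T) + 0.05 * rng.standard_normal((m, m))
    B = rng.uniform(0.1, 0.4, m)
    x0 = mi.normalize(rng.uniform(0.5, 1.5, m))
    times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.4, 1.4, n_samples - 1))])
    return mi.GLVParameters(A=A, B=B), x0, times


@pytest.fixture(scope="session")
def glv_oracle():
    params, x0, times = glv_oracle_system()
    profile = mi.simulate_glv_profile(
        params, x0, times, noise_sd=0.0, seed=0, closure=False
    )
    return params, profile


@pytest.fixture(scope="session")
def cohort():
    """The default two-regime cohort (10 adults, 10 infants), seeded."""
    return mi.simulate_cohort(mi.SyntheticConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_records(cohort):
    """Leave-one-out records for every registered method on the cohort.

    This is the expensive integration fixture (a few minutes, dominated by
    the LIMITS bootstrap); everything downstream shares it.
    """
    profiles, _ = cohort
    records: dict[str, list[mi.EvaluationRecord]] = {}
    for method in mi.METHOD_NAMES:
        spec = mi.InterpolatorSpec(method, DEFAULT_METHOD_PARAMS.get(method, {}))
        recs = []
        for prof in profiles:
            recs.extend(mi.loo_evaluate(prof, spec))
        records[method] = recs
    return records
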