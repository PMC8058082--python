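"""Shared fixtures: small synthetic cohorts and fitted pipeline objects.

Expensive objects (cohort + subtyping forest) are session-scoped and shared
across test modules; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rfsubtype import CohortConfig, discover_subtypes, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter cohort (the study-scale strong-signal conditions)."""
    return generate_cohort(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def subtype_run(default_cohort):
    """Subtype discovery at reduced tree count on the default cohort."""
    return discover_subtypes(default_cohort, n_trees=400, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_gaussians(n_per_class: int, n_features: int, d: float, seed: int):
    """Two-class Gaussian toy problem: first feature shifted by d."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[n_per_class:, 0] += d
    y = np.array([0] * n_per_class + [1] * n_per_class)
    cols = [f"f{j}" for j in range(n_features)]
    return pd.DataFrame(X, columns=cols), y
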