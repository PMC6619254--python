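from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tfnbs import CohortStack

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cohort(n_nodes: int, n_per_group: int, seed: int, effect: dict | None = None) -> CohortStack:
    """Random symmetric cohort; `effect` maps (i, j) edges to mean shifts in group 1."""
    rng = np.random.default_rng(seed)
    s = 2 * n_per_group
    ii, jj = np.triu_indices(n_nodes, k=1)
    vals = rng.standard_normal((s, ii.size))
    if effect:
        col = {(a, b): k for k, (a, b) in enumerate(zip(ii.tolist(), jj.tolist()))}
        for (a, b), shift in effect.items():
            vals[n_per_group:, col[(min(a, b), max(a, b))]] += shift
    subjects = np.zeros((s, n_nodes, n_nodes))
    subjects[:, ii, jj] = vals
    subjects[:, jj, ii] = vals
    return CohortStack(subjects, np.repeat([0, 1], n_per_group))


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture
def small_cohort():
    """10 nodes, 2 x 8 subjects, pure noise."""
    return make_cohort(10, 8, seed=1234)
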