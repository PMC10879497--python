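from __future__ import annotations

import numpy as np
import pytest

from netaging.cohort import (CohortSpec, default_partition,
                             simulate_timeseries, target_correlation_matrix)
from netaging.connectivity import fisher_z, pearson_matrix


@pytest.fixture(scope="session")
def planted_labels() -> np.ndarray:
    """72 ROIs in 6 equal bilateral modules."""
    return default_partition()


@pytest.fixture(scope="session")
def make_planted_zplus(planted_labels):
    """Factory for noisy Z+ matrices with the planted 6-module structure
    (within z 0.55, between z 0.10 by default, 415 usable volumes)."""

    def _make(n_subjects: int, seed: int, within_z: float = 0.55,
              between_z: float = 0.10, n_volumes: int = 415) -> list[np.ndarray]:
        C, _ = target_correlation_matrix(planted_labels, np.tanh(within_z),
                                         np.tanh(between_z))
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_subjects):
            ts = simulate_timeseries(C, n_volumes, seed=rng)
            Z = fisher_z(pearson_matrix(ts)).values
            out.append(np.where(Z > 0, Z, 0.0))
        return out

    return _make


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """2 cohorts x 2 sexes x 3 subjects, no dropout."""
    return CohortSpec(n_subjects_per_cell=3,
                      cohorts=(("A", "Y"), ("B", "X")),
                      dropout_prob_per_timepoint=0.0, seed=42)


def two_cliques(k: int) -> np.ndarray:
    """Adjacency of two disconnected k-cliques."""
    A = np.zeros((2 * k, 2 * k))
    A[:k, :k] = 1
    A[k:, k:] = 1
    np.fill_diagonal(A, 0)
    return A
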