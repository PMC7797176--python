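"""Shared fixtures: small simulated cohorts and trained toy models."""

from __future__ import annotations

import numpy as np
import pytest

import adprog as ap
from adprog.filling import fit_fallback_means


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truths = ap.simulate_cohort(ap.SimConfig(n_subjects=60, seed=11))
    return cohort, truths


@pytest.fixture(scope="session")
def normalized(small_cohort):
    cohort, _ = small_cohort
    stats = ap.fit_norm_stats(cohort)
    norm = ap.znormalize(cohort, stats)
    means = fit_fallback_means(norm)
    return norm, stats, means


@pytest.fixture(scope="session")
def tiny_model(normalized):
    """A quickly trained minimal-RNN with model filling."""
    norm, stats, means = normalized
    cfg = ap.TrainConfig(hidden=16, epochs=10, seed=0)
    return ap.train(norm, "model", cfg, stats, means)


def make_trajectory(values, observed, months=None, resolution=1, subject_id="T"):
    """Hand-build a SubjectTrajectory from dense arrays for unit tests."""
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    V = values.shape[0]
    if months is None:
        months = np.arange(V, dtype=float) * resolution
    masked = values.copy()
    vmask = np.concatenate(
        [np.repeat(observed[:, :1], 3, axis=1), observed[:, 1:]], axis=1
    )
    masked[~vmask] = np.nan
    from adprog.cohort import build_monthly_grid

    return build_monthly_grid(np.asarray(months, float), masked, observed,
                              resolution, subject_id)
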