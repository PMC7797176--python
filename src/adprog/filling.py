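"""Preprocessing missing-data strategies: forward fill, linear fill, mean fill.

Both strategies operate on a subject's gridded value matrix and return a
fully dense copy; the observation mask is never modified, so losses and
metrics continue to score only truly observed entries.  Model filling — the
integrative strategy where the sequence model's own one-step predictions
replace missing inputs — lives in :mod:`adprog.training` but conforms to the
same strategy interface.

Leading gaps (a feature never yet observed) are filled with training-set
fallback values: the pooled mean for continuous markers and the empirical
class-frequency 3-vector for diagnosis.  Trailing gaps are carried forward
under both strategies.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, SubjectTrajectory

__all__ = [
    "FILL_STRATEGIES",
    "fit_fallback_means",
    "forward_fill",
    "linear_fill",
    "fill_matrix",
]

FILL_STRATEGIES = ("forward", "linear", "model")


def fit_fallback_means(train_cohort: Cohort) -> np.ndarray:
    """Training-set fallback values as a 25-vector.

    Entries 0-2 are the empirical diagnosis class frequencies over all
    observed training timepoints; entries 3+ are each marker's mean over all
    observed entries, pooling subjects and timepoints.
    """
    if len(train_cohort) == 0:
        raise ValueError("cannot fit fallback means on an empty cohort")
    schema = train_cohort.schema
    out = np.zeros(schema.n_values)
    dx = np.concatenate(
        [s.visit_values[s.visit_observed[:, 0], :3] for s in train_cohort]
        or [np.zeros((0, 3))]
    )
    if len(dx) == 0:
        raise ValueError("diagnosis never observed in the training cohort")
    out[:3] = dx.mean(axis=0)
    for j in range(schema.n_continuous):
        vals = np.concatenate(
            [s.visit_values[s.visit_observed[:, 1 + j], 3 + j] for s in train_cohort]
        )
        if vals.size == 0:
            raise ValueError(
                f"feature {schema.continuous_names[j]!r} never observed in training cohort"
            )
        out[3 + j] = vals.mean()
    return out


def _feature_columns(n_features: int):
    """Map each of the 23 mask features to its value-column slice."""
    yield 0, slice(0, 3)
    for f in range(1, n_features):
        yield f, slice(2 + f, 3 + f)


def forward_fill(traj: SubjectTrajectory, means: np.ndarray) -> np.ndarray:
    """Last-observation-carried-forward; leading gaps take training means."""
    T = traj.n_timepoints
    out = traj.values.copy()
    for f, cols in _feature_columns(traj.observed.shape[1]):
        obs = traj.observed[:, f]
        last = means[cols].copy()
        for t in range(T):
            if obs[t]:
                last = out[t, cols]
            else:
                out[t, cols] = last
    return out


def linear_fill(
    traj: SubjectTrajectory, means: np.ndarray, hard_diagnosis: bool = False
) -> np.ndarray:
    """Linear interpolation of interior gaps per feature.

    Trailing gaps (no future observation) are forward-filled and leading gaps
    take the training means, matching the forward strategy there.  The
    categorical diagnosis is interpolated on its one-hot coordinates, leaving
    soft 3-vectors at interpolated timepoints; ``hard_diagnosis`` switches to
    carrying the last observed label forward instead.
    """
    T = traj.n_timepoints
    out = traj.values.copy()
    idx = np.arange(T)
    for f, cols in _feature_columns(traj.observed.shape[1]):
        obs = traj.observed[:, f]
        if f == 0 and hard_diagnosis:
            last = means[cols].copy()
            for t in range(T):
                if obs[t]:
                    last = out[t, cols]
                else:
                    out[t, cols] = last
            continue
        if not obs.any():
            out[:, cols] = means[cols]
            continue
        known = idx[obs]
        for c in range(cols.start, cols.stop):
            # np.interp clamps to edge values: trailing gaps become forward
            # fill automatically; leading gaps are overridden with the mean
            out[:, c] = np.interp(idx, known, traj.values[known, c])
        first = known[0]
        out[:first, cols] = means[cols]
        out[known[0]:known[0] + 1, cols] = traj.values[known[0]:known[0] + 1, cols]
    return out


def fill_matrix(
    traj: SubjectTrajectory, means: np.ndarray, strategy: str
) -> np.ndarray:
    """Dispatch on strategy name; "model" defers filling to the forward pass
    and only mean-fills here so the first timepoint is dense."""
    if strategy == "forward":
        return forward_fill(traj, means)
    if strategy == "linear":
        return linear_fill(traj, means)
    if strategy == "model":
        return traj.values.copy()  # filled inside the recurrent forward pass
    raise ValueError(f"unknown fill strategy {strategy!r}; choose from {FILL_STRATEGIES}")
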