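"""Static baselines: constant prediction and the SVM/SVR horizon grid.

The constant baseline repeats each variable's last observed value at every
future month and needs no training.  The SVM/SVR harness adapts static
models to longitudinal forecasting: separate models per target variable
(diagnosis via SVM, ADAS-Cog13 and ventricles/ICV via SVR), per number of
input timepoints (1-4, spaced 6 months apart, features concatenated) and
per horizon (6, 12, ..., 60 months) — a 3 x 4 x 10 = 120-model grid.
Intermediate months are linearly interpolated and months beyond 60 are
forward-filled.  A test subject lacking the requested number of input
timepoints falls back to the largest grid column it can support, so test
sets stay identical across algorithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR

from .cohort import Cohort, NormStats, SubjectTrajectory, build_monthly_grid
from .filling import linear_fill
from .schema import DEFAULT_SCHEMA, FeatureSchema

__all__ = [
    "constant_forecast",
    "SvmGridSpec",
    "SvmHyperparams",
    "build_design_vector",
    "enumerate_training_samples",
    "SvmGrid",
    "fit_svm_grid",
    "svm_forecast",
]

SVM_TARGETS = ("diagnosis", "adas13", "ventricles")
SVM_K_INPUTS = (1, 2, 3, 4)
SVM_HORIZONS = tuple(range(6, 61, 6))  # months
_STEP = 6  # months between SVM input timepoints


# ---------------------------------------------------------------------------
# constant baseline
# ---------------------------------------------------------------------------

def constant_forecast(
    input_traj: SubjectTrajectory,
    horizon_months: int,
    fallback_means: np.ndarray,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Repeat the last observed value of every variable at all future months.

    Operates on natural (unnormalized) values.  Diagnosis becomes a
    degenerate probability vector on the last observed label; a variable
    never observed in the input falls back to the training mean.  A horizon
    of zero yields an empty forecast.
    """
    if horizon_months < 0:
        raise ValueError("horizon must be nonnegative")
    last_month = int(input_traj.grid_months[-1])
    months = np.arange(last_month + 1, last_month + horizon_months + 1)

    dx_idx = np.nonzero(input_traj.visit_observed[:, 0])[0]
    if len(dx_idx):
        probs = input_traj.visit_values[dx_idx[-1], :3]
    else:
        probs = np.asarray(fallback_means[:3], dtype=float)
        probs = probs / probs.sum()
    cont = np.empty(schema.n_continuous)
    for j in range(schema.n_continuous):
        idx = np.nonzero(input_traj.visit_observed[:, 1 + j])[0]
        cont[j] = (
            input_traj.visit_values[idx[-1], 3 + j]
            if len(idx)
            else fallback_means[3 + j]
        )

    df = pd.DataFrame({
        "subject_id": input_traj.subject_id,
        "month": months,
        "p_NC": probs[0],
        "p_MCI": probs[1],
        "p_AD": probs[2],
    })
    for j, name in enumerate(schema.continuous_names):
        df[name] = cont[j]
    df["adas13"] = cont[schema.continuous_index("ADAS13")]
    df["ventricles_icv"] = (
        cont[schema.continuous_index("Ventricles")]
        / cont[schema.continuous_index("ICV")]
    )
    return df


# ---------------------------------------------------------------------------
# SVM/SVR harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SvmGridSpec:
    """The (target, input-timepoints, horizon) model grid — 120 cells."""

    targets: tuple[str, ...] = SVM_TARGETS
    k_inputs: tuple[int, ...] = SVM_K_INPUTS
    horizons: tuple[int, ...] = SVM_HORIZONS

    def cells(self):
        for target in self.targets:
            for k in self.k_inputs:
                for h in self.horizons:
                    yield target, k, h

    @property
    def n_models(self) -> int:
        return len(self.targets) * len(self.k_inputs) * len(self.horizons)


@dataclass(frozen=True)
class SvmHyperparams:
    """Search-space defaults: kernel linear/RBF, penalty, gamma, epsilon."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    epsilon: float = 0.1  # SVR only
    seed: int = 0


def build_design_vector(grid_values: np.ndarray, k_input: int, end_slot: int) -> np.ndarray:
    """Concatenate the 23 per-timepoint features over ``k_input`` slots.

    ``grid_values`` is a dense (S, 25) 6-month-grid matrix; the window covers
    slots end_slot-k+1..end_slot, oldest first.  One-hot diagnosis counts as
    a single variable, so each timepoint contributes 23 numbers and the
    vector has length 23 * k_input.
    """
    if end_slot - k_input + 1 < 0:
        raise ValueError("window extends before the first timepoint")
    parts = []
    for s in range(end_slot - k_input + 1, end_slot + 1):
        row = grid_values[s]
        dx_scalar = float(np.argmax(row[:3]))  # NC=0, MCI=1, AD=2 ordinal code
        parts.append(np.concatenate([[dx_scalar], row[3:]]))
    return np.concatenate(parts)


def enumerate_training_samples(
    n_timepoints: int, k_input: int, horizon_steps: int
) -> list[tuple[int, int]]:
    """All (window-end slot, target slot) pairs at exactly ``horizon_steps``.

    For v timepoints on the 6-month schedule the count is
    max(0, v - (k-1) - h): a 10-visit subject yields 9/8/7 one-timepoint
    samples at 6/12/18-month horizons.
    """
    out = []
    for end in range(k_input - 1, n_timepoints):
        tgt = end + horizon_steps
        if tgt < n_timepoints:
            out.append((end, tgt))
    return out


def _six_month_grid(traj: SubjectTrajectory, means: np.ndarray):
    """(linear-filled dense matrix, gridded trajectory) on the 6-month grid."""
    g6 = build_monthly_grid(
        traj.visit_months, traj.visit_values, traj.visit_observed,
        resolution=_STEP, subject_id=traj.subject_id,
    )
    return linear_fill(g6, means), g6


@dataclass
class SvmGrid:
    """Fitted model grid plus the scaling needed to decode predictions."""

    models: dict[tuple[str, int, int], object]
    target_scale: dict[tuple[str, int, int], tuple[float, float]]
    classes: dict[tuple[str, int, int], np.ndarray]
    spec: SvmGridSpec
    fallback_means: np.ndarray

    def available_k(self, target: str, k_requested: int) -> list[int]:
        ks = sorted(
            {k for (t, k, _h), m in self.models.items() if t == target and m is not None}
        )
        return [k for k in ks if k <= k_requested]


def _target_value(
    g6: SubjectTrajectory, s: int, target: str, schema: FeatureSchema,
    stats: NormStats,
):
    """Observed target at 6-month slot ``s`` of a gridded subject, or None.

    Targets are actual observations (visits mapped to the slot), never
    interpolated values; the ventricle target is the natural-unit
    ventricles/ICV ratio even though the design matrix is z-normalized.
    """
    if s >= g6.n_timepoints:
        return None
    if target == "diagnosis":
        if not g6.observed[s, 0]:
            return None
        return int(np.argmax(g6.values[s, :3]))
    if target == "adas13":
        j = schema.continuous_index("ADAS13")
        return float(g6.values[s, 3 + j]) if g6.observed[s, 1 + j] else None
    vent = schema.continuous_index("Ventricles")
    icv = schema.continuous_index("ICV")
    if g6.observed[s, 1 + vent] and g6.observed[s, 1 + icv]:
        v_nat = g6.values[s, 3 + vent] * stats.sd[vent] + stats.mean[vent]
        i_nat = g6.values[s, 3 + icv] * stats.sd[icv] + stats.mean[icv]
        return float(v_nat / i_nat)
    return None


def fit_svm_grid(
    train_cohort: Cohort,
    fallback_means: np.ndarray,
    stats: NormStats,
    spec: SvmGridSpec = SvmGridSpec(),
    hp: SvmHyperparams = SvmHyperparams(),
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> SvmGrid:
    """Fit the 120-cell grid on a z-normalized, linear-filled training cohort.

    Design matrices use all available timepoints of every training subject;
    targets are observed values only.  A grid cell with no training samples
    (or a single diagnosis class) is marked unavailable.
    """
    grids = {}
    for s in train_cohort:
        filled, g6 = _six_month_grid(s, fallback_means)
        grids[s.subject_id] = (filled, g6, s)

    models: dict[tuple[str, int, int], object] = {}
    scales: dict[tuple[str, int, int], tuple[float, float]] = {}
    classes: dict[tuple[str, int, int], np.ndarray] = {}
    for target, k, h in spec.cells():
        h_steps = h // _STEP
        X, y = [], []
        for filled, g6, s in grids.values():
            for end, tgt_slot in enumerate_training_samples(
                g6.n_timepoints, k, h_steps
            ):
                val = _target_value(g6, tgt_slot, target, schema, stats)
                if val is None:
                    continue
                X.append(build_design_vector(filled, k, end))
                y.append(val)
        key = (target, k, h)
        if not X:
            models[key] = None
            continue
        X = np.array(X)
        y = np.array(y)
        if target == "diagnosis":
            if len(np.unique(y)) < 2:
                models[key] = None
                continue
            clf = SVC(
                kernel=hp.kernel, C=hp.C, gamma=hp.gamma,
                probability=True, random_state=hp.seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                clf.fit(X, y.astype(int))
            models[key] = clf
            classes[key] = clf.classes_
        else:
            mu, sd = float(y.mean()), float(y.std())
            sd = sd if sd > 0 else 1.0
            reg = SVR(kernel=hp.kernel, C=hp.C, gamma=hp.gamma, epsilon=hp.epsilon)
            reg.fit(X, (y - mu) / sd)
            models[key] = reg
            scales[key] = (mu, sd)
    return SvmGrid(
        models=models, target_scale=scales, classes=classes, spec=spec,
        fallback_means=fallback_means,
    )


def _predict_cell(grid: SvmGrid, key, x: np.ndarray):
    model = grid.models.get(key)
    if model is None:
        return None
    if key[0] == "diagnosis":
        p = model.predict_proba(x[None, :])[0]
        full = np.zeros(3)
        full[grid.classes[key].astype(int)] = p
        return full
    mu, sd = grid.target_scale[key]
    return float(model.predict(x[None, :])[0] * sd + mu)


def svm_forecast(
    grid: SvmGrid,
    input_traj: SubjectTrajectory,
    horizon_months: int,
    k_requested: int,
    stats: NormStats,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Forecast one subject from the fitted grid.

    Predictions are made at +6, +12, ..., +60 months from the last input
    timepoint, linearly interpolated to monthly resolution, and
    forward-filled beyond month 60.  If the subject has fewer than
    ``k_requested`` input timepoints the largest feasible grid column is
    used instead.  ``input_traj`` must be z-normalized; ADAS predictions are
    mapped back to natural units via ``stats``.
    """
    if horizon_months <= 0:
        raise ValueError("forecast horizon must be positive")
    filled, g6 = _six_month_grid(input_traj, grid.fallback_means)
    n_slots = g6.n_timepoints
    end = n_slots - 1
    preds: dict[str, dict[int, object]] = {t: {} for t in SVM_TARGETS}
    for target in grid.spec.targets:
        ks = [k for k in grid.available_k(target, k_requested) if k <= n_slots]
        k_use = max(ks) if ks else None
        for h in grid.spec.horizons:
            if k_use is None:
                break
            val = _predict_cell(grid, (target, k_use, h), build_design_vector(filled, k_use, end))
            if val is not None:
                preds[target][h] = val

    last_month = int(input_traj.grid_months[-1])
    out_m = np.arange(last_month + 1, last_month + horizon_months + 1)
    rel = out_m - last_month

    # anchors at relative month 0: last filled input values
    adas_j = schema.continuous_index("ADAS13")
    vent_j = schema.continuous_index("Ventricles")
    icv_j = schema.continuous_index("ICV")
    anchor_probs = filled[end, :3]
    anchor_adas = float(filled[end, 3 + adas_j])
    vent_nat = filled[end, 3 + vent_j] * stats.sd[vent_j] + stats.mean[vent_j]
    icv_nat = filled[end, 3 + icv_j] * stats.sd[icv_j] + stats.mean[icv_j]
    anchor_vent = float(vent_nat / icv_nat)

    def interp_series(points: dict[int, float], anchor: float) -> np.ndarray:
        if not points:
            return np.full(len(rel), anchor)
        xs = np.array([0] + sorted(points))
        ys = np.array([anchor] + [points[h] for h in sorted(points)])
        return np.interp(rel, xs, ys)  # clamps past month 60: forward fill

    probs_pts = preds["diagnosis"]
    if probs_pts:
        xs = np.array([0] + sorted(probs_pts))
        mat = np.vstack([anchor_probs] + [probs_pts[h] for h in sorted(probs_pts)])
        probs = np.stack([np.interp(rel, xs, mat[:, c]) for c in range(3)], axis=1)
        probs = probs / probs.sum(axis=1, keepdims=True)
    else:
        probs = np.tile(anchor_probs / max(anchor_probs.sum(), 1e-12), (len(rel), 1))

    adas_z = interp_series(preds["adas13"], anchor_adas)
    adas = adas_z * stats.sd[adas_j] + stats.mean[adas_j]
    vent = interp_series(preds["ventricles"], anchor_vent)

    return pd.DataFrame({
        "subject_id": input_traj.subject_id,
        "month": out_m,
        "p_NC": probs[:, 0],
        "p_MCI": probs[:, 1],
        "p_AD": probs[:, 2],
        "adas13": adas,
        "ventricles_icv": vent,
    })
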