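"""Longitudinal data model: monthly grids, masks, normalization, splits, CSV I/O.

A cohort is a set of subject trajectories.  Each trajectory keeps two views
of the same subject: the original visit record (possibly off-schedule,
fractional months) and a regular monthly grid (1-, 3- or 6-month spacing)
onto which each visit is assigned to its nearest slot.  Values live in a
T x 25 matrix (3 one-hot diagnosis columns + 22 continuous markers) with a
T x 23 boolean observation mask (diagnosis counted once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, DX, DX_LABELS, FeatureSchema, SchemaError

__all__ = [
    "SubjectTrajectory",
    "Cohort",
    "NormStats",
    "SplitPlan",
    "ParseError",
    "ConfigurationError",
    "one_hot_diagnosis",
    "diagnosis_from_onehot",
    "build_monthly_grid",
    "trajectory_from_visits",
    "read_cohort",
    "write_cohort",
    "read_tadpole",
    "fit_norm_stats",
    "znormalize",
    "denormalize",
    "make_split_plan",
]


class ParseError(ValueError):
    """Raised when a CSV cell cannot be parsed, with its row index."""


class ConfigurationError(ValueError):
    """Raised for infeasible split/experiment configurations."""


def one_hot_diagnosis(label: str | None) -> np.ndarray | None:
    """Encode a diagnosis label as a length-3 one-hot vector.

    NC -> (1,0,0), MCI -> (0,1,0), AD -> (0,0,1).  A missing label (None or
    NaN) returns None: the entry is masked rather than encoded.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return None
    try:
        idx = DX_LABELS.index(label)
    except ValueError:
        raise ValueError(
            f"diagnosis label {label!r} not in {DX_LABELS}"
        ) from None
    vec = np.zeros(3)
    vec[idx] = 1.0
    return vec


def diagnosis_from_onehot(vec: np.ndarray) -> str:
    """Inverse of :func:`one_hot_diagnosis` (argmax for soft vectors)."""
    return DX_LABELS[int(np.argmax(vec))]


@dataclass
class SubjectTrajectory:
    """One subject: original visit record plus its regular monthly grid.

    grid_months are multiples of ``resolution`` from 0 through the last
    (rounded) visit.  ``values`` holds NaN wherever ``observed`` is False.
    """

    subject_id: str
    grid_months: np.ndarray  # (T,) int
    values: np.ndarray  # (T, 25) float, NaN where unobserved
    observed: np.ndarray  # (T, 23) bool
    visit_months: np.ndarray  # (V,) float, relative to first visit
    visit_values: np.ndarray  # (V, 25)
    visit_observed: np.ndarray  # (V, 23)
    resolution: int = 1

    @property
    def n_timepoints(self) -> int:
        return len(self.grid_months)

    @property
    def n_visits(self) -> int:
        return len(self.visit_months)

    def validate(self, schema: FeatureSchema = DEFAULT_SCHEMA) -> None:
        T = self.n_timepoints
        assert self.values.shape == (T, schema.n_values)
        assert self.observed.shape == (T, schema.n_features)
        assert np.all(np.diff(self.grid_months) == self.resolution)
        # one-hot diagnosis sums to 1 where observed; masked values are NaN
        dx_obs = self.observed[:, 0]
        if dx_obs.any():
            np.testing.assert_allclose(
                self.values[dx_obs, :3].sum(axis=1), 1.0, atol=1e-9
            )
        cont = self.values[:, 3:]
        cont_obs = self.observed[:, 1:]
        assert np.all(np.isfinite(cont[cont_obs]))

    def dx_label_at(self, grid_index: int) -> str | None:
        if not self.observed[grid_index, 0]:
            return None
        return diagnosis_from_onehot(self.values[grid_index, :3])


def build_monthly_grid(
    visit_months: np.ndarray,
    visit_values: np.ndarray,
    visit_observed: np.ndarray,
    resolution: int = 1,
    subject_id: str = "",
) -> SubjectTrajectory:
    """Assign visits to a regular grid of ``resolution``-month slots.

    Slots run from month 0 through the last visit's nearest slot; each visit
    goes to its nearest slot and unassigned slots are fully masked.  When two
    visits land on the same slot, each observed feature is taken from the
    visit nearer the slot centre (ties: the earlier visit); features observed
    in only one of the colliding visits are merged, preserving maximal data.
    """
    if resolution not in (1, 3, 6):
        raise ValueError(f"resolution must be 1, 3 or 6 months, got {resolution}")
    if len(visit_months) == 0:
        raise ValueError("at least one visit is required")
    order = np.argsort(visit_months, kind="stable")
    visit_months = np.asarray(visit_months, dtype=float)[order]
    visit_values = np.asarray(visit_values, dtype=float)[order]
    visit_observed = np.asarray(visit_observed, dtype=bool)[order]

    slots = np.rint(visit_months / resolution).astype(int)
    n_slots = int(slots.max()) + 1
    T = n_slots
    n_vals = visit_values.shape[1]
    n_feat = visit_observed.shape[1]
    values = np.full((T, n_vals), np.nan)
    observed = np.zeros((T, n_feat), dtype=bool)
    # distance of the visit currently providing each (slot, feature)
    dist = np.full((T, n_feat), np.inf)

    for v in range(len(visit_months)):
        s = slots[v]
        d = abs(visit_months[v] - s * resolution)
        for f in np.nonzero(visit_observed[v])[0]:
            # strict '<' keeps the earlier visit on exact ties
            if d < dist[s, f]:
                dist[s, f] = d
                observed[s, f] = True
                if f == 0:
                    values[s, :3] = visit_values[v, :3]
                else:
                    values[s, 2 + f] = visit_values[v, 2 + f]

    return SubjectTrajectory(
        subject_id=subject_id,
        grid_months=np.arange(T) * resolution,
        values=values,
        observed=observed,
        visit_months=visit_months,
        visit_values=visit_values,
        visit_observed=visit_observed,
        resolution=resolution,
    )


def trajectory_from_visits(
    subject_id: str,
    months: np.ndarray,
    values: np.ndarray,
    observed: np.ndarray,
    resolution: int = 1,
) -> SubjectTrajectory:
    """Build a trajectory from raw visits; the first visit defines month 0."""
    months = np.asarray(months, dtype=float)
    rel = months - months.min()
    return build_monthly_grid(rel, values, observed, resolution, subject_id)


@dataclass
class Cohort:
    """A set of subject trajectories sharing one feature schema."""

    subjects: list[SubjectTrajectory]
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subset(self, ids) -> "Cohort":
        wanted = set(ids)
        return Cohort(
            [s for s in self.subjects if s.subject_id in wanted],
            schema=self.schema,
            normalized=self.normalized,
        )

    def regrid(self, resolution: int) -> "Cohort":
        """Rebuild every subject's grid at a new temporal resolution."""
        subs = [
            build_monthly_grid(
                s.visit_months, s.visit_values, s.visit_observed,
                resolution, s.subject_id,
            )
            for s in self.subjects
        ]
        return Cohort(subs, schema=self.schema, normalized=self.normalized)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _visits_from_frame(df: pd.DataFrame, schema: FeatureSchema, resolution: int) -> Cohort:
    cont_names = list(schema.continuous_names)
    expected = {"subject_id", "month", DX, *cont_names}
    unknown = set(df.columns) - expected
    if unknown:
        raise SchemaError(f"unknown columns: {sorted(unknown)}")
    missing = expected - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")

    subjects: list[SubjectTrajectory] = []
    for sid, g in sorted(df.groupby("subject_id", sort=True), key=lambda kv: str(kv[0])):
        months, vals, obs = [], [], []
        for idx, row in g.iterrows():
            vec = np.full(schema.n_values, np.nan)
            mask = np.zeros(schema.n_features, dtype=bool)
            dx_raw = row[DX]
            if isinstance(dx_raw, str) and dx_raw.strip():
                vec[:3] = one_hot_diagnosis(dx_raw.strip())
                mask[0] = True
            for j, name in enumerate(cont_names):
                cell = row[name]
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    continue
                if isinstance(cell, str):
                    if not cell.strip():
                        continue
                    try:
                        cell = float(cell)
                    except ValueError:
                        raise ParseError(
                            f"non-numeric value {cell!r} for {name} at row {idx}"
                        ) from None
                vec[3 + j] = float(cell)
                mask[1 + j] = True
            if not mask.any():
                continue  # rows with no observed variables are dropped
            months.append(float(row["month"]))
            vals.append(vec)
            obs.append(mask)
        if not months:
            continue
        subjects.append(
            trajectory_from_visits(
                str(sid), np.array(months), np.array(vals), np.array(obs), resolution
            )
        )
    return Cohort(subjects, schema=schema)


def read_cohort(
    path, schema: FeatureSchema = DEFAULT_SCHEMA, resolution: int = 1
) -> Cohort:
    """Read a long-format CSV (`subject_id, month, DX, <markers>`) into a Cohort.

    Empty cells mean missing.  Diagnosis labels must be NC/MCI/AD.  Rows with
    no observed variables at all are dropped; subjects are sorted by ID.
    """
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, DX: str})
    except pd.errors.EmptyDataError:
        return Cohort([], schema=schema)
    if df.empty:
        return Cohort([], schema=schema)
    return _visits_from_frame(df, schema, resolution)


def write_cohort(cohort: Cohort, path) -> None:
    """Serialize the original visit records back to the long CSV dialect."""
    schema = cohort.schema
    rows = []
    for s in sorted(cohort.subjects, key=lambda s: s.subject_id):
        for v in range(s.n_visits):
            row: dict[str, object] = {
                "subject_id": s.subject_id,
                "month": s.visit_months[v],
            }
            row[DX] = (
                diagnosis_from_onehot(s.visit_values[v, :3])
                if s.visit_observed[v, 0]
                else ""
            )
            for j, name in enumerate(schema.continuous_names):
                row[name] = (
                    s.visit_values[v, 3 + j] if s.visit_observed[v, 1 + j] else ""
                )
            rows.append(row)
    cols = ["subject_id", "month", DX, *schema.continuous_names]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


_TADPOLE_DX = {
    "NL": "NC", "CN": "NC", "NC": "NC",
    "MCI": "MCI", "LMCI": "MCI", "EMCI": "MCI",
    "Dementia": "AD", "AD": "AD",
    # late conversion labels collapse onto the destination state
    "NL to MCI": "MCI", "MCI to Dementia": "AD", "MCI to NL": "NC",
    "Dementia to MCI": "MCI", "NL to Dementia": "AD",
}


def read_tadpole(
    path,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    column_map: dict[str, str] | None = None,
    resolution: int = 1,
) -> Cohort:
    """Thin column-mapping reader for the TADPOLE spreadsheet dialect.

    Maps `RID` -> subject_id, `Month_bl` -> month and translates ADNI
    diagnosis strings (NL/MCI/Dementia and conversion labels) onto NC/MCI/AD.
    ``column_map`` may supply extra {tadpole_name: schema_name} renames for
    the marker columns.
    """
    df = pd.read_csv(path, dtype={"RID": str})
    renames = {"RID": "subject_id", "Month_bl": "month"}
    if column_map:
        renames.update(column_map)
    df = df.rename(columns=renames)
    df = df[[c for c in df.columns if c in {"subject_id", "month", DX, *schema.continuous_names}]]
    df[DX] = df[DX].map(lambda x: _TADPOLE_DX.get(x, x) if isinstance(x, str) else x)
    return _visits_from_frame(df, schema, resolution)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormStats:
    """Per-marker mean/sd estimated on training subjects' observed entries."""

    mean: np.ndarray  # (22,)
    sd: np.ndarray  # (22,)

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("normalization sd must be positive for every feature")


def fit_norm_stats(train_cohort: Cohort) -> NormStats:
    """Pooled mean/sd of each continuous marker over observed training entries."""
    schema = train_cohort.schema
    n = schema.n_continuous
    mean = np.zeros(n)
    sd = np.zeros(n)
    for j in range(n):
        vals = np.concatenate(
            [s.visit_values[s.visit_observed[:, 1 + j], 3 + j] for s in train_cohort]
            or [np.array([])]
        )
        if vals.size == 0:
            raise ValueError(
                f"feature {schema.continuous_names[j]!r} never observed in training set"
            )
        mean[j] = vals.mean()
        s_ = vals.std()
        if s_ == 0:
            raise ValueError(
                f"feature {schema.continuous_names[j]!r} is constant in the training set"
            )
        sd[j] = s_
    return NormStats(mean=mean, sd=sd)


def _transform(cohort: Cohort, stats: NormStats, forward: bool) -> Cohort:
    def tf(mat: np.ndarray) -> np.ndarray:
        out = mat.copy()
        if forward:
            out[:, 3:] = (out[:, 3:] - stats.mean) / stats.sd
        else:
            out[:, 3:] = out[:, 3:] * stats.sd + stats.mean
        return out

    subs = [
        replace(s, values=tf(s.values), visit_values=tf(s.visit_values))
        for s in cohort.subjects
    ]
    return Cohort(subs, schema=cohort.schema, normalized=forward)


def znormalize(cohort: Cohort, stats: NormStats) -> Cohort:
    """z-score the continuous markers; diagnosis columns and masks untouched."""
    return _transform(cohort, stats, forward=True)


def denormalize(cohort: Cohort, stats: NormStats) -> Cohort:
    """Inverse of :func:`znormalize`."""
    return _transform(cohort, stats, forward=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """One repeat of the 18:1:1 subject split with disjoint test blocks.

    ``n_input_visits`` gives, for every validation/test subject, how many of
    its (chronologically ordered) visits serve as model input; the remaining
    visits are forecasting targets.
    """

    repeat: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    n_input_visits: dict[str, int]


def _half_split(n_visits: int) -> int:
    # ceil(V/2) visits are input; single-visit subjects contribute no targets
    return (n_visits + 1) // 2


def make_split_plan(cohort: Cohort, n_repeats: int = 20, seed: int = 0) -> list[SplitPlan]:
    """Repeated 18:1:1 subject splits whose test blocks tile the cohort.

    Subject IDs are permuted once by ``seed`` and partitioned into
    ``n_repeats`` disjoint test blocks; per repeat the remaining subjects are
    split 18:1 into train and validation.  Validation/test subjects use the
    first half (ceil) of their visits as input and the rest as targets.
    """
    ids = sorted(cohort.subject_ids)
    n = len(ids)
    if n_repeats < 1 or n < 2 * n_repeats:
        raise ConfigurationError(
            f"cohort of {n} subjects cannot support {n_repeats} disjoint test blocks"
        )
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    blocks = np.array_split(np.arange(n), n_repeats)
    visits = {s.subject_id: s.n_visits for s in cohort}

    plans = []
    for r, block in enumerate(blocks):
        test = tuple(perm[i] for i in block)
        rest = [sid for sid in perm if sid not in set(test)]
        n_val = max(1, round(len(rest) / 19))
        # deterministic per-repeat shuffle of the non-test subjects
        sub_rng = np.random.default_rng([seed, r])
        rest = [rest[i] for i in sub_rng.permutation(len(rest))]
        val = tuple(rest[:n_val])
        train = tuple(rest[n_val:])
        n_input = {sid: _half_split(visits[sid]) for sid in (*val, *test)}
        plans.append(
            SplitPlan(
                repeat=r,
                train_ids=train,
                val_ids=val,
                test_ids=test,
                n_input_visits=n_input,
            )
        )
    return plans


def split_input_target(
    traj: SubjectTrajectory, n_input: int
) -> tuple[SubjectTrajectory, SubjectTrajectory | None]:
    """Split a subject into an input trajectory and a target trajectory.

    The first ``n_input`` visits become the input trajectory (re-gridded from
    its own first visit); the remaining visits are returned as targets with
    months kept relative to the input's month-0 origin.  Returns
    (input_traj, None) when there are no target visits.
    """
    V = traj.n_visits
    n_input = min(max(1, n_input), V)
    inp = build_monthly_grid(
        traj.visit_months[:n_input],
        traj.visit_values[:n_input],
        traj.visit_observed[:n_input],
        traj.resolution,
        traj.subject_id,
    )
    if n_input == V:
        return inp, None
    tgt = SubjectTrajectory(
        subject_id=traj.subject_id,
        grid_months=traj.grid_months,
        values=traj.values,
        observed=traj.observed,
        visit_months=traj.visit_months[n_input:],
        visit_values=traj.visit_values[n_input:],
        visit_observed=traj.visit_observed[n_input:],
        resolution=traj.resolution,
    )
    return inp, tgt
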