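"""TADPOLE-style scoring: mAUC, BCA, MAE, breakdowns and paired testing.

Diagnosis classification is scored with the multiclass AUC (mean of the
three one-vs-rest two-class AUCs, using each class's predicted probability
as the ranking score, ties counting one half) and balanced class accuracy
(mean over classes of (sensitivity + specificity)/2 on hard argmax
assignments).  Continuous targets are scored with mean absolute error over
observed future entries only; ventricular volume is scored as a fraction of
intracranial volume.  Model comparison across repeated random splits uses
the corrected resampled t-test, whose variance term is inflated by
(1/K + n_test/n_train) to account for overlapping training sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, SubjectTrajectory, diagnosis_from_onehot
from .schema import DEFAULT_SCHEMA, DX_LABELS, FeatureSchema

__all__ = [
    "mauc",
    "bca",
    "mae",
    "corrected_resampled_ttest",
    "fdr_adjust",
    "evaluate_forecasts",
    "group_breakdown",
    "yearly_breakdown",
    "EvalReport",
]


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Rank-based two-class AUC; tied scores contribute one half."""
    ranks = sstats.rankdata(scores)  # average ranks on ties
    n_pos = int(positives.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    return float(
        (ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def mauc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Multiclass AUC: unweighted mean of the three one-vs-rest AUCs.

    ``probs`` is (n, 3) with rows on the simplex; ``labels`` holds true class
    indices 0/1/2.  A class absent from the labels has an undefined AUC and
    is dropped from the mean with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    aucs = []
    for c in range(probs.shape[1]):
        auc = _binary_auc(probs[:, c], labels == c)
        if np.isnan(auc):
            warnings.warn(
                f"class {DX_LABELS[c]} absent from labels; its AUC is undefined",
                stacklevel=2,
            )
        else:
            aucs.append(auc)
    return float(np.mean(aucs))


def bca(pred_labels: np.ndarray, labels: np.ndarray, n_classes: int = 3) -> float:
    """Balanced class accuracy: mean over classes of (sens + spec) / 2."""
    pred_labels = np.asarray(pred_labels)
    labels = np.asarray(labels)
    vals = []
    for c in range(n_classes):
        pos = labels == c
        if not pos.any():
            warnings.warn(
                f"class {DX_LABELS[c]} absent from labels; skipped in BCA",
                stacklevel=2,
            )
            continue
        neg = ~pos
        sens = np.mean(pred_labels[pos] == c)
        spec = np.mean(pred_labels[neg] != c) if neg.any() else np.nan
        vals.append((sens + spec) / 2.0 if np.isfinite(spec) else sens)
    return float(np.mean(vals))


def mae(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error over aligned observed entries."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0:
        return np.nan
    return float(np.mean(np.abs(pred - truth)))


def corrected_resampled_ttest(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_train: int,
    n_test: int,
) -> tuple[float, float]:
    """Paired comparison across K repeated splits with overlap correction.

    t = mean(d) / sqrt((1/K + n_test/n_train) * var(d)), var with K-1
    denominator; two-sided p from Student's t with K-1 degrees of freedom.
    As n_test/n_train -> 0 this reduces to the classical paired t-test.
    """
    d = np.asarray(scores_a, dtype=float) - np.asarray(scores_b, dtype=float)
    K = len(d)
    if K < 2:
        raise ValueError("need at least two paired scores")
    var = d.var(ddof=1)
    mean = d.mean()
    if var == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        warnings.warn("zero variance with nonzero mean difference", stacklevel=2)
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / np.sqrt((1.0 / K + n_test / n_train) * var)
    p = 2.0 * sstats.t.sf(abs(t), df=K - 1)
    return float(t), float(p)


def fdr_adjust(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at false discovery rate ``q``."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# forecast-vs-truth alignment
# ---------------------------------------------------------------------------

def _target_rows(
    forecasts: pd.DataFrame,
    test_pairs: list[tuple[SubjectTrajectory, SubjectTrajectory | None]],
    schema: FeatureSchema,
):
    """Yield per observed target visit: subject, month offset, truth, preds.

    ``test_pairs`` holds (input_traj, target_traj) from the split; target
    visit months are rounded to integer months and matched against the
    forecast table.  Subjects without targets are skipped (excluded from
    metric denominators).
    """
    vent = schema.continuous_index("Ventricles")
    icv = schema.continuous_index("ICV")
    adas = schema.continuous_index("ADAS13")
    fc = {sid: g.set_index("month") for sid, g in forecasts.groupby("subject_id")}
    for inp, tgt in test_pairs:
        if tgt is None or inp.subject_id not in fc:
            continue
        sub_fc = fc[inp.subject_id]
        last_input_month = int(inp.grid_months[-1])
        for v in range(tgt.n_visits):
            month = int(round(tgt.visit_months[v]))
            if month <= last_input_month or month not in sub_fc.index:
                continue
            row = sub_fc.loc[month]
            truth_dx = (
                int(np.argmax(tgt.visit_values[v, :3]))
                if tgt.visit_observed[v, 0]
                else None
            )
            truth_adas = (
                float(tgt.visit_values[v, 3 + adas])
                if tgt.visit_observed[v, 1 + adas]
                else None
            )
            truth_vent = None
            if tgt.visit_observed[v, 1 + vent] and tgt.visit_observed[v, 1 + icv]:
                truth_vent = float(
                    tgt.visit_values[v, 3 + vent] / tgt.visit_values[v, 3 + icv]
                )
            yield {
                "subject_id": inp.subject_id,
                "offset": month - last_input_month,
                "probs": row[["p_NC", "p_MCI", "p_AD"]].to_numpy(dtype=float),
                "pred_adas": float(row["adas13"]),
                "pred_vent": float(row["ventricles_icv"]),
                "truth_dx": truth_dx,
                "truth_adas": truth_adas,
                "truth_vent": truth_vent,
            }


def _score_rows(rows: list[dict]) -> dict[str, float]:
    out: dict[str, float] = {}
    dx_rows = [r for r in rows if r["truth_dx"] is not None]
    if dx_rows:
        probs = np.array([r["probs"] for r in dx_rows])
        labels = np.array([r["truth_dx"] for r in dx_rows])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["mauc"] = mauc(probs, labels)
            out["bca"] = bca(np.argmax(probs, axis=1), labels)
        out["dx_accuracy"] = float(np.mean(np.argmax(probs, axis=1) == labels))
        out["n_dx"] = len(dx_rows)
    a_rows = [r for r in rows if r["truth_adas"] is not None]
    if a_rows:
        out["adas_mae"] = mae(
            [r["pred_adas"] for r in a_rows], [r["truth_adas"] for r in a_rows]
        )
        out["n_adas"] = len(a_rows)
    v_rows = [r for r in rows if r["truth_vent"] is not None]
    if v_rows:
        out["vent_mae"] = mae(
            [r["pred_vent"] for r in v_rows], [r["truth_vent"] for r in v_rows]
        )
        out["n_vent"] = len(v_rows)
    return out


def evaluate_forecasts(
    forecasts: pd.DataFrame,
    test_pairs: list[tuple[SubjectTrajectory, SubjectTrajectory | None]],
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> dict[str, float]:
    """Score a forecast table against observed future visits.

    Returns mAUC / BCA over observed future diagnoses and MAE for ADAS-Cog13
    and ventricles/ICV over observed future marker values.
    """
    rows = list(_target_rows(forecasts, test_pairs, schema))
    return _score_rows(rows)


# ---------------------------------------------------------------------------
# breakdowns
# ---------------------------------------------------------------------------

_GROUPS = {
    ("NC", "NC"): "NC-S", ("NC", "MCI"): "NC-P", ("NC", "AD"): "NC-P",
    ("MCI", "NC"): "MCI-R", ("MCI", "MCI"): "MCI-S", ("MCI", "AD"): "MCI-P",
    ("AD", "AD"): "AD",
    # AD reverters are excluded (tiny group)
    ("AD", "MCI"): None, ("AD", "NC"): None,
}


def _last_observed_dx(traj_vals, traj_obs) -> str | None:
    idx = np.nonzero(traj_obs[:, 0])[0]
    if len(idx) == 0:
        return None
    return diagnosis_from_onehot(traj_vals[idx[-1], :3])


def assign_group(
    inp: SubjectTrajectory, tgt: SubjectTrajectory | None
) -> str | None:
    """Stratum from (diagnosis at last input visit, diagnosis at last visit).

    Subjects lacking an observed diagnosis in either half are excluded, as
    are AD reverters.
    """
    if tgt is None:
        return None
    d_in = _last_observed_dx(inp.visit_values, inp.visit_observed)
    d_last = _last_observed_dx(tgt.visit_values, tgt.visit_observed)
    if d_in is None or d_last is None:
        return None
    return _GROUPS.get((d_in, d_last))


def group_breakdown(
    forecasts: pd.DataFrame,
    test_pairs: list[tuple[SubjectTrajectory, SubjectTrajectory | None]],
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> dict[str, dict[str, float]]:
    """Per-stratum metrics for NC-S, NC-P, MCI-R, MCI-S, MCI-P and AD.

    Diagnosis within a stratum is scored by plain accuracy of the argmax
    prediction (single-class strata make mAUC/BCA undefined).
    """
    groups: dict[str, list[dict]] = {}
    members: dict[str, set[str]] = {}
    by_subject: dict[str, tuple] = {p[0].subject_id: p for p in test_pairs}
    rows_by_subject: dict[str, list[dict]] = {}
    for r in _target_rows(forecasts, test_pairs, schema):
        rows_by_subject.setdefault(r["subject_id"], []).append(r)
    for sid, (inp, tgt) in by_subject.items():
        g = assign_group(inp, tgt)
        if g is None:
            continue
        groups.setdefault(g, []).extend(rows_by_subject.get(sid, []))
        members.setdefault(g, set()).add(sid)
    out = {}
    for g, rows in groups.items():
        scores = _score_rows(rows)
        scores["n_subjects"] = len(members[g])
        out[g] = scores
    return out


def yearly_breakdown(
    forecasts: pd.DataFrame,
    test_pairs: list[tuple[SubjectTrajectory, SubjectTrajectory | None]],
    schema: FeatureSchema = DEFAULT_SCHEMA,
    max_years: int = 6,
) -> dict[int, dict[str, float]]:
    """Metrics bucketed by forecast year: months 1-12 are year 1, and so on.

    Empty buckets are absent from the result.
    """
    buckets: dict[int, list[dict]] = {}
    for r in _target_rows(forecasts, test_pairs, schema):
        year = int(np.ceil(r["offset"] / 12.0))
        if 1 <= year <= max_years:
            buckets.setdefault(year, []).append(r)
    return {y: _score_rows(rows) for y, rows in sorted(buckets.items())}


@dataclass
class EvalReport:
    """Aggregated benchmark result across repeated splits."""

    model: str
    strategy: str
    per_split: list[dict[str, float]] = field(default_factory=list)
    groups: dict[str, dict[str, float]] = field(default_factory=dict)
    yearly: dict[int, dict[str, float]] = field(default_factory=dict)
    comparisons: dict[str, dict[str, float]] = field(default_factory=dict)

    def split_vector(self, metric: str) -> np.ndarray:
        return np.array([s.get(metric, np.nan) for s in self.per_split])

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for metric in ("mauc", "bca", "adas_mae", "vent_mae"):
            v = self.split_vector(metric)
            v = v[np.isfinite(v)]
            if v.size:
                out[metric] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "strategy": self.strategy,
            "summary": self.summary(),
            "per_split": self.per_split,
            "groups": self.groups,
            "yearly": {str(k): v for k, v in self.yearly.items()},
            "comparisons": self.comparisons,
        }
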