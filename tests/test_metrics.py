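"""Scoring tests: mAUC vs brute force, BCA, MAE, paired tests, breakdowns."""

import numpy as np
import pytest
from scipy import stats as sstats

import adprog as ap
from adprog.metrics import (
    assign_group,
    bca,
    corrected_resampled_ttest,
    fdr_adjust,
    mae,
    mauc,
    yearly_breakdown,
)
from conftest import make_trajectory


def brute_force_mauc(probs, labels):
    """O(n^2) pairwise-count oracle: ties contribute one half."""
    aucs = []
    for c in range(3):
        pos = np.nonzero(labels == c)[0]
        neg = np.nonzero(labels != c)[0]
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = 0.0
        for i in pos:
            for j in neg:
                if probs[i, c] > probs[j, c]:
                    wins += 1.0
                elif probs[i, c] == probs[j, c]:
                    wins += 0.5
        aucs.append(wins / (len(pos) * len(neg)))
    return float(np.mean(aucs))


class TestMauc:
    def test_perfect_ranking_is_one(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        probs = np.eye(3)[labels] * 0.8 + 0.1
        assert mauc(probs, labels) == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        probs = np.full((6, 3), 1 / 3)
        assert mauc(probs, labels) == pytest.approx(0.5)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 3, n)
            probs = rng.dirichlet(np.ones(3), size=n)
            probs = np.round(probs, 1)  # induce ties
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert mauc(probs, labels) == pytest.approx(
                    brute_force_mauc(probs, labels), abs=1e-12
                )

    def test_agrees_with_sklearn_on_clean_instances(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, 60)
        probs = rng.dirichlet(np.ones(3), size=60)
        expected = np.mean([
            roc_auc_score(labels == c, probs[:, c]) for c in range(3)
        ])
        assert mauc(probs, labels) == pytest.approx(expected, abs=1e-12)

    def test_missing_class_warns_and_averages_rest(self):
        labels = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1, 0], [0.8, 0.2, 0], [0.2, 0.8, 0], [0.1, 0.9, 0]])
        with pytest.warns(UserWarning, match="AD"):
            val = mauc(probs, labels)
        assert val == pytest.approx(1.0)

    def test_label_permutation_is_chance_level(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(3), size=400)
        vals = []
        for _ in range(50):
            labels = rng.integers(0, 3, 400)
            vals.append(mauc(probs, labels))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, 40)
        probs = rng.dirichlet(np.ones(3), size=40)
        perm = rng.permutation(40)
        assert mauc(probs, labels) == pytest.approx(mauc(probs[perm], labels[perm]))


class TestBca:
    def test_all_correct_is_one(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        assert bca(labels, labels) == pytest.approx(1.0)

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, 6000)
        preds = rng.integers(0, 3, 6000)
        assert bca(preds, labels) == pytest.approx(0.5, abs=0.02)

    def test_absent_class_skipped_with_warning(self):
        labels = np.array([0, 0, 1, 1])
        preds = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="AD"):
            assert bca(preds, labels) == pytest.approx(1.0)


class TestMae:
    def test_exact_predictions_zero(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset(self):
        x = np.arange(5, dtype=float)
        assert mae(x + 0.7, x) == pytest.approx(0.7)

    def test_hand_built_average(self):
        assert mae([1, 2, 4, 8], [0, 0, 0, 0]) == pytest.approx(15 / 4)


class TestCorrectedResampledTTest:
    def test_identical_scores(self):
        a = np.full(20, 0.9)
        t, p = corrected_resampled_ttest(a, a, 180, 10)
        assert t == 0.0 and p == 1.0

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.01, 0.02, 20)
        a = np.full(20, 0.9)
        b = a - d
        K, n_train, n_test = 20, 180, 10
        t, p = corrected_resampled_ttest(a, b, n_train, n_test)
        expected_t = d.mean() / np.sqrt((1 / K + n_test / n_train) * d.var(ddof=1))
        expected_p = 2 * sstats.t.sf(abs(expected_t), df=K - 1)
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert p == pytest.approx(expected_p, rel=1e-12)

    def test_reduces_to_classical_paired_ttest(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.9, 0.02, 20)
        b = rng.normal(0.88, 0.02, 20)
        t_corr, p_corr = corrected_resampled_ttest(a, b, n_train=10 ** 9, n_test=1)
        t_ref, p_ref = sstats.ttest_rel(a, b)
        assert t_corr == pytest.approx(t_ref, rel=1e-6)
        assert p_corr == pytest.approx(p_ref, rel=1e-6)

    def test_correction_shrinks_t(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.9, 0.02, 20)
        b = rng.normal(0.87, 0.02, 20)
        t_corr, _ = corrected_resampled_ttest(a, b, 180, 10)
        t_naive, _ = sstats.ttest_rel(a, b)
        assert abs(t_corr) <= abs(t_naive)


class TestFdr:
    def test_single_small_p_rejected(self):
        assert fdr_adjust([0.01]).tolist() == [True]

    def test_all_ones_not_rejected(self):
        assert not fdr_adjust([1.0, 1.0, 1.0]).any()

    def test_matches_manual_step_up(self):
        # thresholds k*q/m = (0.0125, 0.025, 0.0375, 0.05): the largest k
        # with p_(k) <= k*q/m is k = 2, so the two smallest are rejected
        got = fdr_adjust([0.01, 0.02, 0.04, 0.9]).tolist()
        assert got == [True, True, False, False]


def _dx_traj(labels, months, subject_id="G"):
    T = len(labels)
    vals = np.zeros((T, 25))
    obs = np.zeros((T, 23), dtype=bool)
    for t, lab in enumerate(labels):
        if lab is not None:
            vals[t, :3] = ap.one_hot_diagnosis(lab)
            obs[t, 0] = True
    return make_trajectory(vals, obs, months=months, subject_id=subject_id)


class TestGroupAssignment:
    def test_stable_nc(self):
        traj = _dx_traj(["NC", "NC", "NC", "NC"], [0, 6, 12, 18])
        inp, tgt = ap.split_input_target(traj, 2)
        assert assign_group(inp, tgt) == "NC-S"

    def test_mci_progressing_to_ad(self):
        traj = _dx_traj(["MCI", "MCI", "AD", "AD"], [0, 6, 12, 18])
        inp, tgt = ap.split_input_target(traj, 2)
        assert assign_group(inp, tgt) == "MCI-P"

    def test_fluctuating_nc_counts_as_stable(self):
        # NC, NC, MCI, NC with a 2/2 split: both halves end on NC
        traj = _dx_traj(["NC", "NC", "MCI", "NC"], [0, 6, 12, 18])
        inp, tgt = ap.split_input_target(traj, 2)
        assert assign_group(inp, tgt) == "NC-S"

    def test_ad_reverter_excluded(self):
        traj = _dx_traj(["AD", "AD", "MCI", "MCI"], [0, 6, 12, 18])
        inp, tgt = ap.split_input_target(traj, 2)
        assert assign_group(inp, tgt) is None

    def test_missing_diagnosis_half_excluded(self):
        traj = _dx_traj(["NC", "NC", None, None], [0, 6, 12, 18])
        inp, tgt = ap.split_input_target(traj, 2)
        assert assign_group(inp, tgt) is None


class TestYearlyBreakdown:
    def _pairs_and_forecast(self, target_months):
        import pandas as pd
        labels = ["MCI"] * (2 + len(target_months))
        months = [0, 6] + list(target_months)
        traj = _dx_traj(labels, months, subject_id="Y")
        inp, tgt = ap.split_input_target(traj, 2)
        last = int(inp.grid_months[-1])
        horizon = int(max(target_months)) - last
        fc = pd.DataFrame({
            "subject_id": "Y",
            "month": np.arange(last + 1, last + horizon + 1),
            "p_NC": 0.1, "p_MCI": 0.8, "p_AD": 0.1,
            "adas13": 10.0, "ventricles_icv": 0.03,
        })
        return fc, [(inp, tgt)]

    def test_month_boundaries(self):
        fc, pairs = self._pairs_and_forecast([18, 19])
        # last input month 6: months 18 and 19 are offsets 12 and 13
        by_year = yearly_breakdown(fc, pairs)
        assert by_year[1]["n_dx"] == 1
        assert by_year[2]["n_dx"] == 1

    def test_short_followup_leaves_later_years_absent(self):
        fc, pairs = self._pairs_and_forecast([12, 15])
        by_year = yearly_breakdown(fc, pairs)
        assert set(by_year) == {1}


def test_metrics_ignore_changes_at_unobserved_entries(tiny_model, normalized, small_cohort):
    """Perturbing masked values never changes any score."""
    import dataclasses
    norm, _, _ = normalized
    cohort_raw, _ = small_cohort
    raw_by_id = {s.subject_id: s for s in cohort_raw}
    pairs, frames = [], []
    for s in list(norm)[:8]:
        n_in = (s.n_visits + 1) // 2
        inp, tgt = ap.split_input_target(raw_by_id[s.subject_id], n_in)
        if tgt is None:
            continue
        inp_n, _ = ap.split_input_target(s, n_in)
        frames.append(ap.forecast(tiny_model, inp_n, 24))
        pairs.append((inp, tgt))
    import pandas as pd
    fc = pd.concat(frames, ignore_index=True)
    base = ap.evaluate_forecasts(fc, pairs)
    # scramble unobserved truth entries
    rng = np.random.default_rng(0)
    pairs2 = []
    for inp, tgt in pairs:
        vv = tgt.visit_values.copy()
        vm = np.concatenate(
            [np.repeat(tgt.visit_observed[:, :1], 3, 1), tgt.visit_observed[:, 1:]], 1
        )
        vv[~vm] = rng.normal(size=(~vm).sum()) * 100
        pairs2.append((inp, dataclasses.replace(tgt, visit_values=vv)))
    assert ap.evaluate_forecasts(fc, pairs2) == base
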