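"""Data-model tests: CSV I/O, one-hot coding, gridding, normalization, splits."""

import io

import numpy as np
import pandas as pd
import pytest

import adprog as ap
from adprog.cohort import (
    ConfigurationError,
    build_monthly_grid,
    one_hot_diagnosis,
    split_input_target,
)
from adprog.schema import DEFAULT_SCHEMA, SchemaError


def _toy_csv() -> str:
    cols = ["subject_id", "month", "DX", *DEFAULT_SCHEMA.continuous_names]
    rows = []
    for sid in ("A", "B"):
        for m, dx in zip((0, 6, 12), ("NC", "MCI", "AD")):
            row = {c: "" for c in cols}
            row.update(subject_id=sid, month=m, DX=dx, ADAS13=20 + m, MMSE=28 - m / 6)
            rows.append(row)
    return pd.DataFrame(rows, columns=cols).to_csv(index=False)


class TestCsvIO:
    def test_roundtrip_two_subjects(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(_toy_csv())
        cohort = ap.read_cohort(path)
        assert len(cohort) == 2
        assert all(s.n_visits == 3 for s in cohort)
        out = tmp_path / "back.csv"
        ap.write_cohort(cohort, out)
        again = ap.read_cohort(out)
        for s1, s2 in zip(cohort, again):
            assert s1.subject_id == s2.subject_id
            np.testing.assert_allclose(s1.visit_months, s2.visit_months)
            np.testing.assert_array_equal(s1.visit_observed, s2.visit_observed)

    def test_empty_file_gives_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert len(ap.read_cohort(path)) == 0

    def test_bad_diagnosis_label_named_in_error(self, tmp_path):
        text = _toy_csv().replace("MCI", "Dementia")
        path = tmp_path / "bad.csv"
        path.write_text(text)
        with pytest.raises(ValueError, match="Dementia"):
            ap.read_cohort(path)

    def test_unknown_column_is_schema_error(self, tmp_path):
        df = pd.read_csv(io.StringIO(_toy_csv()))
        df["APOE4"] = 1
        path = tmp_path / "extra.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="APOE4"):
            ap.read_cohort(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        df = pd.read_csv(io.StringIO(_toy_csv()))
        df["ADAS13"] = df["ADAS13"].astype(object)
        df.loc[1, "ADAS13"] = "high"
        path = tmp_path / "parse.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="ADAS13"):
            ap.read_cohort(path)

    def test_tadpole_dialect_reader(self, tmp_path):
        df = pd.read_csv(io.StringIO(_toy_csv()))
        df = df.rename(columns={"subject_id": "RID", "month": "Month_bl"})
        df["DX"] = df["DX"].map({"NC": "NL", "MCI": "MCI", "AD": "Dementia"})
        path = tmp_path / "tadpole.csv"
        df.to_csv(path, index=False)
        cohort = ap.read_tadpole(path)
        assert len(cohort) == 2
        assert cohort.subjects[0].dx_label_at(0) == "NC"


class TestOneHot:
    @pytest.mark.parametrize(
        "label,expected",
        [("NC", (1, 0, 0)), ("MCI", (0, 1, 0)), ("AD", (0, 0, 1))],
    )
    def test_encoding(self, label, expected):
        np.testing.assert_array_equal(one_hot_diagnosis(label), expected)

    def test_missing_is_masked(self):
        assert one_hot_diagnosis(None) is None
        assert one_hot_diagnosis(float("nan")) is None

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="Dementia"):
            one_hot_diagnosis("Dementia")


def _visits(months):
    n = len(months)
    vals = np.tile(np.arange(25, dtype=float), (n, 1))
    vals[:, :3] = [1, 0, 0]
    obs = np.ones((n, 23), dtype=bool)
    return np.asarray(months, float), vals, obs


class TestMonthlyGrid:
    def test_identity_grid_resolution_one(self):
        m, v, o = _visits([0, 8])
        traj = build_monthly_grid(m, v, o, 1)
        assert traj.n_timepoints == 9
        assert traj.observed[0].all() and traj.observed[8].all()
        assert not traj.observed[1:8].any()

    def test_nearest_slot_at_coarse_resolution(self):
        # exhaustive nearest-slot arithmetic: month 8 at resolution 6 is
        # nearer slot 1 (distance 2) than slot 0 (distance 8)
        m, v, o = _visits([0, 8])
        traj = build_monthly_grid(m, v, o, 6)
        assert list(traj.grid_months) == [0, 6]
        assert traj.observed[1].all()
        for month in range(0, 25):
            slots = np.arange(0, month // 6 + 2) * 6
            best = np.min(np.abs(slots - month))
            chosen = np.rint(month / 6) * 6
            assert abs(chosen - month) == best  # assigned slot is a nearest one

    def test_month_four_maps_to_slot_six(self):
        m, v, o = _visits([0, 4])
        traj = build_monthly_grid(m, v, o, 6)
        assert list(traj.grid_months) == [0, 6]
        assert traj.observed[1].all()

    def test_grid_roundtrip_preserves_visits(self, small_cohort):
        cohort, _ = small_cohort
        for s in cohort.subjects[:10]:
            rebuilt = build_monthly_grid(
                s.visit_months, s.visit_values, s.visit_observed, 1, s.subject_id
            )
            np.testing.assert_array_equal(rebuilt.observed, s.observed)

    def test_mask_conservation_without_collisions(self):
        m, v, o = _visits([0, 7, 14])
        o[0, 5:] = False
        o[1, :5] = False
        traj = build_monthly_grid(m, v, o, 1)
        assert traj.observed.sum() == o.sum()

    def test_collision_keeps_nearer_visit_and_merges(self):
        # months 4 and 7 both map to slot 6 (distances 2 and 1); MMSE comes
        # from month 4 alone, the conflicting ADAS13 from the nearer month 7
        m, v, o = _visits([0, 4, 7])
        v[1, 3:] = 100.0
        v[2, 3:] = 200.0
        o[1, :] = False
        o[2, :] = False
        j_adas = DEFAULT_SCHEMA.feature_index("ADAS13")
        j_mmse = DEFAULT_SCHEMA.feature_index("MMSE")
        o[1, j_mmse] = True
        o[2, j_adas] = True
        o[1, j_adas] = True  # conflict: both observe ADAS13
        traj = build_monthly_grid(m, v, o, 6)
        assert traj.observed[1, j_adas] and traj.observed[1, j_mmse]
        assert traj.values[1, 2 + j_adas] == 200.0  # month 7 is nearer slot 6
        assert traj.values[1, 2 + j_mmse] == 100.0


class TestNormalization:
    def test_train_moments_after_znormalize(self, small_cohort):
        cohort, _ = small_cohort
        stats = ap.fit_norm_stats(cohort)
        norm = ap.znormalize(cohort, stats)
        for j in range(DEFAULT_SCHEMA.n_continuous):
            vals = np.concatenate(
                [s.visit_values[s.visit_observed[:, 1 + j], 3 + j] for s in norm]
            )
            assert abs(vals.mean()) < 1e-8
            assert abs(vals.std() - 1.0) < 1e-8

    def test_roundtrip_identity(self, small_cohort):
        cohort, _ = small_cohort
        stats = ap.fit_norm_stats(cohort)
        back = ap.denormalize(ap.znormalize(cohort, stats), stats)
        for s0, s1 in zip(cohort, back):
            np.testing.assert_allclose(
                s0.visit_values[s0.visit_observed[:, 1:].any(axis=1), 3:],
                s1.visit_values[s1.visit_observed[:, 1:].any(axis=1), 3:],
                rtol=1e-10, atol=1e-8,
            )

    def test_diagnosis_untouched(self, small_cohort):
        cohort, _ = small_cohort
        stats = ap.fit_norm_stats(cohort)
        norm = ap.znormalize(cohort, stats)
        for s0, s1 in zip(cohort, norm):
            np.testing.assert_array_equal(s0.visit_values[:, :3], s1.visit_values[:, :3])

    def test_constant_feature_rejected(self, small_cohort):
        cohort, _ = small_cohort
        import dataclasses
        subs = []
        for s in cohort.subjects[:5]:
            vv = s.visit_values.copy()
            vv[:, 3] = 7.0  # CDRSB constant
            subs.append(dataclasses.replace(s, visit_values=vv))
        from adprog.cohort import Cohort
        with pytest.raises(ValueError, match="CDRSB"):
            ap.fit_norm_stats(Cohort(subs))


class TestSplits:
    def test_disjoint_test_blocks_cover_cohort(self, small_cohort):
        cohort, _ = small_cohort
        plans = ap.make_split_plan(cohort, n_repeats=5, seed=3)
        seen = []
        for p in plans:
            assert not set(p.test_ids) & set(seen)
            seen.extend(p.test_ids)
            assert not set(p.test_ids) & set(p.train_ids)
            assert not set(p.val_ids) & set(p.train_ids)
        assert sorted(seen) == sorted(cohort.subject_ids)

    def test_18_1_1_ratio(self):
        cohort, _ = ap.simulate_cohort(ap.SimConfig(n_subjects=400, seed=2))
        plans = ap.make_split_plan(cohort, n_repeats=20, seed=0)
        for p in plans:
            assert len(p.test_ids) == 20
            assert abs(len(p.val_ids) - 20) <= 1
            assert abs(len(p.train_ids) - 360) <= 1

    def test_too_small_cohort_rejected(self):
        cohort, _ = ap.simulate_cohort(ap.SimConfig(n_subjects=20, seed=2))
        with pytest.raises(ConfigurationError):
            ap.make_split_plan(cohort, n_repeats=20, seed=0)

    def test_first_half_visits_are_input(self, small_cohort):
        cohort, _ = small_cohort
        s = next(s for s in cohort if s.n_visits == 6)
        inp, tgt = split_input_target(s, 3)
        assert inp.n_visits == 3
        assert tgt.n_visits == 3
        # input months strictly precede target months
        assert inp.visit_months.max() < tgt.visit_months.min()

    def test_single_visit_subject_has_no_targets(self, small_cohort):
        cohort, _ = small_cohort
        s = cohort.subjects[0]
        inp, tgt = split_input_target(s, s.n_visits)
        assert tgt is None
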