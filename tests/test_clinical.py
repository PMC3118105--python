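"""Tests for the posture-pattern analytics against the published tables."""

from fractions import Fraction
from math import comb

import pandas as pd
import pytest

from dystonia_reflex.clinical import (ARM_JOINTS, CohortLoadError,
                                      PostureRecord, cohort_frame,
                                      combination_table, indicator_tuple,
                                      load_cohort, lr_symmetry_test,
                                      marginal_counts,
                                      proximal_distal_containment,
                                      save_cohort, severity_summary)
from dystonia_reflex.synth import (default_cohort_spec, fixture_table3_cohort,
                                   generate_cohort)


def arm_record(pid="P1", side="left", severity="mild", **joints):
    postures = dict.fromkeys(ARM_JOINTS, "none")
    postures.update(joints)
    return PostureRecord(patient_id=pid, side=side, limb="arm",
                         postures=postures, severity=severity)


def fisher_enumeration_oracle(table):
    """Exact two-sided Fisher p by full enumeration of all 2x2 tables with
    the observed margins, in exact rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):  # hypergeometric P(X = x)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


class TestRecords:
    def test_severity_requires_dystonia(self):
        with pytest.raises(ValueError):
            arm_record(severity="mild")  # all joints none
        with pytest.raises(ValueError):
            arm_record(severity="none", fingers="flexion")

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            arm_record(fingers="supination")

    def test_indicator_tuple_arm(self):
        rec = arm_record(fingers="flexion", shoulder="adduction")
        assert indicator_tuple(rec) == (True, False, False, True)

    def test_merged_ankle_indicator(self):
        for cat, expect in (("plantar_flexion", True), ("inversion", True),
                            ("plantar_flexion_inversion", True),
                            ("dorsiflexion", False), ("eversion", False)):
            rec = PostureRecord(
                patient_id="P1", side="left", limb="leg",
                postures={"toes": "none", "ankle": cat, "knee": "none",
                          "hip": "none"}, severity="mild")
            assert indicator_tuple(rec)[1] is expect


class TestCombinationTable:
    def test_arm_fixture_reproduces_published_marginals(self):
        table = combination_table(fixture_table3_cohort("arm"), "arm")
        assert marginal_counts(table) == {
            "finger_flexion": 116, "wrist_flexion": 41, "elbow_flexion": 38,
            "shoulder_adduction": 12, "total": 118}
        assert len(table.rows) == 10

    def test_leg_fixture_reproduces_published_marginals(self):
        table = combination_table(fixture_table3_cohort("leg"), "leg")
        marg = marginal_counts(table)
        assert marg["total"] == 113
        assert marg["toe_plantar_flexion"] == 55
        assert marg["knee_flexion"] == 32
        assert marg["hip_internal_rotation"] == 11
        assert marg["ankle_plantar_flexion_or_inversion"] == 100
        assert len(table.rows) == 10

    def test_empty_cohort(self):
        table = combination_table([], "arm")
        assert table.grand_total == 0 and table.rows == ()

    def test_single_limb(self):
        table = combination_table(
            [arm_record(fingers="flexion", wrist="flexion")], "arm")
        assert table.rows == (((True, True, False, False), 1),)
        assert table.column_totals == (1, 1, 0, 0)

    def test_conservation_on_generated_cohort(self):
        cohort = generate_cohort(default_cohort_spec(300, seed=3))
        for limb in ("arm", "leg"):
            table = combination_table(cohort, limb)
            n = sum(1 for r in cohort if r.limb == limb)
            assert (table.grand_total + table.other_pattern_count
                    + table.non_dystonic_count) == n

    def test_marginals_match_brute_force_recount(self):
        cohort = generate_cohort(default_cohort_spec(300, seed=3))
        table = combination_table(cohort, "arm")
        marg = marginal_counts(table)
        dystonic = [r for r in cohort if r.limb == "arm" and r.is_dystonic
                    and any(indicator_tuple(r))]
        assert marg["total"] == len(dystonic)
        assert marg["finger_flexion"] == sum(
            r.postures["fingers"] == "flexion" for r in dystonic)
        assert marg["shoulder_adduction"] == sum(
            r.postures["shoulder"] == "adduction" for r in dystonic)


class TestContainment:
    def test_fixture_cohorts_satisfy_containment(self):
        for limb in ("arm", "leg"):
            assert proximal_distal_containment(
                fixture_table3_cohort(limb), limb) == []

    def test_shoulder_without_fingers_is_violation(self):
        rec = arm_record(shoulder="adduction")
        assert proximal_distal_containment([rec], "arm") == [rec]

    def test_empty_cohort(self):
        assert proximal_distal_containment([], "leg") == []


class TestSymmetryTest:
    def build(self, a, b, c, d):
        cohort = []
        fills = [("left", True)] * a + [("left", False)] * b \
            + [("right", True)] * c + [("right", False)] * d
        for i, (side, dyst) in enumerate(fills):
            joints = {"fingers": "flexion" if dyst else "none",
                      "wrist": "none", "elbow": "none", "shoulder": "none"}
            cohort.append(PostureRecord(
                patient_id=f"P{i}", side=side, limb="arm", postures=joints,
                severity="mild" if dyst else "none"))
        return cohort

    def test_perfectly_symmetric_table(self):
        assert lr_symmetry_test(self.build(10, 10, 10, 10), "arm") == 1.0

    def test_diagonal_table_matches_enumeration(self):
        p = lr_symmetry_test(self.build(5, 0, 0, 5), "arm")
        assert p == pytest.approx(
            fisher_enumeration_oracle([[5, 0], [0, 5]]), abs=1e-12)

    def test_row_swap_invariance(self):
        assert lr_symmetry_test(self.build(7, 3, 2, 8), "arm") == \
            pytest.approx(lr_symmetry_test(self.build(2, 8, 7, 3), "arm"))

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert lr_symmetry_test(self.build(5, 0, 3, 0), "arm") == 1.0

    @pytest.mark.parametrize("table", [
        [[3, 4], [5, 2]], [[1, 6], [6, 1]], [[2, 2], [5, 1]],
        [[6, 1], [1, 6]], [[4, 4], [3, 5]]])
    def test_matches_enumeration_oracle(self, table):
        (a, b), (c, d) = table
        p = lr_symmetry_test(self.build(a, b, c, d), "arm")
        assert p == pytest.approx(fisher_enumeration_oracle(table), abs=1e-10)


class TestSeverity:
    def test_single_patient_single_limb(self):
        df = severity_summary([arm_record(fingers="flexion", severity="mild")])
        assert df.set_index("severity").loc["mild", "count"] == 1
        assert df["count"].sum() == 1

    def test_patient_counted_at_maximum_grade(self):
        arm = arm_record(fingers="flexion", severity="mild")
        leg = PostureRecord(
            patient_id="P1", side="left", limb="leg",
            postures={"toes": "plantar_flexion", "ankle": "none",
                      "knee": "none", "hip": "none"}, severity="severe")
        df = severity_summary([arm, leg]).set_index("severity")
        assert df.loc["severe", "count"] == 1
        assert df["count"].sum() == 1

    def test_generated_cohort_recovers_published_distribution(self):
        cohort = generate_cohort(default_cohort_spec(5000, seed=11))
        df = severity_summary(cohort).set_index("severity")
        for grade, pct in (("slight", 11.8), ("mild", 41.2),
                           ("moderate", 24.7), ("severe", 22.3)):
            assert df.loc[grade, "pct"] == pytest.approx(pct, abs=3.0)


class TestIO:
    def test_roundtrip_identity(self, tmp_path):
        cohort = generate_cohort(default_cohort_spec(40, seed=5))
        path = tmp_path / "cohort.csv"
        save_cohort(cohort, path)
        assert load_cohort(path) == cohort

    def test_fixture_loads_cleanly(self, tmp_path):
        path = tmp_path / "fx.csv"
        save_cohort(fixture_table3_cohort("arm"), path)
        assert len(load_cohort(path)) == 118

    def test_severity_without_dystonia_rejected_with_row_number(self, tmp_path):
        df = cohort_frame([arm_record(fingers="flexion")])
        df.loc[0, "fingers"] = "none"  # severity now inconsistent
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortLoadError, match="row 2"):
            load_cohort(path)

    def test_duplicate_limb_rejected(self, tmp_path):
        rec = arm_record(fingers="flexion")
        df = pd.concat([cohort_frame([rec])] * 2, ignore_index=True)
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortLoadError, match="duplicate"):
            load_cohort(path)

    def test_leg_joint_on_arm_row_rejected(self, tmp_path):
        df = cohort_frame([arm_record(fingers="flexion")])
        df.loc[0, "ankle"] = "inversion"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortLoadError, match="not applicable"):
            load_cohort(path)

    def test_missing_column_rejected(self, tmp_path):
        df = cohort_frame([arm_record(fingers="flexion")]).drop(columns=["hip"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortLoadError, match="missing"):
            load_cohort(path)
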