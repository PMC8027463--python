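import numpy as np
import pandas as pd
import pytest

from hemoflow.cohort_stats import (
    CohortTable,
    aggregate_per_group,
    aggregate_per_patient,
    anova_posthoc,
    compare_categorical,
    compare_two_cohorts,
    games_howell,
    repeatability,
)


def make_table(rows, subjects):
    rec = pd.DataFrame(
        rows,
        columns=["segment_id", "subject_id", "view_id", "diameter_um", "va_mm_s",
                 "vs_mm_s", "q_pl_s", "wsr_per_s", "group", "quality"],
    )
    sub = pd.DataFrame(subjects, columns=["subject_id", "cohort"])
    return CohortTable(rec, sub)


def row(i, subject, d=15.0, va=0.5, group=2):
    return (f"s{i}", subject, "v1", d, va, va, 1.0, 1.0, group, 1.0)


class TestCohortTable:
    def test_unknown_subject_rejected(self):
        with pytest.raises(ValueError, match="unknown subjects"):
            make_table([row(0, "ghost")], [("p1", "control")])

    def test_bad_cohort_label_rejected(self):
        with pytest.raises(ValueError, match="cohort labels"):
            make_table([row(0, "p1")], [("p1", "patient")])


class TestAggregation:
    def test_per_patient_mean(self):
        t = make_table(
            [row(0, "p1", d=10), row(1, "p1", d=20), row(2, "p1", d=30)],
            [("p1", "control")],
        )
        assert aggregate_per_patient(t, "D").loc["p1"] == 20.0

    def test_per_patient_order_and_warning(self):
        t = make_table(
            [row(0, "p2", d=10), row(1, "p1", d=30)],
            [("p1", "control"), ("p2", "MI"), ("p3", "control")],
        )
        with pytest.warns(UserWarning, match="p3"):
            vals = aggregate_per_patient(t, "D")
        assert list(vals.index) == ["p1", "p2"]

    def test_per_group_filters_segments(self):
        t = make_table(
            [row(0, "p1", group=1), row(1, "p1", group=1), row(2, "p1", group=2)],
            [("p1", "control")],
        )
        vals = aggregate_per_group(t, "D", 1)
        assert len(vals["control"]) == 2 and len(vals["MI"]) == 0

    def test_per_group_empty_warns(self):
        t = make_table([row(0, "p1", group=1)], [("p1", "control")])
        with pytest.warns(UserWarning):
            vals = aggregate_per_group(t, "Va", 4)
        assert all(len(v) == 0 for v in vals.values())

    def test_patient_and_segment_aggregation_differ_on_unbalanced_data(self):
        """One subject with many segments must not dominate the patient-level
        mean the way it dominates the segment-pooled mean."""
        rows = [row(i, "p1", va=1.0) for i in range(9)] + [row(9, "p2", va=0.0)]
        t = make_table(rows, [("p1", "control"), ("p2", "control")])
        patient_mean = aggregate_per_patient(t, "Va").mean()
        segment_mean = t.records["va_mm_s"].mean()
        assert patient_mean == pytest.approx(0.5)
        assert segment_mean == pytest.approx(0.9)

    def test_imposed_group_effect_direction(self, rng):
        rows, subs = [], []
        for arm, mean in (("control", 0.51), ("MI", 0.40)):
            for p in range(6):
                sid = f"{arm}{p}"
                subs.append((sid, arm))
                for k in range(10):
                    va = rng.normal(mean, 0.05)
                    rows.append((f"{sid}-{k}", sid, "v1", 18.0, va, va, 1, 1, 3, 1.0))
        t = make_table(rows, subs)
        vals = aggregate_per_group(t, "Va", 3)
        assert vals["MI"].mean() < vals["control"].mean()


class TestTwoCohorts:
    def test_identical_lists_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = compare_two_cohorts(x, x)
        assert res.test == "t-test"
        assert res.p_value == pytest.approx(1.0)

    def test_study_scale_effect_detected(self, rng):
        ctrl = rng.normal(0.53, 0.15, 1000)
        mi = rng.normal(0.49, 0.17, 1000)
        res = compare_two_cohorts(ctrl, mi)
        assert res.p_value < 0.001
        assert res.means[0] > res.means[1]

    def test_skewed_arms_use_mann_whitney(self, rng):
        a = rng.lognormal(0.0, 1.0, 1000)
        b = rng.lognormal(0.1, 1.0, 1000)
        res = compare_two_cohorts(a, b)
        assert res.test == "mann-whitney"

    def test_symmetry_in_arm_order(self, rng):
        a = rng.normal(0.5, 0.1, 40)
        b = rng.normal(0.45, 0.1, 40)
        r1 = compare_two_cohorts(a, b)
        r2 = compare_two_cohorts(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        assert r1.means[0] == r2.means[1]

    def test_ci_contains_mean(self, rng):
        a = rng.normal(0.5, 0.1, 30)
        res = compare_two_cohorts(a, rng.normal(0.5, 0.1, 30))
        lo, hi = res.cis[0]
        assert lo < res.means[0] < hi

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            compare_two_cohorts([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCategorical:
    def test_perfect_independence(self):
        res = compare_categorical([[10, 10], [10, 10]])
        assert res.p_value == pytest.approx(1.0)
        assert res.test == "chi-square"

    def test_zero_cell_triggers_fisher(self):
        # diabetes row: 0/56 controls vs 12/47 MI
        res = compare_categorical([[0, 56], [12, 47]])
        assert res.test == "fisher"
        assert res.p_value < 0.05

    def test_large_counts_use_chi_square(self):
        # male sex row: 38/18 vs 47/12
        res = compare_categorical([[38, 18], [47, 12]])
        assert res.test == "chi-square"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[0, 0], [0, 0]])


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_posthoc([g, g, g])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_shifted_group_found_by_posthoc(self, rng):
        g1 = rng.normal(0, 1, 50)
        g2 = rng.normal(0, 1, 50)
        g3 = rng.normal(2, 1, 50)
        res = anova_posthoc([g1, g2, g3])
        assert res.p_value < 0.001
        sig = {(p.group_a, p.group_b) for p in res.pairwise if p.p_value < 0.05}
        assert sig == {(0, 2), (1, 2)}

    def test_heteroscedastic_groups_use_games_howell(self, rng):
        g1 = rng.normal(0, 0.1, 40)
        g2 = rng.normal(0, 0.1, 40)
        g3 = rng.normal(0.5, 1.0, 40)
        res = anova_posthoc([g1, g2, g3])
        assert res.posthoc_method == "games-howell"

    def test_games_howell_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 30), (0.5, 2, 40), (1, 0.5, 35))]
        ours = games_howell(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat([0, 1, 2], [len(g) for g in groups]),
            }
        )
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        for pair, pval in zip(ours, ref["pval"]):
            assert pair.p_value == pytest.approx(pval, abs=1e-6)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])


class TestRepeatability:
    def test_identical_pairs(self):
        res = repeatability([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert res.mean_diff == 0.0 and res.cr == 0.0

    @pytest.mark.parametrize(
        "sd,expected_cr",
        [(2.14, 4.19), (0.04, 0.08), (0.01, 0.02), (4.17, 8.17)],
    )
    def test_printed_coefficients_of_repeatability(self, sd, expected_cr, rng):
        """CR = 1.96 x SD of paired differences, reproduced from the study's
        printed repeatability SDs."""
        d = rng.normal(0, 1, 38)
        d = (d - d.mean()) / d.std(ddof=1) * sd
        res = repeatability([(x, 0.0) for x in d])
        assert round(res.cr, 2) == expected_cr

    def test_swap_invariance(self, rng):
        pairs = rng.normal(0, 1, (20, 2))
        a = repeatability([tuple(p) for p in pairs])
        b = repeatability([(p[1], p[0]) for p in pairs])
        assert a.cr == pytest.approx(b.cr)
        assert a.mean_diff == pytest.approx(-b.mean_diff)

    def test_ci_is_mean_diff_plus_minus_cr(self, rng):
        pairs = rng.normal(0, 1, (15, 2))
        res = repeatability([tuple(p) for p in pairs])
        assert res.ci == pytest.approx((res.mean_diff - res.cr, res.mean_diff + res.cr))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            repeatability([(1.0, 2.0)])
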