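"""Behavioral statistics: transforms, ANOVA vs oracle, classical tests."""

import math

import numpy as np
import pandas as pd
import pytest

from melent.behavioral_analysis import (
    FISHER_Z_CAP,
    MUSICIAN,
    NONMUSICIAN,
    ParticipantProfile,
    UndefinedStatisticError,
    chi_square_2x2,
    cronbach_alpha,
    exclude_outliers,
    fisher_z,
    inferred_uncertainty,
    mixed_anova,
    participant_model_fit,
    pooled_t,
    rank_transform_anova,
    welch_t,
    williams_t,
)
from oracles import mixed_anova_oracle, williams_oracle


class TestInferredUncertainty:
    def test_constant_ratings_give_one(self):
        for value in (1, 5, 9):
            for orientation in ("raw", "reversed"):
                assert inferred_uncertainty([value] * 9, orientation) == \
                    pytest.approx(1.0)

    def test_hand_computed_spike(self):
        ratings = [9, 1, 1, 1, 1, 1, 1, 1, 1]
        p = np.array([9 / 17] + [1 / 17] * 8)
        expected = -np.sum(p * np.log2(p)) / math.log2(9)
        assert inferred_uncertainty(ratings, "raw") == \
            pytest.approx(expected, abs=1e-12)

    def test_orientations_differ_for_nonconstant(self):
        ratings = [9, 1, 3, 5, 2, 8, 4, 6, 7]
        assert inferred_uncertainty(ratings, "raw") != \
            inferred_uncertainty(ratings, "reversed")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            inferred_uncertainty([0, 1, 1, 1, 1, 1, 1, 1, 1])


class TestParticipantModelFit:
    def test_perfect_correlation_capped(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        fit = participant_model_fit(x, x)
        assert fit.r == pytest.approx(1.0)
        assert fit.z == pytest.approx(FISHER_Z_CAP)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = participant_model_fit(x, -x)
        assert fit.r == pytest.approx(-1.0)

    def test_hand_computed_five_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        fit = participant_model_fit(x, y)
        assert fit.r == pytest.approx(r_hand, abs=1e-12)
        assert fit.z == pytest.approx(math.atanh(r_hand), abs=1e-9)

    def test_zero_variance_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            participant_model_fit([1, 1, 1, 1], [1, 2, 3, 4])

    def test_fisher_z_round_trip(self):
        for r in (-0.95, -0.3, 0.0, 0.42, 0.99):
            assert math.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)


class TestExcludeOutliers:
    def test_all_equal_keeps_everyone(self):
        table = pd.DataFrame(np.ones((6, 4)),
                             index=[f"P{i}" for i in range(6)])
        retained, report = exclude_outliers(table)
        assert len(retained) == 6 and report.empty

    def test_gross_outlier_excluded(self):
        values = np.ones((8, 2))
        values[3, 1] = 100.0
        table = pd.DataFrame(values, index=[f"P{i}" for i in range(8)])
        retained, report = exclude_outliers(table)
        assert "P3" not in retained
        assert set(report["participant"]) == {"P3"}

    def test_boundary_value_retained(self):
        """A value exactly on the Tukey fence is kept (strict inequality)."""
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        q1, q3 = np.percentile(col, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        col_with_boundary = np.append(col[:-1], fence)
        table = pd.DataFrame({"cond": col_with_boundary},
                             index=[f"P{i}" for i in range(8)])
        # the fence itself moves with the data; recompute and assert intent
        q1b, q3b = np.percentile(col_with_boundary, [25, 75])
        hi = q3b + 1.5 * (q3b - q1b)
        retained, _ = exclude_outliers(table)
        expected = [f"P{i}" for i, v in enumerate(col_with_boundary)
                    if q1b - 1.5 * (q3b - q1b) <= v <= hi]
        assert retained == expected


def _toy_design(n_per_group=3, effects=None, noise=0.0, seed=0):
    """Tidy balanced 2x2x2 dataset with configurable true effects."""
    effects = effects or {}
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for group in (MUSICIAN, NONMUSICIAN):
        g = 1.0 if group == MUSICIAN else -1.0
        for _ in range(n_per_group):
            pid += 1
            subject = rng.normal(0, effects.get("subject_sd", 0.0))
            for comp in ("complex", "simple"):
                b = 1.0 if comp == "complex" else -1.0
                for ent in ("high", "low"):
                    c = 1.0 if ent == "high" else -1.0
                    value = (5.0 + subject
                             + effects.get("group", 0.0) * g
                             + effects.get("complexity", 0.0) * b
                             + effects.get("entropy", 0.0) * c
                             + effects.get("entropy*group", 0.0) * c * g
                             + rng.normal(0, noise))
                    rows.append((f"P{pid:02d}", group, comp, ent, value))
    return pd.DataFrame(rows, columns=["participant", "group", "complexity",
                                       "entropy", "value"])


class TestMixedAnova:
    def test_null_data_gives_zero_f(self):
        data = _toy_design(n_per_group=4)
        data["value"] = 5.0
        table = mixed_anova(data)
        assert np.allclose(table["F"], 0.0)

    def test_pure_group_shift_hits_only_expertise(self):
        data = _toy_design(n_per_group=5, effects={"group": 2.0}, noise=0.05,
                           seed=3)
        table = mixed_anova(data)
        assert table.loc["expertise", "p"] < 1e-6
        others = table.drop(index="expertise")
        assert (others["p"] > 0.01).all()

    def test_matches_cell_means_oracle(self):
        data = _toy_design(
            n_per_group=3,
            effects={"group": 0.8, "entropy": 0.5, "entropy*group": 0.3,
                     "subject_sd": 0.4},
            noise=0.5, seed=11)
        mine = mixed_anova(data)
        oracle = mixed_anova_oracle(data)
        for effect in oracle.index:
            assert mine.loc[effect, "F"] == pytest.approx(
                oracle.loc[effect, "F"], rel=1e-9), effect
            assert mine.loc[effect, "SS"] == pytest.approx(
                oracle.loc[effect, "SS"], rel=1e-9), effect

    def test_total_ss_additivity(self):
        data = _toy_design(n_per_group=4, effects={"group": 1.0,
                                                   "entropy": 0.7,
                                                   "subject_sd": 0.5},
                           noise=1.0, seed=5)
        table = mixed_anova(data)
        effect_ss = table["SS"].sum()
        # each within stratum shares one error term across its two rows
        error_ss = (table.loc["expertise", "error_SS"]
                    + table.loc["complexity", "error_SS"]
                    + table.loc["entropy", "error_SS"]
                    + table.loc["complexity*entropy", "error_SS"])
        assert table.attrs["ss_total"] == pytest.approx(
            effect_ss + error_ss, rel=1e-9)

    def test_unbalanced_groups_supported(self):
        data = _toy_design(n_per_group=5, effects={"entropy": 1.0}, noise=0.3,
                           seed=7)
        data = data[data["participant"] != "P01"]
        table = mixed_anova(data)
        assert table.loc["entropy", "p"] < 0.01
        assert table.loc["entropy", "df2"] == 9 - 2

    def test_missing_cell_rejected(self):
        data = _toy_design(n_per_group=3)
        broken = data.drop(index=data.index[0])
        with pytest.raises(ValueError):
            mixed_anova(broken)

    def test_cross_check_with_pingouin_marginal(self):
        """Collapsing one within factor, the remaining mixed design matches
        pingouin's mixed_anova."""
        import pingouin as pg

        data = _toy_design(n_per_group=6,
                           effects={"group": 0.5, "entropy": 0.8,
                                    "subject_sd": 0.3},
                           noise=0.6, seed=13)
        collapsed = (data.groupby(["participant", "group", "entropy"])
                     ["value"].mean().reset_index())
        pg_table = pg.mixed_anova(collapsed, dv="value", within="entropy",
                                  subject="participant", between="group")
        mine = mixed_anova(data)
        pg_entropy = pg_table.set_index("Source").loc["entropy", "F"]
        pg_group = pg_table.set_index("Source").loc["group", "F"]
        pg_inter = pg_table.set_index("Source").loc["Interaction", "F"]
        assert mine.loc["entropy", "F"] == pytest.approx(pg_entropy, rel=1e-6)
        assert mine.loc["expertise", "F"] == pytest.approx(pg_group, rel=1e-6)
        assert mine.loc["entropy*expertise", "F"] == pytest.approx(
            pg_inter, rel=1e-6)


class TestRankTransformAnova:
    def test_monotone_transform_invariance(self):
        data = _toy_design(n_per_group=4, effects={"entropy": 0.9}, noise=0.4,
                           seed=2)
        transformed = data.copy()
        transformed["value"] = np.exp(transformed["value"])
        a = rank_transform_anova(data)
        b = rank_transform_anova(transformed)
        assert np.allclose(a["F"], b["F"], rtol=1e-9)

    def test_matches_rank_then_anova(self):
        from scipy.stats import rankdata

        data = _toy_design(n_per_group=3, effects={"group": 1.0}, noise=0.7,
                           seed=4)
        manual = data.copy()
        manual["value"] = rankdata(manual["value"])
        assert np.allclose(rank_transform_anova(data)["F"],
                           mixed_anova(manual)["F"], rtol=1e-12)

    def test_midranks_sum(self):
        from scipy.stats import rankdata

        values = [1, 1, 2, 2, 2, 3]
        ranks = rankdata(values)
        n = len(values)
        assert ranks.sum() == n * (n + 1) / 2


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        base = np.arange(10.0)
        matrix = np.column_stack([base, base, base])
        assert cronbach_alpha(matrix) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        matrix = rng.normal(size=(4000, 6))
        assert abs(cronbach_alpha(matrix)) < 0.1

    def test_hand_computed_3x3(self):
        matrix = np.array([[1.0, 2.0, 3.0],
                           [2.0, 4.0, 5.0],
                           [3.0, 5.0, 6.0]])
        k = 3
        item_var = matrix.var(axis=0, ddof=1).sum()
        total_var = matrix.sum(axis=1).var(ddof=1)
        expected = k / (k - 1) * (1 - item_var / total_var)
        assert cronbach_alpha(matrix) == pytest.approx(expected, abs=1e-12)

    def test_cross_check_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        matrix = pd.DataFrame(rng.normal(size=(30, 5))
                              + rng.normal(size=(30, 1)))
        expected = pg.cronbach_alpha(matrix)[0]
        assert cronbach_alpha(matrix) == pytest.approx(expected, abs=1e-9)


class TestSummaryTTests:
    def test_welch_identical_groups(self):
        t, _ = welch_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0

    def test_welch_gmsi_worked_example(self):
        """Printed musical-training summaries for the two groups."""
        t, df = welch_t(13.94, 3.56, 17, 53.12, 7.83, 17)
        assert t == pytest.approx(-18.79, abs=0.05)
        assert df == pytest.approx(22.36, abs=0.1)

    def test_welch_matches_scipy_toy_case(self):
        from scipy.stats import ttest_ind

        a = np.array([1.0, 2.0, 4.0, 4.5])
        b = np.array([3.0, 5.0, 7.0])
        t, df = welch_t(a.mean(), a.std(ddof=1), len(a),
                        b.mean(), b.std(ddof=1), len(b))
        ref = ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert df == pytest.approx(ref.df, abs=1e-9)

    def test_pooled_age_worked_example(self):
        t, df = pooled_t(26.65, 5.68, 17, 28.94, 6.42, 17)
        assert abs(t) == pytest.approx(1.10, abs=0.02)
        assert df == 32

    def test_pooled_matches_scipy_toy_case(self):
        from scipy.stats import ttest_ind

        a = np.array([1.0, 2.0])
        b = np.array([3.0, 6.0])
        t, df = pooled_t(a.mean(), a.std(ddof=1), 2,
                         b.mean(), b.std(ddof=1), 2)
        ref = ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert df == 2


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        assert chi_square_2x2([[10, 20], [5, 10]]) == pytest.approx(0.0)

    def test_gender_worked_example(self):
        assert chi_square_2x2([[9, 8], [8, 9]]) == pytest.approx(0.12,
                                                                 abs=0.005)

    def test_perfect_association(self):
        assert chi_square_2x2([[10, 0], [0, 10]]) == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestWilliamsT:
    def test_equal_correlations_give_zero(self):
        t, df = williams_t(0.5, 0.5, 0.3, 30)
        assert t == 0.0 and df == 27

    def test_sign_symmetry(self):
        t1, _ = williams_t(0.6, 0.3, 0.4, 25)
        t2, _ = williams_t(0.3, 0.6, 0.4, 25)
        assert t1 == pytest.approx(-t2, abs=1e-12)

    @pytest.mark.parametrize("r12,r13,r23,n", [
        (0.5, 0.3, 0.4, 103),
        (0.7, 0.5, 0.6, 24),
        (-0.2, 0.4, 0.1, 50),
    ])
    def test_matches_symbolic_oracle(self, r12, r13, r23, n):
        t, df = williams_t(r12, r13, r23, n)
        assert df == n - 3
        assert t == pytest.approx(williams_oracle(r12, r13, r23, n),
                                  abs=1e-10)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            williams_t(0.9, -0.9, 0.9, 20)


def test_participant_profile_group_bounds():
    ParticipantProfile("P1", MUSICIAN, 30, "female", 40, 30, 30)
    with pytest.raises(ValueError):
        ParticipantProfile("P2", MUSICIAN, 30, "male", 20, 30, 30)
    with pytest.raises(ValueError):
        ParticipantProfile("P3", NONMUSICIAN, 30, "male", 25, 30, 30)
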