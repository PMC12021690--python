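import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rateragree.agreement import (
    DegenerateMatrixError, anova_mean_squares, classify_fleiss,
    evaluator_bias_anova, icc, icc_all, mae_vs_reference,
    one_way_f_from_summary, pairwise_pearson, spearman_brown,
)
from conftest import make_matrix
from oracle_icc import brute_force_icc


def random_matrix(shape=(8, 4), scale=10.0, seed=0):
    rng = np.random.default_rng(seed)
    return make_matrix(70 + scale * rng.standard_normal(shape))


@st.composite
def matrix_strategy(draw):
    n = draw(st.integers(3, 8))
    k = draw(st.integers(2, 5))
    seed = draw(st.integers(0, 2**20))
    rng = np.random.default_rng(seed)
    base = rng.choice([0.0, 50.0, 100.0], size=(n, k))
    jitter = rng.uniform(-5, 5, size=(n, k))
    values = np.clip(base + jitter, 0, 100)
    if np.ptp(values.mean(axis=1)) == 0 or np.ptp(values) == 0:
        values[0, 0] += 7.0
    return values


class TestAnovaMeanSquares:
    def test_hand_computed_3x2(self, hand_matrix_3x2):
        ms = anova_mean_squares(hand_matrix_3x2)
        assert ms.msb == pytest.approx(5416.6667, abs=1e-3)
        assert ms.msw == pytest.approx(416.6667, abs=1e-3)
        assert ms.df == {"between": 2, "within": 3, "evaluators": 1,
                         "residual": 2}

    def test_identical_columns_no_within_variance(self):
        col = np.array([100.0, 50.0, 0.0, 50.0])
        ms = anova_mean_squares(make_matrix(np.column_stack([col, col, col])))
        assert ms.msw == pytest.approx(0.0, abs=1e-12)
        assert ms.mse == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_no_between_variance(self):
        row = [100.0, 50.0, 0.0]
        ms = anova_mean_squares(make_matrix([row, row, row, row]))
        assert ms.msb == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_flagged_degenerate(self):
        ms = anova_mean_squares(make_matrix(np.full((4, 3), 50.0)))
        assert ms.degenerate

    @given(matrix_strategy())
    def test_within_ss_decomposition_identity(self, values):
        # one-way within SS = evaluator SS + residual SS
        ms = anova_mean_squares(make_matrix(values))
        n, k = ms.n, ms.k
        lhs = n * (k - 1) * ms.msw
        rhs = (k - 1) * ms.msj + (n - 1) * (k - 1) * ms.mse
        assert lhs == pytest.approx(rhs, rel=1e-8, abs=1e-8)


class TestIcc:
    def test_hand_computed_icc1(self, hand_matrix_3x2):
        ms = anova_mean_squares(hand_matrix_3x2)
        est = icc(ms, "ICC1")
        assert est.value == pytest.approx((5416.6667 - 416.6667)
                                          / (5416.6667 + 416.6667), abs=1e-4)
        assert est.value == pytest.approx(0.857, abs=5e-4)

    def test_spearman_brown_links_single_to_average(self):
        assert spearman_brown(0.74, 4) == pytest.approx(0.92, abs=5e-3)

    def test_perfect_reliability_identical_columns(self):
        col = np.array([100.0, 50.0, 0.0])
        ms = anova_mean_squares(make_matrix(np.column_stack([col, col])))
        assert icc(ms, "ICC1").value == pytest.approx(1.0)
        assert icc(ms, "ICC1k").value == pytest.approx(1.0)

    def test_degenerate_matrix_raises(self):
        ms = anova_mean_squares(make_matrix(np.full((3, 3), 50.0)))
        with pytest.raises(DegenerateMatrixError):
            icc(ms, "ICC1")

    def test_matches_brute_force_oracle_on_small_matrices(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            n = int(rng.integers(2, 6))
            k = int(rng.integers(2, 4))
            values = rng.choice([0.0, 50.0, 100.0], size=(n, k))
            if np.ptp(values.mean(axis=1)) == 0:
                continue
            expected = brute_force_icc(values.tolist())
            ms = anova_mean_squares(make_matrix(values))
            for form, want in expected.items():
                assert icc(ms, form).value == pytest.approx(want, abs=1e-8)
            checked += 1

    def test_matches_pingouin_values_and_cis(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        values = rng.normal(70, 10, (15, 4))
        long = pd.DataFrame(
            [(i, r, values[i, r]) for i in range(15) for r in range(4)],
            columns=["targets", "raters", "ratings"])
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
        ms = anova_mean_squares(make_matrix(values))
        for form, pg_type in [("ICC1", "ICC(1,1)"), ("ICC1k", "ICC(1,k)"),
                              ("ICC2", "ICC(A,1)"), ("ICC2k", "ICC(A,k)")]:
            est = icc(ms, form)
            assert est.value == pytest.approx(ref.loc[pg_type, "ICC"], abs=1e-9)
            lo, hi = ref.loc[pg_type, "CI95"]
            assert est.ci_low == pytest.approx(lo, abs=5e-3)
            assert est.ci_high == pytest.approx(hi, abs=5e-3)
            assert est.p_value == pytest.approx(ref.loc[pg_type, "pval"],
                                                abs=1e-9)

    @given(matrix_strategy())
    def test_average_measures_relation_holds(self, values):
        ms = anova_mean_squares(make_matrix(values))
        if ms.degenerate or ms.msb == 0:
            return
        e1 = icc(ms, "ICC1").value
        e1k = icc(ms, "ICC1k").value
        e2 = icc(ms, "ICC2").value
        e2k = icc(ms, "ICC2k").value
        k = ms.k
        for single, avg in ((e1, e1k), (e2, e2k)):
            implied = spearman_brown(single, k)
            if math.isfinite(avg) and math.isfinite(implied):
                assert avg == pytest.approx(implied, rel=1e-8, abs=1e-10)
            else:
                assert avg == implied  # both infinite with the same sign
        if e1 >= 0:
            assert e1 <= e1k + 1e-12
        if e2 >= 0:
            assert e2 <= e2k + 1e-12

    def test_ci_brackets_value(self):
        m = random_matrix(seed=3)
        for est in icc_all(m):
            assert est.ci_low <= est.value <= est.ci_high

    def test_row_permutation_changes_nothing(self):
        m = random_matrix(seed=5)
        perm = np.random.default_rng(1).permutation(m.n)
        m2 = make_matrix(m.values[perm])
        for a, b in zip(icc_all(m), icc_all(m2)):
            assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_column_shift_contrast_consistency_vs_agreement(self):
        # adding a constant to one rater leaves that rater's Pearson r
        # untouched but strictly lowers absolute agreement (ICC2)
        # start from equal column means so the shift genuinely increases
        # evaluator dispersion rather than cancelling an existing offset
        base = random_matrix(seed=11).values
        base = base - base.mean(axis=0, keepdims=True) + 70.0
        m = make_matrix(base)
        shifted = m.values.copy()
        shifted[:, 1] += 8.0
        m2 = make_matrix(shifted)
        r1, _ = pairwise_pearson(m)
        r2, _ = pairwise_pearson(m2)
        assert np.allclose(r1, r2, atol=1e-12)
        icc2_before = icc(anova_mean_squares(m), "ICC2").value
        icc2_after = icc(anova_mean_squares(m2), "ICC2").value
        assert icc2_after < icc2_before

    def test_negative_estimate_reported_and_banded_poor(self):
        # anti-correlated columns force a negative ICC
        m = make_matrix([[0.0, 100.0], [100.0, 0.0], [0.0, 100.0],
                         [100.0, 0.0]])
        est = icc(anova_mean_squares(m), "ICC1")
        assert est.value < 0 and est.band == "poor"
        truncated = icc(anova_mean_squares(m), "ICC1", truncate_negative=True)
        assert truncated.value == 0.0


class TestFleissBands:
    @pytest.mark.parametrize("value,band", [
        (0.39, "poor"),
        (0.40, "fair-to-good"),   # boundary goes to the higher band
        (0.74, "fair-to-good"),
        (0.75, "excellent"),
        (0.92, "excellent"),
        (1.0, "excellent"),
        (-0.2, "poor"),
    ])
    def test_bands(self, value, band):
        assert classify_fleiss(value) == band


class TestPearson:
    def test_duplicated_column_r_one(self):
        col = np.array([100.0, 50.0, 0.0, 50.0])
        r, p = pairwise_pearson(make_matrix(np.column_stack([col, col])))
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_column_r_minus_one(self):
        col = np.array([100.0, 50.0, 0.0, 50.0])
        neg = 2 * col.mean() - col
        r, _ = pairwise_pearson(make_matrix(np.column_stack([col, neg])))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_column_flagged_nan(self):
        m = make_matrix([[50.0, 10.0], [50.0, 60.0], [50.0, 30.0]])
        r, p = pairwise_pearson(m)
        assert math.isnan(r[0, 1]) and math.isnan(p[0, 1])

    def test_grid_symmetric_unit_diagonal(self):
        m = random_matrix(seed=9)
        r, p = pairwise_pearson(m)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.all((p >= 0) & (p <= 1))


class TestEvaluatorBias:
    def test_identical_columns_no_effect(self):
        col = np.array([10.0, 50.0, 90.0])
        m = make_matrix(np.column_stack([col, col, col]))
        rep = evaluator_bias_anova(m)
        assert rep.anova_f == 0.0 and rep.anova_p == 1.0

    def test_constant_offset_detected_paired(self):
        rng = np.random.default_rng(2)
        base = 70 + 15 * rng.standard_normal(30)
        noise = 5 * rng.standard_normal((30, 2))
        m = make_matrix(np.column_stack([base, base + 8.0]) + noise)
        rep = evaluator_bias_anova(m, design="repeated_measures")
        ms = anova_mean_squares(m)
        assert rep.anova_f == pytest.approx(ms.msj / ms.mse)
        assert rep.anova_p < 0.05

    def test_one_way_reconstruction_from_summary(self):
        f, p = one_way_f_from_summary(
            means=[78.0, 70.7, 79.4, 78.4],
            sds=[14.3, 16.4, 14.5, 14.1],
            n_per_group=107)
        assert f == pytest.approx(7.74, abs=5e-3)
        assert p < 0.001

    def test_one_way_agrees_with_scipy(self):
        from scipy import stats

        m = random_matrix(seed=13)
        rep = evaluator_bias_anova(m, design="one_way")
        ref = stats.f_oneway(*[m.values[:, j] for j in range(m.k)])
        assert rep.anova_f == pytest.approx(float(ref.statistic))

    def test_column_permutation_only_relabels(self):
        m = random_matrix(seed=17)
        perm = [2, 0, 3, 1]
        m2 = make_matrix(m.values[:, perm],
                         evaluator_ids=[m.evaluator_ids[j] for j in perm])
        a = evaluator_bias_anova(m)
        b = evaluator_bias_anova(m2)
        assert a.anova_f == pytest.approx(b.anova_f, abs=1e-10)
        assert dict(zip(a.evaluator_ids, a.evaluator_means)) == pytest.approx(
            dict(zip(b.evaluator_ids, b.evaluator_means)))


class TestMae:
    def test_equal_column_zero(self):
        col = np.array([100.0, 50.0, 0.0])
        m = make_matrix(np.column_stack([col, col]), evaluator_ids=["E1", "E2"])
        assert mae_vs_reference(m, "E1") == {"E2": pytest.approx(0.0)}

    def test_constant_shift(self):
        col = np.array([70.0, 50.0, 90.0])
        m = make_matrix(np.column_stack([col, col + 8.0]),
                        evaluator_ids=["E1", "E2"])
        assert mae_vs_reference(m, "E1")["E2"] == pytest.approx(8.0)

    def test_hand_sum(self):
        m = make_matrix([[100.0, 100.0], [50.0, 0.0], [0.0, 50.0]],
                        evaluator_ids=["E1", "E2"])
        assert mae_vs_reference(m, "E1")["E2"] == pytest.approx(100 / 3)

    def test_reference_excluded_and_unknown_rejected(self):
        m = random_matrix(seed=19)
        out = mae_vs_reference(m, "E1")
        assert "E1" not in out and all(v >= 0 for v in out.values())
        with pytest.raises(KeyError):
            mae_vs_reference(m, "EX")


class TestParameterRecovery:
    def test_icc1_unbiased_at_study_scale(self):
        # moderate replicate count; the dedicated recovery study runs 500
        from rateragree.simulate import SimulationConfig, replicate_gaussian_icc

        cfg = SimulationConfig(mode="gaussian", n_participants=107, n_raters=4,
                               icc_target=0.74, grand_mean=0.0, total_var=1.0)
        est = replicate_gaussian_icc(cfg, 150, seed=123)
        assert est[:, 0].mean() == pytest.approx(0.74, abs=0.015)
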