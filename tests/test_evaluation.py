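import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    agreement_brute,
    bland_altman_brute,
    kruskal_wallis_h_brute,
    mann_whitney_exact_brute,
    mcnemar_exact_brute,
    pearson_chi2_brute,
    wilcoxon_exact_brute,
)

from gfrval.evaluation import (
    accuracy_within,
    agreement_summary,
    bland_altman,
    bonferroni_adjust,
    bonferroni_adjust_rounded,
    chi_square_2xk,
    differences,
    kruskal_wallis,
    kruskal_wallis_posthoc,
    mann_whitney_u,
    mcnemar,
    stage_concordance,
    wilcoxon_signed_rank,
)

finite_pairs = st.lists(
    st.tuples(st.floats(1.0, 200.0), st.floats(1.0, 200.0)),
    min_size=1,
    max_size=60,
)


class TestDifferences:
    def test_elementwise(self):
        np.testing.assert_array_equal(
            differences([10, 20, 30], [5, 10, 40]), [5, 10, -10]
        )

    def test_identity(self):
        np.testing.assert_array_equal(differences([3.0, 4.0], [3.0, 4.0]), [0.0, 0.0])

    def test_single_pair(self):
        assert differences([52.25], [43.45])[0] == pytest.approx(8.80)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            differences([1.0], [1.0, 2.0])

    def test_nonpositive_reference(self):
        with pytest.raises(ValueError):
            differences([1.0], [0.0])


class TestAccuracyWithin:
    def test_strict_inequality_boundary(self):
        # exactly 30% off is NOT within
        assert accuracy_within([70.0], [100.0], 0.30) == (0, 0.0)
        assert accuracy_within([71.0], [100.0], 0.30) == (1, 100.0)

    def test_both_sides_out(self):
        assert accuracy_within([49.0, 151.0], [100.0, 100.0], 0.50) == (0, 0.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            s = rng.uniform(10, 100, n)
            e = s * rng.uniform(0.4, 1.8, n)
            for tol in (0.15, 0.30, 0.50):
                count, pct = accuracy_within(e, s, tol)
                ref = sum(1 for a, b in zip(e, s) if abs(a - b) / b < tol)
                assert count == ref
                assert pct == pytest.approx(100.0 * ref / n)


class TestAgreementSummary:
    def test_direct_enumeration(self):
        summ = agreement_summary([86.0, 60.0, 10.0], [100.0, 100.0, 100.0])
        assert (summ.p15_count, summ.p30_count, summ.p50_count) == (1, 1, 2)

    def test_boundary_strictness(self):
        summ = agreement_summary([85.0], [100.0])
        assert summ.p15_count == 0

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 80))
            s = rng.uniform(10, 120, n)
            e = s * rng.uniform(0.4, 1.8, n)
            summ = agreement_summary(e, s)
            ref = agreement_brute(e.tolist(), s.tolist())
            for field in (
                "n", "median_diff", "median_abs_diff",
                "p15_count", "p30_count", "p50_count",
                "p15_pct", "p30_pct", "p50_pct",
            ):
                assert getattr(summ, field) == pytest.approx(ref[field]), field
            assert summ.diff_iqr == pytest.approx(ref["diff_iqr"])
            assert summ.abs_diff_iqr == pytest.approx(ref["abs_diff_iqr"])

    @given(finite_pairs)
    @settings(max_examples=100)
    def test_nesting_invariant(self, pairs):
        e = [p[0] for p in pairs]
        s = [p[1] for p in pairs]
        summ = agreement_summary(e, s)
        assert summ.p15_count <= summ.p30_count <= summ.p50_count <= summ.n

    def test_translation_shifts_median(self, rng):
        s = rng.uniform(20, 100, 40)
        e = s * rng.uniform(0.7, 1.3, 40)
        base = agreement_summary(e, s)
        shifted = agreement_summary(e + 7.5, s)
        assert shifted.median_diff == pytest.approx(base.median_diff + 7.5)


class TestBlandAltman:
    def test_closed_form(self):
        res = bland_altman([4.0, 5.0, 6.0], [5.0, 5.0, 5.0])  # d = -1, 0, 1
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert (res.loa_low, res.loa_high) == pytest.approx((-1.96, 1.96))
        assert res.loa_width == pytest.approx(3.92)

    def test_zero_variance(self):
        res = bland_altman([10.0] * 4, [5.0] * 4)
        assert res.sd_diff == 0.0
        assert res.loa_width == 0.0
        assert res.loa_low == res.loa_high == 5.0

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError, match="n >= 2"):
            bland_altman([1.0], [1.0])

    def test_matches_brute_force(self, rng):
        s = rng.uniform(10, 120, 100)
        e = s * rng.uniform(0.5, 1.6, 100)
        res = bland_altman(e, s)
        ref = bland_altman_brute(e.tolist(), s.tolist())
        for key, val in ref.items():
            assert getattr(res, key) == pytest.approx(val, abs=1e-10), key

    def test_loa_width_identity(self, rng):
        s = rng.uniform(10, 120, 50)
        e = s + rng.normal(0, 10, 50)
        res = bland_altman(e, s)
        assert abs(res.loa_width - 3.92 * res.sd_diff) < 1e-12

    def test_translation_property(self, rng):
        s = rng.uniform(10, 120, 30)
        e = s * rng.uniform(0.8, 1.2, 30)
        a = bland_altman(e, s)
        b = bland_altman(e + 3.0, s)
        assert b.mean_diff == pytest.approx(a.mean_diff + 3.0)
        assert b.sd_diff == pytest.approx(a.sd_diff)

    def test_scatter_series(self):
        res = bland_altman([4.0, 6.0], [2.0, 2.0])
        np.testing.assert_allclose(res.means, [3.0, 4.0])
        np.testing.assert_allclose(res.diffs, [2.0, 4.0])


class TestWilcoxon:
    def test_enumerated_example(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.exact
        assert res.p_value == pytest.approx(0.25)

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.degenerate
        assert res.p_value == 1.0
        assert res.statistic == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 11))
            d = rng.normal(0, 1, n)
            res = wilcoxon_signed_rank(d)
            w_ref, p_ref = wilcoxon_exact_brute(d.tolist())
            assert res.statistic == pytest.approx(w_ref)
            assert res.p_value == pytest.approx(p_ref)

    def test_ties_handled_exactly(self):
        d = [1.0, 1.0, -1.0, 2.0, 2.0]
        res = wilcoxon_signed_rank(d)
        w_ref, p_ref = wilcoxon_exact_brute(d)
        assert res.p_value == pytest.approx(p_ref)

    def test_large_sample_approximation_reasonable(self, rng):
        d = rng.normal(0.0, 1.0, 100)
        res = wilcoxon_signed_rank(d)
        assert not res.exact
        assert 0.0 <= res.p_value <= 1.0


class TestMannWhitney:
    def test_enumerated_example(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.exact
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            nx = int(rng.integers(1, 7))
            ny = int(rng.integers(1, 13 - nx))
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.5, 1, ny)
            res = mann_whitney_u(x, y)
            u_ref, p_ref = mann_whitney_exact_brute(x.tolist(), y.tolist())
            assert res.statistic == pytest.approx(u_ref)
            assert res.p_value == pytest.approx(p_ref)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_large_sample(self, rng):
        res = mann_whitney_u(rng.normal(0, 1, 50), rng.normal(0.3, 1, 60))
        assert not res.exact
        assert 0.0 <= res.p_value <= 1.0


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_constant_groups_degenerate(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])
        assert res.degenerate
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            groups = [rng.normal(m, 1, int(rng.integers(3, 15))) for m in (0, 0.5, 1)]
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(
                kruskal_wallis_h_brute([g.tolist() for g in groups])
            )

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])

    def test_posthoc_structure(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 1, 2)]
        post = kruskal_wallis_posthoc(groups, alpha=0.05)
        assert post["adjusted_level"] == pytest.approx(0.05 / 3)
        assert set(post["pairwise"]) == {(0, 1), (0, 2), (1, 2)}


class TestMcnemar:
    @pytest.mark.parametrize(
        "b,c,expected",
        [(1, 3, 0.625), (5, 5, 1.0), (0, 8, 0.0078125)],
    )
    def test_exact_values(self, b, c, expected):
        res = mcnemar(b, c)
        assert res.exact
        assert res.p_value == pytest.approx(expected)

    def test_degenerate(self):
        res = mcnemar(0, 0)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_matches_binomial_oracle(self, rng):
        for _ in range(30):
            b = int(rng.integers(0, 13))
            c = int(rng.integers(0, 13))
            if b + c == 0:
                continue
            assert mcnemar(b, c).p_value == pytest.approx(mcnemar_exact_brute(b, c))

    def test_large_sample_continuity_corrected(self):
        res = mcnemar(30, 10)
        assert not res.exact
        assert res.statistic == pytest.approx((abs(30 - 10) - 1) ** 2 / 40)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(-1, 2)


class TestChiSquare:
    def test_independence(self):
        res = chi_square_2xk([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        res = chi_square_2xk([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            table = rng.integers(1, 40, size=(2, 3))
            res = chi_square_2xk(table)
            stat_ref, df_ref = pearson_chi2_brute(table.tolist())
            assert res.statistic == pytest.approx(stat_ref)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2xk([[0, 0], [5, 5]])


class TestBonferroni:
    def test_printed_level(self):
        assert bonferroni_adjust_rounded(0.05, 3) == 0.0167

    def test_identity(self):
        assert bonferroni_adjust(0.05, 1) == 0.05

    def test_exact_division(self):
        assert bonferroni_adjust(0.01, 5) == pytest.approx(0.002)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 3)


class TestStageConcordance:
    def test_identity(self):
        diff, test, table = stage_concordance([65.0, 45.0, 20.0], [65.0, 45.0, 20.0])
        np.testing.assert_array_equal(diff, [0, 0, 0])
        assert test.degenerate
        np.testing.assert_array_equal(np.diag(table), [1, 1, 1])

    def test_single_boundary_crossing(self):
        diff, _, _ = stage_concordance([65.0], [55.0])
        assert diff[0] == -1

    def test_systematic_overestimation(self):
        sgfr = np.array([15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 80.0])
        egfr = 1.5 * sgfr
        diff, _, _ = stage_concordance(egfr, sgfr)
        assert np.all(diff <= 0)
        assert np.any(diff < 0)

    def test_cross_table_margins(self, rng):
        s = rng.uniform(10, 100, 50)
        e = s * rng.uniform(0.6, 1.5, 50)
        _, _, table = stage_concordance(e, s)
        assert table.sum() == 50


@given(
    st.lists(st.floats(-50, 50), min_size=1, max_size=11),
)
@settings(max_examples=60)
def test_wilcoxon_p_in_unit_interval(d):
    res = wilcoxon_signed_rank(d)
    assert 0.0 <= res.p_value <= 1.0


@given(
    st.lists(st.floats(0, 10), min_size=1, max_size=8),
    st.lists(st.floats(0, 10), min_size=1, max_size=8),
)
@settings(max_examples=60)
def test_mwu_p_in_unit_interval(x, y):
    res = mann_whitney_u(x, y)
    assert 0.0 <= res.p_value <= 1.0
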