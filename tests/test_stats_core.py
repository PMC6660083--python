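"""Unit and property tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metsig import stats_core as sc


def exhaustive_mw_pvalue(a, b):
    """Brute-force two-sided U-test p by enumerating all label assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    na = len(a)
    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = pooled[[i for i in range(len(pooled)) if i not in idx_a]]
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
    observed = u_stat(tuple(range(na)))
    nb = len(pooled) - na
    mean_u = na * nb / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        u = u_stat(idx)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_groups_exact(self):
        res = sc.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method is sc.Method.exact

    def test_identical_groups_p_one(self):
        res = sc.mann_whitney_u([1.0, 2.0, 3.5, 7.0], [7.0, 3.5, 2.0, 1.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 5, size=2)
        a = rng.normal(size=na).round(3)
        b = rng.normal(size=nb).round(3)
        res = sc.mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(exhaustive_mw_pvalue(a, b), abs=1e-9)

    def test_large_or_tied_samples_use_normal_approx(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=15).astype(float)
        b = rng.integers(0, 5, size=15).astype(float)
        assert sc.mann_whitney_u(a, b).method is sc.Method.normal_approx

    def test_empty_or_single_group_rejected(self):
        with pytest.raises(ValueError):
            sc.mann_whitney_u([], [1, 2])
        with pytest.raises(ValueError):
            sc.mann_whitney_u([1.0], [1, 2])


class TestAurocURelation:
    @pytest.mark.parametrize("seed", range(50))
    def test_auroc_equals_normalized_u(self, seed):
        """AUROC of cases over controls == U_cases / (n1 n0), U by brute force."""
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(3, 8, size=2)
        cases = rng.integers(0, 6, size=n1).astype(float)
        controls = rng.integers(0, 6, size=n0).astype(float)
        u_brute = sum((x > y) + 0.5 * (x == y) for x in cases for y in controls)
        scores = np.concatenate([cases, controls])
        labels = np.array([1] * n1 + [0] * n0)
        assert sc.auroc_from_scores(scores, labels) == pytest.approx(
            u_brute / (n1 * n0), abs=1e-12)

    def test_perfect_separation(self):
        assert sc.auroc_from_scores([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_null_expectation(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert sc.auroc_from_scores(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sc.auroc_from_scores([1, 2], [1, 1])


class TestBHFdr:
    def test_equal_pvalues_unchanged(self):
        res = sc.bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(res.adjusted, 0.2)

    def test_step_up_hand_oracle(self):
        res = sc.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(res.adjusted, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_at_least_raw_and_rank_monotone(self, pvals):
        res = sc.bh_fdr(pvals)
        assert np.all(res.adjusted >= res.raw - 1e-12)
        assert np.all(res.adjusted <= 1.0)
        order = np.argsort(res.raw, kind="mergesort")
        assert np.all(np.diff(res.adjusted[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.bh_fdr([0.5, 1.2])


class TestStoreyQ:
    def test_pi0_one_reduces_to_bh(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        q = sc.storey_q(p, pi0=1.0)
        assert np.allclose(q.adjusted, sc.bh_fdr(p).adjusted)

    def test_uniform_pvalues_pi0_near_one(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=1000)
        q = sc.storey_q(p)
        assert 0.85 <= q.pi0 <= 1.0

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(size=200)])
        q = sc.storey_q(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q.adjusted[order]) >= -1e-12)
        assert np.all((q.adjusted >= 0) & (q.adjusted <= 1))

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            sc.storey_q(np.linspace(0.01, 0.99, 20), lambda_grid=[0.5, 0.5, 0.5, 0.5])

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            sc.storey_q([0.1, 0.2])


class TestFisherExact:
    def test_enumeration_oracle(self):
        # full hypergeometric enumeration: 4252/184756
        res = sc.fisher_exact_2x2(2, 8, 8, 2)
        assert res.p_value == pytest.approx(4252 / 184756, rel=1e-9)

    def test_equal_proportions(self):
        assert sc.fisher_exact_2x2(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_large_contrast_highly_significant(self):
        assert sc.fisher_exact_2x2(902, 63001, 589, 63314).p_value < 1e-4

    @pytest.mark.parametrize("table", [(3, 7, 9, 1), (0, 5, 5, 0), (4, 4, 2, 6)])
    def test_symmetry_under_row_and_column_swap(self, table):
        a, b, c, d = table
        p1 = sc.fisher_exact_2x2(a, b, c, d).p_value
        p2 = sc.fisher_exact_2x2(d, c, b, a).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sc.fisher_exact_2x2(-1, 2, 3, 4)


class TestContingencyMetrics:
    def test_printed_row(self):
        m = sc.panel_contingency_metrics(19, 1, 2, 18)
        assert m.sensitivity == pytest.approx(0.95)
        assert m.specificity == pytest.approx(0.90)
        assert m.accuracy == pytest.approx(37 / 40)

    def test_perfect_classifier(self):
        m = sc.panel_contingency_metrics(20, 0, 0, 20)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    @pytest.mark.parametrize("tp,fn,fp,tn", [(19, 1, 2, 18), (5, 5, 3, 7), (1, 9, 9, 1)])
    def test_wilson_intervals_contain_point_estimates(self, tp, fn, fp, tn):
        m = sc.panel_contingency_metrics(tp, fn, fp, tn)
        assert m.sensitivity_ci[0] <= m.sensitivity <= m.sensitivity_ci[1]
        assert m.specificity_ci[0] <= m.specificity <= m.specificity_ci[1]

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            sc.panel_contingency_metrics(0, 0, 2, 18)
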