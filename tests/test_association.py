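import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from btcprof.association import (
    bh_adjust,
    fisher_exact_2x2,
    group_tmb_test,
    mutation_indicator_matrix,
    pairwise_gene_tests,
)

from conftest import make_variants


def enumerated_fisher_p(a, b, c, d):
    """Independent oracle: sum hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFisher:
    def test_balanced_table(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == 1.0
        assert odds == 1.0

    def test_perfect_association(self):
        odds, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184756, rel=1e-9)
        assert np.isinf(odds)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fisher_exact_2x2([[0, 0], [0, 0]])

    @pytest.mark.parametrize("table", [[[1, -1], [0, 2]], [[0.5, 1], [1, 1]]])
    def test_bad_entries_rejected(self, table):
        with pytest.raises(ValueError):
            fisher_exact_2x2(table)

    def test_haldane_correction(self):
        odds, _ = fisher_exact_2x2([[10, 0], [0, 10]], haldane_correction=True)
        assert odds == pytest.approx(441.0)

    @pytest.mark.parametrize("table", [(3, 7, 2, 8), (0, 5, 5, 0), (1, 1, 9, 9), (6, 0, 3, 2)])
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(enumerated_fisher_p(a, b, c, d), rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) > 0))
    def test_invariant_under_transpose_and_double_swap(self, table):
        a, b, c, d = table
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        _, p_t = fisher_exact_2x2([[a, c], [b, d]])
        _, p_s = fisher_exact_2x2([[d, c], [b, a]])
        assert p == pytest.approx(p_t, rel=1e-12)
        assert p == pytest.approx(p_s, rel=1e-12)


class TestBhAdjust:
    def test_identical_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_order_invariance(self):
        p = [0.001, 0.9, 0.04, 0.3, 0.02]
        q = bh_adjust(p)
        perm = [3, 1, 0, 4, 2]
        q_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm)

    @pytest.mark.parametrize("bad", [[0.0], [1.1], [-0.5]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestPairwise:
    @staticmethod
    def _matrix(a_samples, b_samples, n):
        cols = [f"s{i}" for i in range(n)]
        m = pd.DataFrame(False, index=["A", "B"], columns=cols)
        m.loc["A", [f"s{i}" for i in a_samples]] = True
        m.loc["B", [f"s{i}" for i in b_samples]] = True
        return m

    def test_identical_mutation_sets_co_occur(self):
        m = self._matrix(range(20), range(20), 40)
        res = pairwise_gene_tests(m)
        assert res.iloc[0]["direction"] == "co_occurrent"

    def test_disjoint_halves_exclusive(self):
        m = self._matrix(range(20), range(20, 40), 40)
        res = pairwise_gene_tests(m)
        assert res.iloc[0]["direction"] == "exclusive"

    def test_margins_sum_to_cohort_size(self):
        m = self._matrix(range(5), range(3, 12), 30)
        row = pairwise_gene_tests(m).iloc[0]
        assert row[["n_both", "n_a_only", "n_b_only", "n_neither"]].sum() == 30

    def test_missing_gene_named(self):
        m = self._matrix(range(5), range(5), 10)
        with pytest.raises(KeyError, match="GHOST"):
            pairwise_gene_tests(m, genes=["A", "GHOST"])

    def test_false_positive_rate_controlled_on_independent_genes(self):
        """With all genes independent, the fraction of called pairs stays
        within the FDR bound plus Monte-Carlo slack."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(15)]  # 105 pairs
        m = pd.DataFrame(
            rng.random((15, 1000)) < 0.2,
            index=genes,
            columns=[f"s{i}" for i in range(1000)],
        )
        res = pairwise_gene_tests(m)
        fp_rate = (res["direction"] != "none").mean()
        assert fp_rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(res))


class TestGroupTmbTest:
    def test_identical_groups(self):
        values = [1.0, 2.0, 3.0] * 2
        labels = ["a"] * 3 + ["b"] * 3
        t, p, means = group_tmb_test(values, labels)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert means["a"] == means["b"]

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 100)
        y = rng.normal(2, 1, 100)  # 2 SD shift
        _, p, _ = group_tmb_test(np.r_[x, y], ["x"] * 100 + ["y"] * 100)
        assert p < 0.001

    def test_constant_group_finite_statistic(self):
        values = [1.0] * 5 + [2.0, 2.5, 3.0, 3.5, 4.0]
        t, p, _ = group_tmb_test(values, ["c"] * 5 + ["v"] * 5)
        assert np.isfinite(t) and 0 < p < 1

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_tmb_test([1.0, 2.0, 3.0], ["a", "b", "b"])


def test_indicator_matrix_from_variants():
    variants = make_variants(
        [("s1", "TP53", "missense"), ("s2", "KRAS", "missense"), ("s1", "TP53", "nonsense")]
    )
    m = mutation_indicator_matrix(variants, ["s1", "s2", "s3"])
    assert bool(m.at["TP53", "s1"]) and not bool(m.at["TP53", "s2"])
    assert not m["s3"].any()
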