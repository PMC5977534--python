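"""Correlation, fold-change agreement and differential-expression selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ffpeseq import (
    ExpressionMatrix,
    agreement_sweep,
    benjamini_hochberg,
    correlation_matrix,
    de_genes,
    fc_agreement,
    fold_changes,
    pairwise_cc,
)


def series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestPairwiseCC:
    def test_identical_and_anticorrelated(self):
        a = series([6, 7, 8, 9, 10])
        assert pairwise_cc(a, a, floor=5.0)[0] == pytest.approx(1.0)
        b = 16 - a  # above floor, mirrored
        assert pairwise_cc(a, b, floor=5.0)[0] == pytest.approx(-1.0)

    def test_both_floored_genes_excluded(self):
        a = series([5, 5, 6, 7, 8])
        b = series([5, 9, 6.5, 7.5, 8.5])
        cc, n = pairwise_cc(a, b, floor=5.0)
        assert n == 4  # g0 floored in both, dropped

    def test_too_few_usable_genes_rejected(self):
        a = series([5, 5, 5, 6])
        with pytest.raises(ValueError, match="need >= 3"):
            pairwise_cc(a, a, floor=5.0)

    def test_gene_subset_restriction(self):
        a = series([6, 7, 8, 9, 10])
        b = series([6, 7, 8, 9, 1000.0])
        full, _ = pairwise_cc(a, b, floor=5.0)
        sub, n = pairwise_cc(a, b, floor=5.0, gene_subset=["g0", "g1", "g2", "g3"])
        assert n == 4
        assert sub == pytest.approx(1.0)
        assert full < 1.0
        with pytest.raises(ValueError, match="unknown genes"):
            pairwise_cc(a, b, floor=5.0, gene_subset=["nope"])


class TestCorrelationMatrix:
    def make_expr(self, cols):
        return ExpressionMatrix(values=pd.DataFrame(cols), floor=5.0)

    def test_duplicate_column_fully_correlated(self):
        col = series([6, 7, 9, 12])
        expr = self.make_expr({"a": col, "b": col, "c": series([12, 9, 7, 6])})
        cc, n = correlation_matrix(expr)
        assert cc.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(cc), 1.0)
        assert cc.equals(cc.T)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(0)
        cols = {k: series(rng.uniform(5, 15, 30)) for k in "abcd"}
        expr = self.make_expr(cols)
        cc1, _ = correlation_matrix(expr, ["a", "b", "c", "d"])
        cc2, _ = correlation_matrix(expr, ["d", "b", "a", "c"])
        pd.testing.assert_frame_equal(cc1.loc[cc2.index, cc2.columns], cc2)

    def test_degenerate_pair_becomes_nan_with_warning(self):
        expr = self.make_expr({"a": series([5, 5, 5, 6]), "b": series([5, 5, 5, 6])})
        with pytest.warns(UserWarning, match="undefined"):
            cc, _ = correlation_matrix(expr)
        assert np.isnan(cc.loc["a", "b"])


class TestFoldChanges:
    def test_identity_and_shift(self):
        a = series([6, 7, 8])
        assert (fold_changes(a, a) == 0).all()
        assert (fold_changes(a + 1, a) == 1).all()

    def test_brute_force_elementwise(self):
        rng = np.random.default_rng(1)
        a = series(np.maximum(rng.normal(8, 2, 50), 5.0))
        b = series(np.maximum(rng.normal(8, 2, 50), 5.0))
        fc = fold_changes(a, b)
        for g in a.index[:10]:
            assert fc[g] == a[g] - b[g]

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            fold_changes(series([1, 2]), series([1, 2], prefix="x"))


class TestAgreement:
    def test_hand_enumerated_example(self):
        fc_ffpe = series([2.0, -1.5, 0.5, 3.0])
        fc_ff = series([0.1, -0.2, 5.0, -1.0])
        a = fc_agreement(fc_ffpe, fc_ff, threshold=2.0)
        assert (a.n_selected, a.n_agree) == (3, 2)
        assert a.fraction_agree == pytest.approx(2 / 3)

    def test_perfect_and_inverted_agreement(self):
        fc = series([2, -3, 1.5, -2.5])
        assert fc_agreement(fc, fc, 2.0).fraction_agree == 1.0
        assert fc_agreement(fc, -fc, 2.0).fraction_agree == 0.0

    def test_threshold_one_excludes_exact_zeros(self):
        fc_ffpe = series([0.0, 0.4, -0.2, 1.0])
        a = fc_agreement(fc_ffpe, fc_ffpe, threshold=1.0)
        assert a.n_selected == 3  # the both-floored zero gene is not selected

    def test_zero_ff_fold_change_counts_as_disagreement(self):
        fc_ffpe = series([2.0])
        fc_ff = series([0.0])
        assert fc_agreement(fc_ffpe, fc_ff, 2.0).fraction_agree == 0.0

    def test_no_selected_genes_flagged_as_undefined(self):
        a = fc_agreement(series([0.1, -0.1]), series([1, 1]), threshold=8.0)
        assert a.n_selected == 0 and a.fraction_agree is None

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            fc_agreement(series([1.0]), series([1.0]), threshold=0.5)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_ff_negation(self, seed):
        rng = np.random.default_rng(seed)
        fc_ffpe = series(rng.normal(0, 2, 40))
        fc_ff = series(rng.normal(0, 2, 40))  # continuous: no exact zeros
        f_pos = fc_agreement(fc_ffpe, fc_ff, 2.0).fraction_agree
        f_neg = fc_agreement(fc_ffpe, -fc_ff, 2.0).fraction_agree
        if f_pos is not None:
            assert f_pos + f_neg == pytest.approx(1.0)

    def test_sweep_denominators_nonincreasing(self):
        rng = np.random.default_rng(2)
        fc_ffpe = series(rng.normal(0, 2, 500))
        fc_ff = series(rng.normal(0, 2, 500))
        sweep = agreement_sweep(fc_ffpe, fc_ff)
        ns = [a.n_selected for a in sweep]
        assert ns == sorted(ns, reverse=True)
        assert [a.threshold for a in sweep] == list(range(1, 11))

    def test_identical_vectors_agree_at_every_threshold(self):
        rng = np.random.default_rng(3)
        fc = series(rng.normal(0, 4, 300))
        for a in agreement_sweep(fc, fc):
            assert a.fraction_agree == 1.0

    def test_non_ascending_thresholds_rejected(self):
        with pytest.raises(ValueError):
            agreement_sweep(series([1.0]), series([1.0]), thresholds=[2, 2])


class TestDEGenes:
    def make_groups(self, a, b):
        idx = pd.Index([f"g{i}" for i in range(a.shape[0])], name="gene_id")
        return (
            pd.DataFrame(a, index=idx, columns=[f"a{j}" for j in range(a.shape[1])]),
            pd.DataFrame(b, index=idx, columns=[f"b{j}" for j in range(b.shape[1])]),
        )

    def test_extreme_effect_always_selected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (200, 20))
        b = rng.normal(0, 1, (200, 20))
        a[0] += 10  # one gene shifted by 10 SDs
        ga, gb = self.make_groups(a, b)
        result = de_genes(ga, gb, fdr=0.001)
        assert "g0" in result.gene_ids

    def test_welch_t_matches_brute_force_formula(self):
        a = np.array([[1.0, 2.0, 3.0], [5.0, 5.5, 6.0], [0.0, 0.1, -0.1]])
        b = np.array([[2.0, 2.5, 4.0, 3.5], [5.2, 5.1, 5.3, 5.0], [1.0, 1.2, 0.8, 1.1]])
        ga, gb = self.make_groups(a, b)
        result = de_genes(ga, gb)
        for i in range(3):
            va, vb = a[i].var(ddof=1), b[i].var(ddof=1)
            t_expected = (a[i].mean() - b[i].mean()) / np.sqrt(va / 3 + vb / 4)
            assert result.table["t"].iloc[i] == pytest.approx(t_expected, abs=1e-10)

    def test_zero_variance_in_both_groups_gets_p_one(self):
        a = np.ones((2, 3))
        b = np.vstack([np.ones(3), [0.0, 1.0, 2.0]])
        ga, gb = self.make_groups(a, b)
        result = de_genes(ga, gb)
        assert result.table["p"].iloc[0] == 1.0

    def test_expressed_filter_drops_floored_genes(self):
        rng = np.random.default_rng(5)
        a = np.full((3, 4), 5.0)
        a[0] = rng.uniform(6, 8, 4)  # only g0 expressed
        ga, gb = self.make_groups(a, np.full((3, 4), 5.0))
        result = de_genes(ga, gb, floor=5.0)
        assert list(result.table.index) == ["g0"]

    def test_small_groups_rejected(self):
        ga, gb = self.make_groups(np.ones((2, 1)), np.ones((2, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            de_genes(ga, gb)


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force_bh(p):
        """Step-up: q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    @given(
        p=st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=1000,
        )
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), self.brute_force_bh(p), rtol=1e-10)
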