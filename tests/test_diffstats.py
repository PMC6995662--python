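"""SAM statistic/FDR, fold change, Bonferroni constants, correlation filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_two_class
from smokesig.diffstats import (
    bonferroni_cutoff,
    correlation_filter,
    fold_change,
    sam_fdr,
    sam_statistic,
    volcano_table,
    welch_pvalues,
)


class TestSamStatistic:
    def test_s0_zero_equals_pooled_t(self):
        """At s0=0 the SAM d is the classic equal-variance two-sample t."""
        X, labels = make_two_class(20, 8, 12, seed=1)
        d = sam_statistic(X, labels, s0=0.0)
        t_ref = stats.ttest_ind(
            X.to_numpy()[:, labels == 1].T, X.to_numpy()[:, labels == 0].T, equal_var=True
        ).statistic
        assert np.allclose(d, t_ref, atol=1e-10)

    def test_identical_class_values_give_zero(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                          [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]])
        labels = np.array([1, 1, 1, 0, 0, 0])
        d = sam_statistic(X, labels, s0=0.5)
        assert d[1] == 0.0

    def test_scale_equivariance_at_s0_zero(self):
        X, labels = make_two_class(10, 5, 5, seed=2)
        d1 = sam_statistic(X, labels, s0=0.0)
        d2 = sam_statistic(X * 7.3, labels, s0=0.0)
        assert np.allclose(d1, d2, atol=1e-10)

    def test_single_class_rejected(self):
        X, _ = make_two_class(5, 3, 3, seed=0)
        with pytest.raises(ValueError):
            sam_statistic(X, np.ones(6), s0=0.0)


class TestSamFdr:
    def test_planted_genes_detected_at_q10(self):
        """Power: with d=2 shifts at n=141, nearly all planted genes pass q<=0.1."""
        X, labels = make_two_class(2000, 82, 59, d_planted=2.0, n_planted=40, seed=3)
        res = sam_fdr(X, labels, n_permutations=300, seed=0)
        planted = res.index[:40]
        assert (res.loc[planted, "q"] <= 0.1).mean() >= 0.9

    def test_null_data_yields_no_discoveries(self):
        counts = []
        for seed in range(5):
            X, labels = make_two_class(1000, 40, 30, seed=100 + seed)
            res = sam_fdr(X, labels, n_permutations=200, seed=seed)
            counts.append(int((res["q"] <= 0.1).sum()))
        assert np.median(counts) == 0

    def test_invariant_to_coupled_sample_and_label_permutation(self):
        X, labels = make_two_class(50, 10, 10, d_planted=1.0, n_planted=5, seed=4)
        res1 = sam_fdr(X, labels, n_permutations=150, seed=5)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        res2 = sam_fdr(X.iloc[:, perm], labels[perm], n_permutations=150, seed=5)
        assert np.allclose(res1["q"], res2["q"])

    def test_q_invariant_to_gene_ordering(self):
        X, labels = make_two_class(60, 10, 10, d_planted=1.5, n_planted=6, seed=6)
        res1 = sam_fdr(X, labels, n_permutations=150, seed=1)
        perm = np.random.default_rng(1).permutation(X.shape[0])
        res2 = sam_fdr(X.iloc[perm], labels, n_permutations=150, seed=1)
        assert np.allclose(res1["q"].loc[res2.index], res2["q"])

    def test_q_monotone_in_abs_d(self):
        X, labels = make_two_class(200, 15, 15, d_planted=1.0, n_planted=30, seed=7)
        res = sam_fdr(X, labels, n_permutations=150, seed=2)
        srt = res.sort_values("d", key=np.abs, ascending=False)
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_too_few_distinct_permutations_warns(self):
        X, labels = make_two_class(5, 3, 3, seed=8)
        with pytest.warns(UserWarning, match="distinct permutations"):
            sam_fdr(X, labels, n_permutations=100, seed=0)


class TestFoldChangeAndVolcano:
    def test_fold_change_examples(self):
        X = pd.DataFrame([[8.0, 8.0, 2.0, 2.0], [3.0, 3.0, 3.0, 3.0], [1.0, 1.0, 0.0, 0.0]])
        labels = np.array([1, 1, 0, 0])
        fc = fold_change(X, labels)
        assert fc[0] == pytest.approx(4.0)
        assert np.log2(fc[0]) == pytest.approx(2.0)
        assert fc[1] == pytest.approx(1.0)
        assert np.isnan(fc[2])  # zero denominator -> missing, not infinite

    def test_welch_p_matches_hand_computed_formula(self):
        """Independent oracle: Welch statistic and Satterthwaite df by hand."""
        X, labels = make_two_class(20, 9, 11, d_planted=0.8, n_planted=5, seed=9)
        p = welch_pvalues(X, labels)
        A = X.to_numpy()[:, labels == 1]
        B = X.to_numpy()[:, labels == 0]
        va, vb = A.var(axis=1, ddof=1) / A.shape[1], B.var(axis=1, ddof=1) / B.shape[1]
        t = (A.mean(axis=1) - B.mean(axis=1)) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (A.shape[1] - 1) + vb**2 / (B.shape[1] - 1))
        p_ref = 2 * stats.t.sf(np.abs(t), df)
        assert np.allclose(p, p_ref, atol=1e-10)

    def test_volcano_table_columns_consistent(self):
        X, labels = make_two_class(30, 10, 10, seed=10)
        lin = np.exp2(X) - 1.0
        v = volcano_table(X, labels, linear_values=lin)
        assert np.allclose(v["neg_log10_p"], -np.log10(v["p"]), equal_nan=True)


class TestBonferroni:
    def test_genomewide_expression_cutoff(self):
        c = bonferroni_cutoff(21342, 0.05)
        assert float(f"{c.per_test_p:.2e}") == pytest.approx(2.34e-6)
        assert round(c.neg_log10, 2) == 5.63

    def test_copy_number_cutoff_exact_and_rounded_chains(self):
        c = bonferroni_cutoff(23494, 0.05)
        assert round(c.neg_log10, 2) == 5.67  # exact chain
        assert round(-np.log10(2.10e-6), 2) == 5.68  # reported rounded chain

    def test_single_test_and_exact_product(self):
        c = bonferroni_cutoff(1, 0.05)
        assert c.per_test_p == 0.05
        for n in (7, 100, 21342):
            c = bonferroni_cutoff(n, 0.05)
            assert c.per_test_p * n == pytest.approx(0.05, abs=0, rel=1e-15)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_cutoff(0)


def _exact_corr_pair(r, n, seed=0):
    """Two vectors whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonalize
    z /= z.std()
    y = r * x + np.sqrt(1 - r * r) * z
    return x, y


class TestCorrelationFilter:
    def _frames(self, pairs):
        genes = [f"G{i}" for i in range(len(pairs))]
        cols = [f"S{j}" for j in range(len(pairs[0][0]))]
        layer = pd.DataFrame([p[1] for p in pairs], index=genes, columns=cols)
        ge = pd.DataFrame([p[0] for p in pairs], index=genes, columns=cols)
        return layer, ge

    def test_perfect_anticorrelation_selected(self):
        x = np.arange(10.0)
        layer, ge = self._frames([(x, -x)])
        assert correlation_filter(layer, ge) == {"G0"}

    def test_threshold_boundary(self):
        pairs = [_exact_corr_pair(-0.49, 50, seed=1), _exact_corr_pair(-0.51, 50, seed=2)]
        layer, ge = self._frames(pairs)
        assert correlation_filter(layer, ge, threshold=0.5) == {"G1"}

    def test_sign_symmetric_membership(self):
        pairs = [_exact_corr_pair(0.8, 40, seed=3)]
        layer, ge = self._frames(pairs)
        assert correlation_filter(layer, ge) == {"G0"}
        layer_neg = -layer
        assert correlation_filter(layer_neg, ge) == {"G0"}

    def test_independent_layer_never_passes_at_cohort_size(self):
        # P(|r| > 0.5) at n=141 is ~1e-10 per gene; 2000 null genes select none
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(2000)]
        cols = [f"S{j}" for j in range(141)]
        layer = pd.DataFrame(rng.normal(size=(2000, 141)), index=genes, columns=cols)
        ge = pd.DataFrame(rng.normal(size=(2000, 141)), index=genes, columns=cols)
        assert correlation_filter(layer, ge) == set()

    def test_planted_cohort_me_genes_pass(self, default_cohort):
        _, (ge, me, cnv, samples, ann, truth) = default_cohort
        ge_log = np.log2(ge.values + 1.0)
        selected = correlation_filter(me.values, ge_log)
        hit = len(selected & truth.planted_me) / len(truth.planted_me)
        assert hit >= 0.95

    def test_insufficient_pairs_skipped_with_warning(self):
        layer = pd.DataFrame([[1.0, np.nan, np.nan, np.nan]], index=["G0"],
                             columns=["S0", "S1", "S2", "S3"])
        ge = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["G0"], columns=layer.columns)
        with pytest.warns(UserWarning, match="complete pairs"):
            assert correlation_filter(layer, ge) == set()
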