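"""Per-gene two-class statistics.

Implements the SAM (significance analysis of microarrays) moderated
t-statistic d = (mean1 - mean2) / (s + s0) with permutation-based q-values,
fold changes and volcano tables (Welch t-test), the Bonferroni family-wise
cutoff, and the |Pearson r| > 0.5 filter linking methylation / copy number
to expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _group_stats(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Means of each class and the pooled standard error term s_i.

    s_i = sqrt( (1/n1 + 1/n2) * (SS1 + SS2) / (n1 + n2 - 2) ), the classic
    gene-specific scatter of the two-sample t statistic.
    """
    g1 = labels == 1
    g0 = ~g1
    n1, n0 = int(g1.sum()), int(g0.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    m1 = X[:, g1].mean(axis=1)
    m0 = X[:, g0].mean(axis=1)
    ss1 = ((X[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((X[:, g0] - m0[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n0) * (ss1 + ss0) / (n1 + n0 - 2))
    return m1, m0, s


def tusher_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Exchangeability ('fudge') factor s0 by the percentile-scan procedure.

    Candidate s0 values are percentiles of {s_i}; for each candidate the
    genes are binned into windows of s and the coefficient of variation of
    the window-wise MAD of d is computed; the candidate minimizing that CV
    is returned.
    """
    qs = np.percentile(s, np.arange(0, 101, 5))
    edges = np.percentile(s, np.linspace(0, 100, 11))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)
    best, best_cv = 0.0, np.inf
    for s0 in qs:
        d = r / (s + s0)
        mads = []
        for b in range(10):
            sel = bins == b
            if sel.sum() >= 3:
                db = d[sel]
                mads.append(np.median(np.abs(db - np.median(db))) * 1.4826)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


def sam_statistic(
    X: np.ndarray | pd.DataFrame, labels: np.ndarray, s0: float | None = None
) -> np.ndarray:
    """SAM d-statistic per gene; ``s0=0`` reduces to the pooled-SE t statistic.

    ``s0=None`` selects s0 by :func:`tusher_s0`.
    """
    vals = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    m1, m0, s = _group_stats(vals, labels)
    r = m1 - m0
    if s0 is None:
        s0 = tusher_s0(r, s)
    return r / (s + s0)


def _permutation_labels(
    labels: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """A (n_permutations x n) array of label permutations preserving class sizes."""
    n = len(labels)
    n1 = int((labels == 1).sum())
    total = math.comb(n, n1)
    if total < n_permutations:
        warnings.warn(
            f"only {total} distinct permutations exist; using all of them",
            stacklevel=2,
        )
        perms = np.zeros((total, n), dtype=float)
        for i, pos in enumerate(combinations(range(n), n1)):
            perms[i, list(pos)] = 1.0
        return perms
    # index-based draws: the null depends only on (n, n1), so reordering
    # samples together with their labels leaves the q-values unchanged
    perms = np.zeros((n_permutations, n), dtype=float)
    for i in range(n_permutations):
        perms[i, rng.permutation(n)[:n1]] = 1.0
    return perms


def sam_fdr(
    X: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    s0: float | None = None,
    linear_values: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """SAM with permutation-null q-values.

    The observed d-statistics are compared with the pooled null distribution
    of d over label permutations (class sizes preserved); the resulting
    two-sided permutation p-values are converted to q-values by
    Benjamini-Hochberg. Columns: ``d``, ``numerator``, ``s``, ``p``, ``q``,
    ``fold_change``, ``rank`` (1 = largest |d|).

    ``linear_values`` (same shape, linear scale) feeds the fold-change
    column; if omitted the log2 input is exponentiated (log2(x+1) convention).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    vals = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=float)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(vals.shape[0])
    m1, m0, s = _group_stats(vals, labels)
    r = m1 - m0
    if s0 is None:
        s0 = tusher_s0(r, s)
    d_obs = r / (s + s0)

    rng = np.random.default_rng(seed)
    perms = _permutation_labels(labels, n_permutations, rng)  # B x n
    n1 = labels.sum()
    n0 = len(labels) - n1
    # evaluate the null on a canonical (content-sorted) sample ordering so the
    # q-values are exactly invariant to reordering samples with their labels;
    # the sort keys are row-order-invariant column summaries
    keys = np.vstack([(vals**3).sum(axis=0), (vals**2).sum(axis=0), vals.sum(axis=0)])
    canon = vals[:, np.lexsort(keys)]
    sum1 = canon @ perms.T  # genes x B
    sumsq1 = (canon**2) @ perms.T
    tot = canon.sum(axis=1)[:, None]
    totsq = (canon**2).sum(axis=1)[:, None]
    m1p = sum1 / n1
    m0p = (tot - sum1) / n0
    ss1 = sumsq1 - n1 * m1p**2
    ss0 = (totsq - sumsq1) - n0 * m0p**2
    sp = np.sqrt(np.maximum((1.0 / n1 + 1.0 / n0) * (ss1 + ss0) / (n1 + n0 - 2), 0.0))
    d_null = (m1p - m0p) / (sp + s0)

    null_abs = np.sort(np.abs(d_null), axis=None)
    n_null = null_abs.size
    ge_count = n_null - np.searchsorted(null_abs, np.abs(d_obs), side="left")
    p = (1.0 + ge_count) / (1.0 + n_null)
    q = multipletests(p, method="fdr_bh")[1]

    if linear_values is None:
        lin = np.exp2(vals) - 1.0
    else:
        lin = np.asarray(linear_values, dtype=float)
    fc = _fold_change_from_linear(lin, labels)

    order = np.argsort(-np.abs(d_obs), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    return pd.DataFrame(
        {
            "d": d_obs,
            "numerator": r,
            "s": s,
            "p": p,
            "q": q,
            "fold_change": fc,
            "rank": rank,
        },
        index=index,
    )


def _fold_change_from_linear(lin: np.ndarray, labels: np.ndarray) -> np.ndarray:
    g1 = labels == 1
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(lin[:, g1], axis=1)
        m0 = np.nanmean(lin[:, ~g1], axis=1)
    fc = np.full(lin.shape[0], np.nan)
    ok = m0 != 0
    fc[ok] = m1[ok] / m0[ok]
    return fc


def fold_change(X_linear: np.ndarray | pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """Per-gene linear-scale fold change, class 1 over class 0.

    A zero class-0 mean yields a missing value rather than an infinity.
    """
    lin = np.asarray(X_linear, dtype=float)
    index = X_linear.index if isinstance(X_linear, pd.DataFrame) else None
    return pd.Series(_fold_change_from_linear(lin, np.asarray(labels)), index=index, name="fold_change")


def welch_pvalues(X: np.ndarray | pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    """Two-sided Welch (unequal-variance) t-test p-value per gene."""
    vals = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    g1 = labels == 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(
            vals[:, g1], vals[:, ~g1], axis=1, equal_var=False, nan_policy="omit"
        )
    return np.asarray(res.pvalue)


def volcano_table(
    X_log: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    linear_values: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene (log2 fold change, -log10 p) for volcano plotting.

    The fold change is computed on the linear scale (``linear_values`` if
    given, otherwise by inverting the log2(x+1) convention); p-values come
    from Welch's t-test on the log-scale values.
    """
    vals = np.asarray(X_log, dtype=float)
    index = X_log.index if isinstance(X_log, pd.DataFrame) else pd.RangeIndex(vals.shape[0])
    lin = np.exp2(vals) - 1.0 if linear_values is None else np.asarray(linear_values, dtype=float)
    fc = _fold_change_from_linear(lin, np.asarray(labels))
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)
    p = welch_pvalues(vals, labels)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    return pd.DataFrame(
        {"log2_fold_change": log2fc, "p": p, "neg_log10_p": nlp}, index=index
    )


@dataclass(frozen=True)
class BonferroniCutoff:
    """Family-wise per-test threshold alpha / n_tests and its -log10."""

    n_tests: int
    alpha: float
    per_test_p: float
    neg_log10: float


def bonferroni_cutoff(n_tests: int, alpha: float = 0.05) -> BonferroniCutoff:
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    per_test = alpha / n_tests
    return BonferroniCutoff(n_tests, alpha, per_test, -math.log10(per_test))


def correlation_filter(
    layer: pd.DataFrame, ge: pd.DataFrame, threshold: float = 0.5
) -> set[str]:
    """Genes whose layer values correlate with their own expression.

    Pearson r is computed per gene across pairwise-complete shared samples;
    genes with |r| > ``threshold`` are returned. Genes with fewer than three
    complete pairs are skipped with a warning. Both frames are genes x
    samples, matched by symbol and sample id.
    """
    common_genes = [g for g in layer.index if g in set(ge.index)]
    common_samples = [s for s in layer.columns if s in set(ge.columns)]
    selected: set[str] = set()
    skipped = []
    L = layer.loc[common_genes, common_samples].to_numpy(dtype=float)
    G = ge.loc[common_genes, common_samples].to_numpy(dtype=float)
    for i, g in enumerate(common_genes):
        ok = np.isfinite(L[i]) & np.isfinite(G[i])
        if ok.sum() < 3:
            skipped.append(g)
            continue
        x, y = L[i, ok], G[i, ok]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if abs(r) > threshold:
            selected.add(g)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} genes with <3 complete pairs", stacklevel=2
        )
    return selected
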