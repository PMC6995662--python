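"""Linear PLS1 discriminant modeling via NIPALS.

The classifier regresses a 0/1 class label on autoscaled gene values through
a small number of latent components. The per-gene regression coefficient
vector ``b`` is the model's "contribution" measure: genes are ranked by |b|
for backward elimination.

For a single response the NIPALS weight vector at each step is simply the
(normalized) covariance X'y of the deflated matrix, so fitting is exact and
deterministic; successive score vectors are mutually orthogonal, and with as
many components as the predictor rank the coefficients coincide with
ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ClassificationMetrics, confusion, stratified_kfold


@dataclass
class PLSModel:
    n_components: int
    gene_symbols: list[str]
    W: np.ndarray  # p x A weights, unit norm columns
    P: np.ndarray  # p x A X-loadings
    q: np.ndarray  # A, y-loadings
    coef: np.ndarray  # p, regression coefficients on the autoscaled data
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    class_encoding: dict = field(default_factory=lambda: {"never": 0, "current": 1})
    scores: np.ndarray | None = None  # n x A training scores

    def to_dict(self) -> dict:
        return {
            "kind": "pls",
            "n_components": self.n_components,
            "gene_symbols": list(self.gene_symbols),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "class_encoding": self.class_encoding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_components=d["n_components"],
            gene_symbols=list(d["gene_symbols"]),
            W=np.asarray(d["W"]),
            P=np.asarray(d["P"]),
            q=np.asarray(d["q"]),
            coef=np.asarray(d["coef"]),
            x_mean=np.asarray(d["x_mean"]),
            x_scale=np.asarray(d["x_scale"]),
            y_mean=d["y_mean"],
            class_encoding=d.get("class_encoding", {"never": 0, "current": 1}),
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[1])]


def fit_pls(X, y, n_components: int = 2, scale: bool = True) -> PLSModel:
    """Fit a PLS1 discriminant model on a samples x genes matrix.

    X is centered and (by default) scaled to unit variance; y (0/1) is
    centered. Zero-variance genes are dropped with a warning; a component
    count exceeding the predictor rank is truncated with a warning.
    """
    vals, genes = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = vals.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    x_mean = vals.mean(axis=0)
    x_scale = vals.std(axis=0, ddof=1) if scale else np.ones(p)
    keep = x_scale > 0 if scale else vals.std(axis=0, ddof=1) > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"dropped {len(dropped)} zero-variance genes: {dropped[:5]}", stacklevel=2)
        vals = vals[:, keep]
        genes = [g for g, k in zip(genes, keep) if k]
        x_mean, x_scale = x_mean[keep], x_scale[keep]
        p = vals.shape[1]
        if p == 0:
            raise ValueError("no genes with nonzero variance")
    if not scale:
        x_scale = np.ones(p)

    A = min(n_components, p, n - 1)
    if A < n_components:
        warnings.warn(
            f"n_components truncated from {n_components} to {A}", stacklevel=2
        )
    Xc = (vals - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    a = 0
    for _ in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            warnings.warn(
                f"n_components truncated to rank {a}", stacklevel=2
            )
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_a = Xc.T @ t / tt
        q_a = float(yc @ t / tt)
        Xc -= np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        a += 1
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=a,
        gene_symbols=genes,
        W=W,
        P=P,
        q=q,
        coef=coef,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        scores=T,
    )


def _align(model_genes: list[str], X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [g for g in model_genes if g not in X.columns]
        if missing:
            raise ValueError(f"new data lacks model genes: {missing[:10]}")
        return X[model_genes].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model_genes):
        raise ValueError(
            f"expected {len(model_genes)} gene columns, got {X.shape[1]}"
        )
    return X


def predict_pls(model: PLSModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Continuous score and hard class (score >= 0.5 under the 0/1 encoding)."""
    vals = _align(model.gene_symbols, X_new)
    score = (vals - model.x_mean) / model.x_scale @ model.coef + model.y_mean
    return score, (score >= 0.5).astype(int)


def contributions(model: PLSModel) -> pd.Series:
    """|coefficient| per gene, sorted descending; ties broken by symbol."""
    s = pd.Series(np.abs(model.coef), index=model.gene_symbols, name="contribution")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def cv_predict(
    X, y, n_components: int, folds: np.ndarray, scale: bool = True
) -> np.ndarray:
    """Out-of-fold hard predictions for a fixed fold assignment."""
    vals, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    pred = np.empty(len(y), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in np.unique(folds):
            tr = folds != f
            model = fit_pls(vals[tr], y[tr], n_components, scale=scale)
            # fit_pls may drop zero-variance genes; symbols are column indices here
            keep = [int(g) for g in model.gene_symbols]
            _, cls = predict_pls(model, vals[~tr][:, keep])
            pred[~tr] = cls
    return pred


def cv_metrics(
    X, y, n_components: int, folds: np.ndarray, scale: bool = True
) -> ClassificationMetrics:
    return confusion(np.asarray(y, dtype=int), cv_predict(X, y, n_components, folds, scale))


def select_n_components(
    X, y, max_components: int = 10, k: int = 5, seed: int = 0, folds: np.ndarray | None = None
) -> int:
    """Component count maximizing stratified k-fold CV accuracy (ties: smallest)."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    vals, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if folds is None:
        folds = stratified_kfold(y, k=k, seed=seed)
    upper = min(max_components, vals.shape[1], len(y) - 1)
    best_a, best_acc = 1, -1.0
    for a in range(1, upper + 1):
        acc = cv_metrics(vals, y, a, folds).accuracy
        if acc > best_acc + 1e-12:
            best_a, best_acc = a, acc
    return best_a
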