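"""Kernel PLS classification (Rosipal-Trejo formulation).

The predictors are autoscaled exactly as in the linear model, a Gram matrix
K is formed from a kernel (linear, RBF or polynomial), double-centered in
feature space, and PLS1 components are extracted on the centered kernel.
With the linear kernel the predictions coincide with linear PLS at the same
component count, which anchors the implementation's correctness.

Feature-space centering uses the standard identities

    K_c      = H K H,                      H = I - (1/n) 1 1'
    K_test_c = (K_t - (1/n) 1_t 1' K) H

applied to the training and test Gram matrices respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ClassificationMetrics, confusion, stratified_kfold
from .pls import _as_matrix


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    ``gamma`` defaults to 1/p (set at fit time when None). ``degree`` and
    ``coef0`` apply to the polynomial kernel only.
    """

    kind: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("degree must be >= 1")

    def resolve(self, p: int) -> "KernelSpec":
        if self.kind != "linear" and self.gamma is None:
            return KernelSpec(self.kind, 1.0 / p, self.degree, self.coef0)
        return self

    def complexity(self) -> tuple:
        """Sort key for the tie rule: linear < rbf (gamma ascending) < polynomial."""
        order = {"linear": 0, "rbf": 1, "polynomial": 2}
        return (order[self.kind], self.gamma or 0.0, self.degree)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "gamma": self.gamma, "degree": self.degree, "coef0": self.coef0}


def gram_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """K[i, j] = k(a_i, b_j) for row-vector samples; symmetric PSD when A is B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"gene dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    spec = spec.resolve(A.shape[1])
    if spec.kind == "linear":
        return A @ B.T
    if spec.kind == "rbf":
        d2 = (
            (A**2).sum(axis=1)[:, None]
            + (B**2).sum(axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-spec.gamma * np.maximum(d2, 0.0))
    return (spec.gamma * (A @ B.T) + spec.coef0) ** spec.degree


@dataclass
class KPLSModel:
    kernel: KernelSpec
    n_components: int
    X_train: np.ndarray  # autoscaled training inputs, for kernel evaluation
    K_train: np.ndarray  # uncentered training Gram matrix
    T: np.ndarray  # n x A orthonormal scores
    U: np.ndarray  # n x A y-side scores
    dual_coef: np.ndarray  # n, so that yhat = K_test_centered @ dual_coef + y_mean
    gene_symbols: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    class_encoding: dict = field(default_factory=lambda: {"never": 0, "current": 1})

    def to_dict(self) -> dict:
        return {
            "kind": "kpls",
            "kernel": self.kernel.to_dict(),
            "n_components": self.n_components,
            "gene_symbols": list(self.gene_symbols),
            "X_train": self.X_train.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "class_encoding": self.class_encoding,
        }


def center_train_kernel(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    return H @ K @ H


def center_test_kernel(K_test: np.ndarray, K_train: np.ndarray) -> np.ndarray:
    n = K_train.shape[0]
    ones_row = K_train.mean(axis=0)[None, :]  # (1/n) 1' K
    Kc = K_test - ones_row
    return Kc - Kc.mean(axis=1, keepdims=True)


def fit_kpls(X, y, kernel: KernelSpec = KernelSpec(), n_components: int = 2) -> KPLSModel:
    """Fit a kernel PLS1 classifier on a samples x genes matrix."""
    vals, genes = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = vals.shape
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    x_mean = vals.mean(axis=0)
    x_scale = vals.std(axis=0, ddof=1)
    keep = x_scale > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance genes", stacklevel=2)
        vals, x_mean, x_scale = vals[:, keep], x_mean[keep], x_scale[keep]
        genes = [g for g, k in zip(genes, keep) if k]
    Xs = (vals - x_mean) / x_scale
    spec = kernel.resolve(Xs.shape[1])
    K = gram_matrix(Xs, Xs, spec)
    Kc = center_train_kernel(K)
    y_mean = float(y.mean())
    yc = y - y_mean

    A = min(n_components, n - 1)
    if A < n_components:
        warnings.warn(f"n_components truncated from {n_components} to {A}", stacklevel=2)
    Kd = Kc.copy()
    yd = yc.copy()
    T = np.zeros((n, A))
    U = np.zeros((n, A))
    a = 0
    for _ in range(A):
        ny = np.linalg.norm(yd)
        if ny < 1e-12:
            break
        u = yd / ny
        t = Kd @ u
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            break
        t /= nt
        proj = np.eye(n) - np.outer(t, t)
        Kd = proj @ Kd @ proj
        yd = yd - t * float(t @ yd)
        T[:, a], U[:, a] = t, u
        a += 1
    T, U = T[:, :a], U[:, :a]
    M = T.T @ Kc @ U  # A x A
    dual = U @ np.linalg.solve(M, T.T @ yc)
    return KPLSModel(
        kernel=spec,
        n_components=a,
        X_train=Xs,
        K_train=K,
        T=T,
        U=U,
        dual_coef=dual,
        gene_symbols=genes,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
    )


def predict_kpls(model: KPLSModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Continuous score and hard class for new samples."""
    if isinstance(X_new, pd.DataFrame):
        missing = [g for g in model.gene_symbols if g not in X_new.columns]
        if missing:
            raise ValueError(f"new data lacks model genes: {missing[:10]}")
        vals = X_new[model.gene_symbols].to_numpy(dtype=float)
    else:
        vals = np.asarray(X_new, dtype=float)
        if vals.shape[1] != len(model.gene_symbols):
            raise ValueError(
                f"expected {len(model.gene_symbols)} gene columns, got {vals.shape[1]}"
            )
    Xs = (vals - model.x_mean) / model.x_scale
    Kt = gram_matrix(Xs, model.X_train, model.kernel)
    Ktc = center_test_kernel(Kt, model.K_train)
    score = Ktc @ model.dual_coef + model.y_mean
    return score, (score >= 0.5).astype(int)


def cv_metrics_kpls(
    X, y, kernel: KernelSpec, n_components: int, folds: np.ndarray
) -> ClassificationMetrics:
    """Pooled out-of-fold confusion metrics for a fixed fold assignment."""
    vals, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    pred = np.empty(len(y), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in np.unique(folds):
            tr = folds != f
            model = fit_kpls(vals[tr], y[tr], kernel, n_components)
            keep = [int(g) for g in model.gene_symbols]
            _, cls = predict_kpls(model, vals[~tr][:, keep])
            pred[~tr] = cls
    return confusion(y.astype(int), pred)


def default_kernel_grid(p: int) -> list[KernelSpec]:
    """Linear plus an RBF gamma grid {2^k / p, k = -3..3}."""
    grid = [KernelSpec("linear")]
    grid += [KernelSpec("rbf", gamma=(2.0**k) / p) for k in range(-3, 4)]
    return grid


def tune_kernel(
    X,
    y,
    grid: list[KernelSpec] | None = None,
    max_components: int = 5,
    k: int = 5,
    seed: int = 0,
) -> tuple[KernelSpec, int]:
    """Grid search over kernels and component counts by stratified CV accuracy.

    Ties prefer the simplest kernel (linear first, then RBF with ascending
    gamma), then the smallest component count.
    """
    vals, _ = _as_matrix(X)
    if grid is None:
        grid = default_kernel_grid(vals.shape[1])
    if not grid:
        raise ValueError("kernel grid is empty")
    y = np.asarray(y, dtype=float)
    folds = stratified_kfold(y, k=k, seed=seed)
    candidates = []
    for spec in grid:
        spec = spec.resolve(vals.shape[1])
        for a in range(1, min(max_components, len(y) - 1) + 1):
            acc = cv_metrics_kpls(vals, y, spec, a, folds).accuracy
            candidates.append((-acc, spec.complexity(), a, spec))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, best_a, best_spec = candidates[0]
    return best_spec, best_a
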