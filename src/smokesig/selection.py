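"""Integrated three-stage signature-gene identification.

Stage 1 (statistical): expression candidates by SAM q <= 0.1; methylation /
copy-number candidates by |Pearson r| > 0.5 between the layer and the gene's
own expression.

Stage 2 (experimental): a curated gene list is merged into the candidates so
literature-supported genes are not overwhelmed by the genome-wide pool.

Stage 3 (iterative contribution selection): a linear PLS classifier is fit
on the remaining genes, genes are ranked by |regression coefficient|, the
least important gene is removed, and seeded stratified 5-fold CV accuracy is
recorded; removal repeats until accuracy has not improved for ``patience``
consecutive removals (or two genes remain). The returned signature is the
gene set at the best-accuracy iteration, with ties resolved toward fewer
genes. A kernel PLS model is then fit on the signature to squeeze out any
remaining nonlinear accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffstats import correlation_filter, sam_fdr
from .evaluation import ClassificationMetrics, confusion, stratified_kfold
from .kpls import KernelSpec, KPLSModel, cv_metrics_kpls, fit_kpls, predict_kpls, tune_kernel
from .pls import PLSModel, contributions, cv_metrics, fit_pls, predict_pls, select_n_components


@dataclass
class SelectionConfig:
    """Tunable parameters of the three-stage identification."""

    fdr_threshold: float = 0.1
    corr_threshold: float = 0.5
    sam_permutations: int = 1000
    sam_seed: int = 0
    cv_k: int = 5
    cv_seed: int = 0
    patience: int = 10
    max_components: int = 10
    kernel_grid: list[KernelSpec] | None = None
    kpls_max_components: int = 5


@dataclass
class SignatureSet:
    layer: str
    genes: list[str]
    cv_metrics: ClassificationMetrics | None = None
    validation_metrics: ClassificationMetrics | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "layer": self.layer,
            "genes": list(self.genes),
            "cv_metrics": self.cv_metrics.to_dict() if self.cv_metrics else None,
            "validation_metrics": (
                self.validation_metrics.to_dict() if self.validation_metrics else None
            ),
            "provenance": self.provenance,
        }


def statistical_candidates(
    layer_matrix: pd.DataFrame,
    ge_matrix: pd.DataFrame,
    labels: np.ndarray,
    layer: str,
    config: SelectionConfig = SelectionConfig(),
) -> set[str]:
    """Stage-1 candidates: SAM for GE, expression-correlation for ME/CNV.

    Matrices are genes x samples, preprocessed and imputed.
    """
    if layer == "GE":
        sam = sam_fdr(
            layer_matrix,
            labels,
            n_permutations=config.sam_permutations,
            seed=config.sam_seed,
        )
        cand = set(sam.index[sam["q"] <= config.fdr_threshold])
    else:
        cand = correlation_filter(layer_matrix, ge_matrix, threshold=config.corr_threshold)
    if not cand:
        raise ValueError(
            f"no stage-1 candidates for layer {layer}; consider relaxing the "
            f"{'FDR' if layer == 'GE' else 'correlation'} threshold"
        )
    return cand


def merge_experimental(
    candidates: set[str], curated: list[str], universe: set[str]
) -> tuple[set[str], list[str]]:
    """Union candidates with curated genes present in the data universe.

    Returns (merged set, curated genes actually injected). Curated genes
    absent from the universe are skipped with a warning.
    """
    present = [g for g in curated if g in universe]
    absent = [g for g in curated if g not in universe]
    if absent:
        warnings.warn(
            f"{len(absent)} curated genes absent from the data and skipped: {absent[:10]}",
            stacklevel=2,
        )
    injected = [g for g in present if g not in candidates]
    return candidates | set(present), injected


def iterative_elimination(
    X: pd.DataFrame,
    y: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Backward elimination by PLS coefficient magnitude under 5-fold CV.

    ``X`` is samples x candidate genes (imputed). Returns the selection
    trace (one row per iteration: removed gene, remaining count, CV
    accuracy/sensitivity/specificity, components used) and the best gene
    set. The trace's iteration 0 is the full candidate model.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate genes")
    y = np.asarray(y, dtype=float)
    folds = stratified_kfold(y, k=config.cv_k, seed=config.cv_seed)
    genes = list(X.columns)
    rows = []
    best_acc = -np.inf
    best_set = list(genes)
    since_best = 0
    removed = None
    iteration = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while True:
            sub = X[genes].to_numpy(dtype=float)
            a = select_n_components(
                sub, y, max_components=min(config.max_components, len(genes)), folds=folds
            )
            m = cv_metrics(sub, y, a, folds)
            rows.append(
                {
                    "iteration": iteration,
                    "removed_gene": removed,
                    "remaining_count": len(genes),
                    "cv_accuracy": m.accuracy,
                    "cv_sensitivity": m.sensitivity,
                    "cv_specificity": m.specificity,
                    "n_components": a,
                    "fold_seed": config.cv_seed,
                }
            )
            if m.accuracy > best_acc + 1e-12:
                best_acc = m.accuracy
                best_set = list(genes)
                since_best = 0
            else:
                if m.accuracy >= best_acc - 1e-12:
                    # tie with the running best: prefer the smaller set
                    best_set = list(genes)
                since_best += 1
            if len(genes) <= 2 or since_best >= config.patience:
                break
            model = fit_pls(X[genes], y, a)
            ranking = contributions(model)
            removed = ranking.index[-1]
            genes = [g for g in genes if g != removed]
            iteration += 1
    trace = pd.DataFrame(rows)
    return trace, best_set


@dataclass
class LayerRunResult:
    signature: SignatureSet
    trace: pd.DataFrame
    pls_model: PLSModel
    kpls_model: KPLSModel
    kpls_cv_metrics: ClassificationMetrics
    resubstitution_metrics: ClassificationMetrics
    kpls_validation_metrics: ClassificationMetrics | None = None


def run_layer(
    layer: str,
    X: pd.DataFrame,
    ge: pd.DataFrame,
    labels: np.ndarray,
    curated: list[str] | None = None,
    config: SelectionConfig = SelectionConfig(),
    X_validation: pd.DataFrame | None = None,
    y_validation: np.ndarray | None = None,
) -> LayerRunResult:
    """End-to-end identification for one omics layer.

    ``X`` and ``ge`` are genes x samples training matrices (transformed and
    imputed); ``X_validation`` is an independent cohort on the same genes.
    The three selection stages run strictly on the training cohort; the
    validation cohort is only ever scored.
    """
    y = np.asarray(labels, dtype=float)
    candidates = statistical_candidates(X, ge, y, layer, config)
    curated = curated or []
    merged, injected = merge_experimental(candidates, curated, set(X.index))
    ordered = [g for g in X.index if g in merged]
    Xt = X.loc[ordered].T  # samples x genes
    trace, signature_genes = iterative_elimination(Xt, y, config)

    folds = stratified_kfold(y, k=config.cv_k, seed=config.cv_seed)
    Xsig = Xt[signature_genes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = select_n_components(
            Xsig, y, max_components=min(config.max_components, len(signature_genes)), folds=folds
        )
        pls_model = fit_pls(Xsig, y, a)
        pls_cv = cv_metrics(Xsig.to_numpy(dtype=float), y, a, folds)
        kspec, ka = tune_kernel(
            Xsig,
            y,
            grid=config.kernel_grid,
            max_components=config.kpls_max_components,
            k=config.cv_k,
            seed=config.cv_seed,
        )
        kpls_model = fit_kpls(Xsig, y, kspec, ka)
        kpls_cv = cv_metrics_kpls(Xsig.to_numpy(dtype=float), y, kspec, ka, folds)
        _, resub_pred = predict_kpls(kpls_model, Xsig)
    resub = confusion(y.astype(int), resub_pred)

    validation = None
    kpls_validation = None
    if X_validation is not None:
        if y_validation is None:
            raise ValueError("y_validation required with X_validation")
        Xv = X_validation.loc[signature_genes].T
        yv = np.asarray(y_validation, dtype=int)
        _, pred = predict_pls(pls_model, Xv)
        validation = confusion(yv, pred)
        _, kpred = predict_kpls(kpls_model, Xv)
        kpls_validation = confusion(yv, kpred)

    signature = SignatureSet(
        layer=layer,
        genes=signature_genes,
        cv_metrics=pls_cv,
        validation_metrics=validation,
        provenance={
            "n_stage1_candidates": len(candidates),
            "curated_injected": injected,
            "n_candidates_after_merge": len(merged),
            "pls_components": a,
            "kernel": kspec.to_dict(),
            "kpls_components": ka,
        },
    )
    return LayerRunResult(
        signature=signature,
        trace=trace,
        pls_model=pls_model,
        kpls_model=kpls_model,
        kpls_cv_metrics=kpls_cv,
        resubstitution_metrics=resub,
        kpls_validation_metrics=kpls_validation,
    )
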