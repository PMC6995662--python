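"""Reading and preprocessing of omics tables.

Applies the study's preprocessing rules: unknown-symbol filtering, removal of
genes missing in all samples (partially missing genes are kept), log2
transform for expression and log2(CNV/2) for copy numbers, promoter-mean
aggregation of methylation probes, removal of samples lacking clinical
covariates, and the train/validation gene intersection.

Coordinates are 1-based inclusive. Missing cells in TSV input are empty
strings or one of ``NA``, ``NaN``, ``null``. All readers accept gzip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLINICAL_FIELDS, OmicsMatrix, validate_annotation, validate_sample_table

_NA_TOKENS = ["", "NA", "NaN", "nan", "null"]


class ParseError(ValueError):
    """A malformed input table; the message names the offending row/column."""


def load_omics(path: str | Path, layer: str) -> OmicsMatrix:
    """Read a genes x samples TSV (first column = symbol, header = sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=_NA_TOKENS, keep_default_na=False
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: header row has no sample columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene symbols {dups[:5]}")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ParseError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
                )
            df[col] = coerced
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.index.name = "symbol"
    df.columns.name = "sample_id"
    return OmicsMatrix(layer, df)


def write_omics(m: OmicsMatrix, path: str | Path) -> Path:
    path = Path(path)
    m.values.to_csv(path, sep="\t", na_rep="NA")
    return path


def load_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_TOKENS, keep_default_na=False)
    table.index = table.index.astype(str)
    return validate_sample_table(table)


def load_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    ann.index = ann.index.astype(str)
    return validate_annotation(ann)


def filter_genes(m: OmicsMatrix, valid_symbols: set[str] | None = None) -> OmicsMatrix:
    """Keep genes with a recognized symbol and at least one observed value.

    Genes missing in *all* samples are removed; genes missing in only part of
    the samples are retained.
    """
    keep = m.values.notna().any(axis=1)
    if valid_symbols is not None:
        keep &= m.values.index.isin(valid_symbols)
    return OmicsMatrix(m.layer, m.values.loc[keep].copy(), m.transformed)


def intersect_common_genes(train: OmicsMatrix, validation: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both cohorts to their shared genes, in the training order."""
    if train.layer != validation.layer:
        raise ValueError(f"layer mismatch: {train.layer} vs {validation.layer}")
    common = [g for g in train.gene_symbols if g in set(validation.gene_symbols)]
    if not common:
        raise ValueError("no genes shared between training and validation cohorts")
    return (
        OmicsMatrix(train.layer, train.values.loc[common].copy(), train.transformed),
        OmicsMatrix(validation.layer, validation.values.loc[common].copy(), validation.transformed),
    )


def transform_ge(m: OmicsMatrix) -> OmicsMatrix:
    """log2(x + 1) transform of linear-scale expression (tolerates zeros)."""
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        bad = m.values.index[(m.values < 0).any(axis=1)].tolist()
        raise ValueError(f"negative expression values for genes: {bad[:5]}")
    return OmicsMatrix(m.layer, np.log2(m.values + 1.0), transformed=True)


def transform_cnv(m: OmicsMatrix) -> OmicsMatrix:
    """log2(CNV/2) transform: diploid 2 -> 0, single copy 1 -> -1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        nonpos = (m.values <= 0).any(axis=1)
    if nonpos.any():
        bad = m.values.index[nonpos].tolist()
        raise ValueError(f"nonpositive copy numbers for genes: {bad[:5]}")
    return OmicsMatrix(m.layer, np.log2(m.values / 2.0), transformed=True)


def inverse_transform_cnv(m: OmicsMatrix) -> OmicsMatrix:
    return OmicsMatrix(m.layer, 2.0 * np.exp2(m.values), transformed=False)


def aggregate_promoter_me(
    probe_values: pd.DataFrame, probe_positions: pd.DataFrame, ann: pd.DataFrame
) -> OmicsMatrix:
    """Mean beta over probes inside each gene's promoter interval.

    ``probe_values`` is probes x samples; ``probe_positions`` has columns
    ``chromosome`` and ``position`` indexed by probe id. Genes without any
    promoter probe are absent from the output; missing probe values are
    excluded from the mean.
    """
    validate_annotation(ann)
    rows = {}
    pos = probe_positions
    for symbol, gene in ann.iterrows():
        on_chrom = pos.index[
            (pos["chromosome"] == gene["chromosome"])
            & (pos["position"] >= gene["promoter_start"])
            & (pos["position"] <= gene["promoter_end"])
        ]
        hit = [p for p in on_chrom if p in probe_values.index]
        if hit:
            rows[symbol] = probe_values.loc[hit].mean(axis=0, skipna=True)
    if not rows:
        return OmicsMatrix("ME", pd.DataFrame(columns=probe_values.columns, dtype=float))
    out = pd.DataFrame(rows).T
    out.index.name = "symbol"
    return OmicsMatrix("ME", out)


def filter_samples(
    samples: pd.DataFrame, *matrices: OmicsMatrix
) -> tuple[pd.DataFrame, ...]:
    """Drop samples lacking any of age, gender, stage or vital status.

    Surviving samples keep their original order in the table and in every
    matrix.
    """
    validate_sample_table(samples)
    keep = samples[list(CLINICAL_FIELDS)].notna().all(axis=1)
    kept = samples.loc[keep]
    out = [kept]
    for m in matrices:
        cols = [s for s in m.sample_ids if s in set(kept.index)]
        out.append(OmicsMatrix(m.layer, m.values[cols].copy(), m.transformed))
    return tuple(out)


def impute_train_mean(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Per-gene mean imputation with means computed on the training split only.

    Input frames are genes x samples and must share the gene index. Genes
    with no observed training value are filled with 0 (they carry no signal).
    """
    means = train.mean(axis=1, skipna=True).fillna(0.0)
    out = [train.apply(lambda col: col.fillna(means))]
    for o in others:
        if not o.index.equals(train.index):
            raise ValueError("imputation requires matching gene indices")
        out.append(o.apply(lambda col: col.fillna(means)))
    return tuple(out)


def prepare_layer(
    layer: str,
    ge: OmicsMatrix,
    me: OmicsMatrix,
    cnv: OmicsMatrix,
    samples: pd.DataFrame,
    classes: tuple[str, str] = ("never", "current"),
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Standard preprocessing for one classification run.

    Returns ``(X_layer, X_ge_log, y)`` where the matrices are genes x samples,
    transformed (GE: log2(x+1); CNV: log2(x/2); ME: beta scale as-is),
    gene-filtered, imputed with per-gene means, and restricted to samples of
    the two requested smoking classes; ``y`` is 1 for the second class
    (smokers by default).
    """
    keep = samples["smoking"].isin(classes)
    ids = list(samples.index[keep])
    if not ids:
        raise ValueError(f"no samples in classes {classes}")
    y = (samples.loc[ids, "smoking"] == classes[1]).to_numpy(dtype=float)

    ge_t = transform_ge(filter_genes(ge))
    layer_map = {"GE": ge_t, "ME": filter_genes(me), "CNV": None}
    if layer == "CNV":
        layer_map["CNV"] = transform_cnv(filter_genes(cnv))
    X = layer_map[layer]
    Xv = X.values[ids]
    gev = ge_t.values[ids]
    # align the layer with GE on shared genes for downstream correlation use
    common = [g for g in Xv.index if g in set(gev.index)]
    Xv = Xv.loc[common]
    gev = gev.loc[common]
    (Xv,) = impute_train_mean(Xv)
    (gev,) = impute_train_mean(gev)
    return Xv, gev, y
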