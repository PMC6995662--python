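"""In-memory containers for the three omics layers and their metadata.

Matrices are genes x samples throughout; missing values are ``NaN`` in the
underlying :class:`pandas.DataFrame` and exposed through ``missing_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("GE", "ME", "CNV")

#: Tobacco-exposure categories (CDC definitions used by the study design).
SMOKING_CATEGORIES = ("never", "current", "former", "ever")

#: Required clinical covariates; samples lacking any of them are dropped.
CLINICAL_FIELDS = ("age", "gender", "stage", "vital_status")


@dataclass
class OmicsMatrix:
    """One omics layer: a genes x samples numeric table with a missing mask.

    Parameters
    ----------
    layer:
        One of ``GE`` (log-scale or linear expression), ``ME`` (methylation
        beta values in [0, 1]) or ``CNV`` (raw copy numbers, baseline 2 on
        autosomes).
    values:
        DataFrame indexed by gene symbol with sample ids as columns. ``NaN``
        marks missing entries.
    transformed:
        True once a log transform has been applied; scale invariants (ME in
        [0, 1], CNV >= 0) are only enforced on untransformed data.
    """

    layer: str
    values: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if not self.transformed:
            finite = self.values.to_numpy(dtype=float)
            finite = finite[np.isfinite(finite)]
            if self.layer == "ME" and finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("ME beta values must lie in [0, 1] before transform")
            if self.layer == "CNV" and finite.size and finite.min() < 0:
                raise ValueError("raw CNV values must be >= 0")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values.copy(), self.transformed)


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a sample table for the required columns and smoking categories."""
    required = ("smoking",) + CLINICAL_FIELDS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"sample table lacks columns: {missing}")
    bad = set(table["smoking"].dropna()) - set(SMOKING_CATEGORIES)
    if bad:
        raise ValueError(f"unknown smoking categories: {sorted(bad)}")
    return table


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table (symbol-indexed, 1-based inclusive coords)."""
    required = ["chromosome", "arm", "start", "end", "promoter_start", "promoter_end"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    if (ann["start"] > ann["end"]).any():
        bad = ann.index[ann["start"] > ann["end"]].tolist()
        raise ValueError(f"start > end for genes: {bad[:5]}")
    if (ann["promoter_start"] > ann["promoter_end"]).any():
        bad = ann.index[ann["promoter_start"] > ann["promoter_end"]].tolist()
        raise ValueError(f"malformed promoter interval for genes: {bad[:5]}")
    return ann


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping for synthetic cohorts (recovery tests)."""

    planted_ge: set[str] = field(default_factory=set)
    planted_me: set[str] = field(default_factory=set)
    planted_cnv: set[str] = field(default_factory=set)
    #: (chromosome, start, end, favored_class, mean_copy_number) per amplicon
    amplicon_regions: list[tuple[str, int, int, str, float]] = field(default_factory=list)

    def planted(self, layer: str) -> set[str]:
        return {"GE": self.planted_ge, "ME": self.planted_me, "CNV": self.planted_cnv}[layer]

    def to_dict(self) -> dict:
        return {
            "planted_ge": sorted(self.planted_ge),
            "planted_me": sorted(self.planted_me),
            "planted_cnv": sorted(self.planted_cnv),
            "amplicon_regions": [list(r) for r in self.amplicon_regions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_ge=set(d.get("planted_ge", [])),
            planted_me=set(d.get("planted_me", [])),
            planted_cnv=set(d.get("planted_cnv", [])),
            amplicon_regions=[tuple(r) for r in d.get("amplicon_regions", [])],
        )
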