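"""Genome-overview pattern computations.

Mountain profiles: per-group median raw copy number of each gene, ordered
along the genome (baseline 2 on autosomes, 1 on male ChrY). Deflection
tables: per-gene -log10 p of the two-class copy-number comparison with a
Bonferroni cutoff line. Focal-peak calling reports the genes at the top of
localized amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .containers import OmicsMatrix
from .diffstats import BonferroniCutoff, bonferroni_cutoff, welch_pvalues

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}


def _sorted_annotation(ann: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    sub = ann.loc[[g for g in genes if g in ann.index]].copy()
    sub["_c"] = sub["chromosome"].map(lambda c: _CHROM_ORDER.get(c, 99))
    return sub.sort_values(["_c", "start"]).drop(columns="_c")


def mountain_profile(
    cnv_raw: OmicsMatrix, ann: pd.DataFrame, groups: dict[str, list[str]]
) -> dict[str, pd.DataFrame]:
    """Per-group per-gene median raw copy number, genome-ordered.

    ``groups`` maps a subgroup label (e.g. ``current_male``) to sample ids.
    Genes absent from the annotation are dropped with a warning; missing
    values are excluded from the medians. Each profile has columns
    chromosome, arm, position, median_cn.
    """
    if cnv_raw.transformed:
        raise ValueError("mountain profiles require raw (untransformed) copy numbers")
    covered = [g for g in cnv_raw.gene_symbols if g in ann.index]
    if len(covered) < len(cnv_raw.gene_symbols):
        import warnings

        warnings.warn(
            f"dropped {len(cnv_raw.gene_symbols) - len(covered)} genes not in the annotation",
            stacklevel=2,
        )
    order = _sorted_annotation(ann, covered)
    out = {}
    for name, ids in groups.items():
        if not ids:
            raise ValueError(f"group {name!r} is empty")
        med = cnv_raw.values.loc[order.index, ids].median(axis=1, skipna=True)
        out[name] = pd.DataFrame(
            {
                "chromosome": order["chromosome"],
                "arm": order["arm"],
                "position": order["start"],
                "median_cn": med,
            }
        )
    return out


@dataclass
class DeflectionTable:
    """Per-gene two-class CNV comparison with a family-wise cutoff."""

    table: pd.DataFrame  # neg_log10_p, direction, chromosome/arm/position if annotated
    cutoff: BonferroniCutoff

    @property
    def fraction_above_cutoff(self) -> float:
        return float((self.table["neg_log10_p"] > self.cutoff.neg_log10).mean())


def deflection_table(
    cnv: OmicsMatrix,
    labels: np.ndarray,
    ann: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DeflectionTable:
    """Welch t-test per gene between the two classes with Bonferroni cutoff.

    ``direction`` is the class with the greater median ("class1" for label 1,
    "class0" otherwise).
    """
    labels = np.asarray(labels)
    p = welch_pvalues(cnv.values, labels)
    g1 = labels == 1
    med1 = cnv.values.loc[:, g1].median(axis=1, skipna=True)
    med0 = cnv.values.loc[:, ~g1].median(axis=1, skipna=True)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    table = pd.DataFrame(
        {
            "p": p,
            "neg_log10_p": nlp,
            "direction": np.where(med1.to_numpy() >= med0.to_numpy(), "class1", "class0"),
        },
        index=cnv.values.index,
    )
    if ann is not None:
        order = _sorted_annotation(ann, list(table.index))
        table = table.loc[order.index]
        table[["chromosome", "arm", "position"]] = order[["chromosome", "arm", "start"]]
    return DeflectionTable(table, bonferroni_cutoff(len(table), alpha))


@dataclass
class FocalPeak:
    chromosome: str
    start: int
    end: int
    region_genes: list[str]
    peak_genes: list[str]  # genes tied at the maximum median
    peak_median: float


def focal_peaks(
    profile: pd.DataFrame,
    min_prominence: float = 0.5,
    window: int = 25,
    tie_tolerance: float = 1e-9,
) -> list[FocalPeak]:
    """Localized copy-number peaks in a genome-ordered mountain profile.

    A peak is a local maximum of ``median_cn`` with prominence at least
    ``min_prominence`` within a ``window``-gene neighborhood; the reported
    region extends over contiguous genes within ``min_prominence/2`` of the
    peak value (the shoulder of the amplicon), and ``peak_genes`` lists all
    genes tied at the maximum. Calling is per chromosome, so it is invariant
    to translating genomic coordinates.
    """
    peaks: list[FocalPeak] = []
    for chrom, sub in profile.groupby("chromosome", sort=False):
        v = sub["median_cn"].to_numpy(dtype=float)
        if len(v) < 3:
            continue
        wlen = max(3, window) if window else None
        idx, _props = find_peaks(
            v, prominence=min_prominence, wlen=wlen, plateau_size=1
        )
        seen: set[tuple[int, int]] = set()
        for pk in idx:
            lo = hi = int(pk)
            floor = v[pk] - min_prominence / 2.0
            while lo > 0 and v[lo - 1] >= floor:
                lo -= 1
            while hi < len(v) - 1 and v[hi + 1] >= floor:
                hi += 1
            if (lo, hi) in seen:
                continue
            seen.add((lo, hi))
            region = sub.iloc[lo : hi + 1]
            vmax = region["median_cn"].max()
            tied = region.index[region["median_cn"] >= vmax - tie_tolerance].tolist()
            peaks.append(
                FocalPeak(
                    chromosome=chrom,
                    start=int(region["position"].min()),
                    end=int(region["position"].max()),
                    region_genes=list(region.index),
                    peak_genes=tied,
                    peak_median=float(vmax),
                )
            )
    return peaks


def smoking_gender_groups(samples: pd.DataFrame) -> dict[str, list[str]]:
    """The four subgroup partitions behind the key pattern contrasts."""
    groups = {}
    for smoking in ("never", "current"):
        for gender in ("male", "female"):
            ids = list(
                samples.index[
                    (samples["smoking"] == smoking) & (samples["gender"] == gender)
                ]
            )
            if ids:
                groups[f"{smoking}_{gender}"] = ids
    return groups


def chry_median(profile: pd.DataFrame) -> float:
    """Median of the ChrY gene medians in one subgroup profile."""
    y = profile[profile["chromosome"] == "chrY"]["median_cn"]
    return float(y.median())
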