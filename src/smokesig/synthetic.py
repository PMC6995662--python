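"""Seeded smoker/nonsmoker multi-omics cohort simulator.

Emulates the structure of level-3 lung-adenocarcinoma cohorts: a
never-smoker vs current-smoker two-class design (default class sizes 59/82),
log-normal gene expression with planted differentially expressed genes,
logit-normal promoter methylation with planted genes strongly negatively
coupled to their own expression, and segment-structured copy numbers with
class-specific focal amplicons plus a broad ChrY deficit in male
never-smokers. Missing entries are placed completely at random.

Known planted signals (``GroundTruth``) make every downstream stage testable
without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GroundTruth, OmicsMatrix

#: ChrY copy-number sentinel for female samples: a small positive constant
#: (not zero) so that the log2(CNV/2) transform stays finite.
FEMALE_CHRY_SENTINEL = 0.05

_STAGES = ("I", "II", "III", "IV")


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults reproduce the reference design: 59 never / 82 current smokers,
    2000 genes, 40 planted signature genes per layer, expression effect of
    Cohen's d = 2 on the log2 scale, ME-GE coupling targeting Pearson
    r = -0.877, focal amplicons of +1.5 copies and a ChrY deficit of 0.4
    copies in male never-smokers.
    """

    n_never: int = 59
    n_current: int = 82
    n_genes: int = 2000
    n_signature_ge: int = 40
    n_signature_me: int = 40
    n_signature_cnv: int = 40
    effect_size_ge: float = 2.0
    me_ge_correlation: float = -0.877
    missing_rate: float = 0.02
    chry_deletion_depth: float = 0.4
    amplicon_gain: float = 1.5
    seed: int = 0
    #: Seed for the cohort *structure* (gene layout, planted sets, baselines,
    #: effect signs). Defaults to ``seed``. Two configs sharing a
    #: structure_seed but differing in ``seed`` give independent cohorts with
    #: identical planted truth — i.e. a matched validation cohort.
    structure_seed: int | None = None
    # Noise magnitudes (log2-sd for GE, copy-number units for CNV).
    ge_noise_sd: float = 1.0
    cnv_arm_sd: float = 0.08
    cnv_gene_sd: float = 0.10
    cnv_amplicon_sd: float = 0.20

    def validate(self) -> "CohortConfig":
        for name in ("n_never", "n_current", "n_genes",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_signature_ge", "n_signature_me", "n_signature_cnv"):
            v = getattr(self, name)
            if v < 0 or v > self.n_genes:
                raise ValueError(f"{name} must lie in [0, n_genes], got {v}")
        if not -1.0 <= self.me_ge_correlation <= 0.0:
            raise ValueError(
                f"me_ge_correlation must lie in [-1, 0], got {self.me_ge_correlation}"
            )
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ValueError(f"missing_rate must lie in [0, 0.05], got {self.missing_rate}")
        if self.chry_deletion_depth < 0 or self.chry_deletion_depth > 1:
            raise ValueError(
                f"chry_deletion_depth must lie in [0, 1], got {self.chry_deletion_depth}"
            )
        return self


#: Chromosomes whose p-arm carries no (simulated) genes, mirroring the
#: acrocentric autosomes represented q-arm-only on copy-number arrays.
ACROCENTRIC = {"chr13", "chr14", "chr15", "chr21", "chr22"}


def _build_annotation(n_genes: int) -> pd.DataFrame:
    """Lay out symbols across chr1..22, X and Y with p/q arms and promoters."""
    n_y = max(12, round(0.01 * n_genes))
    n_x = max(10, round(0.03 * n_genes))
    n_auto = n_genes - n_y - n_x
    per_auto = [n_auto // 22 + (1 if i < n_auto % 22 else 0) for i in range(22)]
    chroms = [f"chr{i + 1}" for i in range(22)] + ["chrX", "chrY"]
    counts = per_auto + [n_x, n_y]
    rows = []
    g = 0
    for chrom, count in zip(chroms, counts):
        half = count // 2
        for j in range(count):
            symbol = f"GENE{g + 1:05d}"
            start = 1_000_000 * (j + 1)
            end = start + 20_000
            if chrom in ACROCENTRIC:
                arm = "q"
            else:
                arm = "p" if j < half else "q"
            rows.append(
                {
                    "symbol": symbol,
                    "chromosome": chrom,
                    "arm": arm,
                    "start": start,
                    "end": end,
                    "promoter_start": max(1, start - 1500),
                    "promoter_end": start + 500,
                }
            )
            g += 1
    ann = pd.DataFrame(rows).set_index("symbol")
    return ann


def _pick_amplicons(
    ann: pd.DataFrame, n_planted: int, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Choose contiguous autosomal gene runs; the first run has exactly 7 genes."""
    if n_planted == 0:
        return []
    sizes = []
    remaining = n_planted
    if remaining >= 7:
        sizes.append(7)
        remaining -= 7
    while remaining > 0:
        s = int(min(remaining, rng.integers(5, 11)))
        # avoid a trailing 1-gene stub when possible
        if 0 < remaining - s < 3 and s > 3:
            s = remaining
        sizes.append(s)
        remaining -= s
    autosomes = [c for c in ann["chromosome"].unique() if c not in ("chrX", "chrY")]
    arm_pool = []
    for chrom in autosomes:
        for arm in ("p", "q"):
            sub = ann[(ann["chromosome"] == chrom) & (ann["arm"] == arm)]
            if len(sub) >= 3:
                arm_pool.append((chrom, arm, sub))
    arm_pool.sort(key=lambda a: -len(a[2]))
    out = []
    used: set[tuple[str, str]] = set()
    for size in sorted(sizes, reverse=True):
        # each amplicon sits on its own arm with at least one flanking gene
        fits = [
            (c, a, s) for c, a, s in arm_pool if (c, a) not in used and len(s) >= size + 2
        ]
        if not fits:
            raise ValueError(
                "n_genes too small to place the requested amplicons "
                f"(no free chromosome arm with >= {size + 2} genes)"
            )
        chrom, arm, sub = fits[int(rng.integers(0, len(fits)))]
        used.add((chrom, arm))
        lo = int(rng.integers(1, len(sub) - size))
        out.append((chrom, list(sub.index[lo : lo + size])))
    # keep a 7-gene amplicon first (it anchors the focal-peak checks)
    for i, (_c, gs) in enumerate(out):
        if len(gs) == 7:
            out.insert(0, out.pop(i))
            break
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort: returns (GE, ME, CNV, sample table, annotation, truth).

    GE is on the linear scale (so that the standard log2(x+1) preprocessing
    recovers the class-conditional Gaussians it was built from), ME on the
    beta scale in [0, 1], CNV on the raw copy-number scale (baseline 2 on
    autosomes, 1 on male ChrY). Identical seeds give bit-identical output.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    rng_s = np.random.default_rng(
        cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    )
    n = cfg.n_never + cfg.n_current
    ann = _build_annotation(cfg.n_genes)
    genes = list(ann.index)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    smoking = np.array(["never"] * cfg.n_never + ["current"] * cfg.n_current)
    is_current = smoking == "current"
    gender = rng.choice(["male", "female"], size=n)
    samples = pd.DataFrame(
        {
            "smoking": smoking,
            "age": np.clip(rng.normal(65, 8, size=n).round().astype(int), 30, 90),
            "gender": gender,
            "stage": rng.choice(_STAGES, size=n, p=[0.5, 0.25, 0.2, 0.05]),
            "vital_status": rng.choice(["alive", "dead"], size=n, p=[0.6, 0.4]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- planted gene assignment (disjoint, autosomal, outside amplicons) ---
    autosomal = ann.index[~ann["chromosome"].isin(["chrX", "chrY"])]
    amp_regions = _pick_amplicons(ann, cfg.n_signature_cnv, rng_s)
    planted_cnv: list[str] = [g for _c, gs in amp_regions for g in gs]
    free = [g for g in autosomal if g not in set(planted_cnv)]
    pick = rng_s.permutation(len(free))
    planted_ge = [free[i] for i in pick[: cfg.n_signature_ge]]
    planted_me = [
        free[i] for i in pick[cfg.n_signature_ge : cfg.n_signature_ge + cfg.n_signature_me]
    ]

    # --- CNV: baseline + per-(sample, arm) segment offsets + gene noise ---
    cnv = np.full((cfg.n_genes, n), 2.0)
    chrom_arr = ann["chromosome"].to_numpy()
    is_y = chrom_arr == "chrY"
    male = (gender == "male")
    never_male = male & ~is_current
    cnv[np.ix_(is_y, male)] = 1.0
    cnv[np.ix_(is_y, never_male)] = 1.0 - cfg.chry_deletion_depth
    arm_key = (ann["chromosome"] + ann["arm"]).to_numpy()
    for key in pd.unique(arm_key):
        rows = arm_key == key
        if key.startswith("chrY"):
            continue
        n_rows = int(rows.sum())
        # two sub-segments per arm with independent per-sample offsets
        split = n_rows // 2
        off1 = rng.normal(0.0, cfg.cnv_arm_sd, size=n)
        off2 = rng.normal(0.0, cfg.cnv_arm_sd, size=n)
        idx = np.where(rows)[0]
        cnv[idx[:split]] += off1
        cnv[idx[split:]] += off2
    cnv += rng.normal(0.0, cfg.cnv_gene_sd, size=cnv.shape)
    # male ChrY noise is present too; female ChrY is a flat sentinel
    cnv[np.ix_(is_y, ~male)] = FEMALE_CHRY_SENTINEL
    # amplicons: class-specific gain, shared across the region per sample
    gene_pos = {g: i for i, g in enumerate(genes)}
    truth_regions = []
    for k, (chrom, region_genes) in enumerate(amp_regions):
        favored = "current" if k % 2 == 0 else "never"
        members = is_current if favored == "current" else ~is_current
        gain = cfg.amplicon_gain + rng.normal(0.0, cfg.cnv_amplicon_sd, size=int(members.sum()))
        rows = [gene_pos[g] for g in region_genes]
        cnv[np.ix_(rows, members)] += gain[np.newaxis, :]
        starts = ann.loc[region_genes, "start"]
        ends = ann.loc[region_genes, "end"]
        truth_regions.append(
            (chrom, int(starts.min()), int(ends.max()), favored, 2.0 + cfg.amplicon_gain)
        )
    np.clip(cnv, FEMALE_CHRY_SENTINEL, None, out=cnv)

    # --- GE on log2 scale ---
    baseline = rng_s.normal(7.0, 1.5, size=cfg.n_genes)
    ge_log = baseline[:, None] + rng.normal(0.0, cfg.ge_noise_sd, size=(cfg.n_genes, n))
    d = cfg.effect_size_ge
    sign_ge = rng_s.choice([-1.0, 1.0], size=len(planted_ge))
    for s, g in zip(sign_ge, planted_ge):
        ge_log[gene_pos[g], is_current] += s * d * cfg.ge_noise_sd
    # ME-coupled genes: shared latent factor carrying the class shift
    shared = {}
    sign_me = rng_s.choice([-1.0, 1.0], size=len(planted_me))
    for s, g in zip(sign_me, planted_me):
        latent = rng.normal(0.0, 1.0, size=n)
        latent[is_current] += s * d
        shared[g] = latent
        ge_log[gene_pos[g]] = baseline[gene_pos[g]] + cfg.ge_noise_sd * latent
    # CNV-dosage genes: expression follows copy number
    for g in planted_cnv:
        i = gene_pos[g]
        ge_log[i] = baseline[i] + 1.0 * (cnv[i] - 2.0) + rng.normal(0.0, 0.3, size=n)
    ge_linear = np.maximum(np.exp2(ge_log) - 1.0, 0.0)

    # --- ME beta values (logit-normal) ---
    me_mid = rng_s.normal(0.0, 0.8, size=cfg.n_genes)
    me_latent = me_mid[:, None] + 0.5 * rng.normal(0.0, 1.0, size=(cfg.n_genes, n))
    r = cfg.me_ge_correlation
    for g in planted_me:
        i = gene_pos[g]
        s = shared[g]
        s_std = (s - s.mean()) / s.std()
        eps = rng.normal(0.0, 1.0, size=n)
        coupled = r * s_std + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        # inner scale 0.6 keeps the sigmoid near-linear so the beta-scale
        # Pearson r stays close to the latent target
        me_latent[i] = rng_s.normal(0.0, 0.3) + 0.6 * coupled
    me = 1.0 / (1.0 + np.exp(-me_latent))

    # --- missingness, completely at random ---
    def _mask(x: np.ndarray) -> np.ndarray:
        if cfg.missing_rate > 0:
            m = rng.random(x.shape) < cfg.missing_rate
            x = x.copy()
            x[m] = np.nan
        return x

    idx = pd.Index(genes, name="symbol")
    cols = pd.Index(sample_ids, name="sample_id")
    ge_m = OmicsMatrix("GE", pd.DataFrame(_mask(ge_linear), index=idx, columns=cols))
    me_m = OmicsMatrix("ME", pd.DataFrame(_mask(me), index=idx, columns=cols))
    cnv_m = OmicsMatrix("CNV", pd.DataFrame(_mask(cnv), index=idx, columns=cols))
    truth = GroundTruth(
        planted_ge=set(planted_ge),
        planted_me=set(planted_me),
        planted_cnv=set(planted_cnv),
        amplicon_regions=truth_regions,
    )
    return ge_m, me_m, cnv_m, samples, ann, truth


def write_cohort(
    out_dir: str | Path,
    ge: OmicsMatrix,
    me: OmicsMatrix,
    cnv: OmicsMatrix,
    samples: pd.DataFrame,
    ann: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write a cohort as TSV tables plus a ground-truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, m in (("ge", ge), ("me", me), ("cnv", cnv)):
        p = out / f"{name}.tsv"
        m.values.to_csv(p, sep="\t", na_rep="NA")
        paths[name] = p
    paths["samples"] = out / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", na_rep="NA")
    paths["annotation"] = out / "annotation.tsv"
    ann.to_csv(paths["annotation"], sep="\t")
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    return paths
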