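"""Genome-wide copy-number patterns: mountain profiles, deflection, peaks.

Reproduces the pattern analyses on a simulated cohort: per-subgroup median
copy-number profiles along the genome, the ChrY deficit of male
never-smokers, the two-class deflection fractions, and focal-amplicon peak
genes.
"""

from smokesig import CohortConfig, deflection_table, focal_peaks, generate_cohort, mountain_profile
from smokesig.patterns import chry_median, smoking_gender_groups

cfg = CohortConfig(seed=1)
ge, me, cnv, samples, ann, truth = generate_cohort(cfg)

groups = smoking_gender_groups(samples)
profs = mountain_profile(cnv, ann, groups)
print("ChrY median copy number by subgroup (male baseline is 1.0):")
for name in ("never_male", "current_male"):
    print(f"  {name}: {chry_median(profs[name]):.2f}")

y = (samples["smoking"] == "current").to_numpy(dtype=float)
d = deflection_table(cnv, y, ann)
print(f"deflection: {100 * d.fraction_above_cutoff:.1f}% of genes above the "
      f"Bonferroni line (-log10 p > {d.cutoff.neg_log10:.2f})")

print("focal amplicons in the current-smoker profile:")
ids = list(samples.index[samples["smoking"] == "current"])
prof = mountain_profile(cnv, ann, {"current": ids})["current"]
for p in focal_peaks(prof, min_prominence=0.5, window=25):
    print(f"  {p.chromosome}:{p.start}-{p.end}: {len(p.region_genes)} genes, "
          f"peak {p.peak_genes[0]} at {p.peak_median:.2f} copies")
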