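"""Per-gene two-class statistics: SAM q-values, volcano table, Bonferroni.

Runs the SAM permutation FDR on the expression layer of a simulated cohort
and shows how many planted genes are recovered at the q <= 0.1 cutoff, plus
the genome-wide Bonferroni constants used for the volcano/deflection plots.
"""

import numpy as np

from smokesig import CohortConfig, bonferroni_cutoff, generate_cohort, sam_fdr, volcano_table
from smokesig.preprocess import prepare_layer

cfg = CohortConfig(seed=1)
ge, me, cnv, samples, ann, truth = generate_cohort(cfg)
X, _, y = prepare_layer("GE", ge, me, cnv, samples)

res = sam_fdr(X, y, n_permutations=1000, seed=0)
hits = res.index[res["q"] <= 0.1]
planted_hits = len(set(hits) & truth.planted_ge)
print(f"SAM q<=0.1 genes: {len(hits)} "
      f"({planted_hits}/{len(truth.planted_ge)} planted GE genes recovered)")

v = volcano_table(X, y)
c = bonferroni_cutoff(len(v), 0.05)
above = (v["neg_log10_p"] > c.neg_log10).sum()
print(f"Bonferroni per-test p = {c.per_test_p:.2e} (-log10 = {c.neg_log10:.2f}); "
      f"{above} genes exceed the family-wise line")
top = res.nsmallest(3, "q")
print("top genes by |d| (d, fold change, q):")
for g, row in top.iterrows():
    print(f"  {g}: d={row['d']:+.2f}, FC={row['fold_change']:.2f}, q={row['q']:.3g}")
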