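# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the limits of what the test suite demonstrates.

## Classification model

The classifier is PLS1 discriminant analysis. The predictor matrix X
(samples × genes) is autoscaled — centered and scaled to unit variance per
gene — and the 0/1 class label y (never-smoker = 0, current smoker = 1) is
centered. Autoscaling is not forced by the procedure itself but makes the
per-gene regression coefficients comparable across genes, which matters
because |b_g| is the elimination criterion. NIPALS extraction for a single
response needs no iteration: each weight vector is the normalized
covariance X′y of the deflated matrix, so the fit is exact, deterministic
and fast. Successive score vectors are orthogonal (checked to 1e-8) and
with as many components as the predictor rank the coefficients equal
ordinary least squares (the main linear oracle). The hard class is
score ≥ 0.5; an equivalent ±1 encoding with a 0 threshold would give the
same classifier.

The number of components A is never fixed a priori: it is chosen per fit by
stratified 5-fold CV accuracy over 1..max_components (default 10), ties to
the smallest A. All reported results are conditional on this selection
rule.

Kernel PLS follows the dual (Rosipal–Trejo) formulation: the Gram matrix of
the autoscaled inputs is double-centered in feature space,
`K_c = H K H` with `H = I − (1/n)11′`, components are extracted on the
centered kernel, and prediction uses
`K_test_c = (K_t − (1/n)1_t 1′K) H`. With the linear kernel the predictions
coincide with linear PLS at equal A (tolerance 1e-6 in tests) — this
equivalence is the module's correctness anchor, and the RBF kernel is
checked on an XOR construction that no linear model can separate. The
default tuning grid is linear plus RBF with γ ∈ {2^k/p, k = −3..3}; ties
prefer the simplest kernel. KPLS is applied only after the signature is
chosen; the selection loop itself is strictly linear.

## Selection procedure

Stage 1 (statistical): GE candidates are genes with SAM q ≤ 0.1. The SAM
statistic uses the pooled standard-error scatter s_i of the two-sample t
statistic plus an exchangeability factor s₀ chosen by the percentile-scan
rule (minimizing the coefficient of variation of windowed MADs of d); at
s₀ = 0 the statistic reduces exactly to the pooled t, which is the tested
oracle. q-values come from the pooled permutation null of d (default 1000
class-size-preserving label permutations, seeded; fewer distinct
permutations than requested triggers a warning and full enumeration)
converted by Benjamini–Hochberg. The permutation null is evaluated against
a canonical, content-sorted sample ordering so the q-values are exactly
invariant to reordering samples together with their labels. ME/CNV
candidates are genes with |Pearson r| > 0.5 between the layer and the
gene's own (log2) expression, pairwise-complete, genes with fewer than
three complete pairs skipped with a warning. Pearson rather than a rank
correlation is used because the reference quantity for the methylation
coupling is a Pearson coefficient.

Stage 2 merges a user-supplied curated gene list into the candidates
(restricted to genes present in the data; absent symbols are warned about
and skipped, injected genes recorded in the provenance).

Stage 3 removes exactly one gene per iteration — the smallest |b_g|, ties
broken by ascending symbol — refits, and records pooled stratified 5-fold
CV accuracy on folds fixed once per run by a single seed. "Accuracy could
not be further improved" is operationalized with a patience counter
(default 10): the loop stops when no strict improvement over the running
best has occurred for `patience` consecutive removals, or when two genes
remain. The returned set is the best-accuracy iteration with ties resolved
toward fewer genes, so on plateaus the procedure keeps shrinking the set by
up to `patience` genes. The contribution ranking is recomputed on the full
training set each iteration, not per fold. Accuracy (not balanced
accuracy) is the stop metric; class imbalance is reported, not corrected.

A consequence worth knowing: with strongly informative candidate sets, CV
accuracy saturates at 1.0 immediately, every iteration ties, and the stop
rule returns the candidate set minus `patience` genes. Backward elimination
by reduced-rank PLS coefficients also does not reliably purge exactly
collinear duplicates — coefficients of duplicated columns split in half
only at full rank — so redundant aliases of a gene can both survive. Both
behaviors are exercised in the tests.

## Synthetic cohorts

The generator emulates a two-class LUAD cohort at the reference design: 59
never / 82 current smokers, 2000 genes laid out on chr1–22, X and Y
(acrocentric chromosomes 13/14/15/21/22 carry genes on the q arm only), 40
planted signature genes per layer, and ≤5% completely-at-random
missingness (default 2%).

* **GE** is Gaussian on the log2 scale (per-gene baseline ~N(7, 1.5), noise
  sd 1) and emitted on the linear scale as 2^x − 1, so the standard
  log2(x+1) preprocessing recovers the Gaussians exactly. Planted GE genes
  are shifted between classes by Cohen's d = 2 with random sign.
* **ME** is logit-normal on the beta scale. Each planted ME gene shares a
  latent factor with its own expression with sign-flipped loading:
  the factor carries the class shift, expression is the factor itself, and
  the methylation latent is r·ŝ + √(1−r²)·ε at target r = −0.877, passed
  through a sigmoid with inner scale 0.6. The inner scale was calibrated
  once so that the sigmoid's attenuation leaves the realized beta-scale
  Pearson r at the target (realized mean ≈ −0.88 at n = 141).
* **CNV** is raw copy number, baseline 2 on autosomes with per-(sample,
  arm-segment) offsets (sd 0.08) and per-gene noise (sd 0.10). Planted CNV
  genes form contiguous amplicons (one of exactly 7 genes, the rest 5–10)
  elevated by +1.5 copies (per-sample sd 0.2) in a designated class, and
  their expression follows copy number (dosage coupling) so they pass the
  stage-1 correlation filter. ChrY is 1.0 for males, reduced by the
  deletion depth (default 0.4) in male never-smokers, and a small positive
  sentinel (0.05, not zero) for females so log transforms stay finite.
* A `structure_seed` separates structural draws (gene layout, planted
  sets, baselines, signs) from noise draws, so a validation cohort with
  identical planted truth but independent noise is one `replace(cfg,
  seed=...)` away. Identical full seeds give bit-identical cohorts.

What the generator does **not** emulate: platform-specific artifacts (27K
vs 450K probe chemistry, SNP-array waviness), batch effects, stromal
contamination, correlated gene–gene expression structure beyond the
planted couplings, or realistic linkage between neighboring genes' copy
numbers beyond shared arm segments. Passing recovery tests therefore shows
the procedure is implemented correctly and behaves as designed under its
own assumptions — not that it would reach the same accuracy on real
cohorts, where effects are weaker and correlated.

## Problem sizes and defaults

Parameter recovery and the acceptance script use the reference design
(141 samples × 2000 genes, 10 generator seeds for the expression layer,
single seeds for the methylation and copy-number layers); null controls use
20 seeds of the same size with all planted effects (including the ChrY
deficit) set to zero and 500 SAM permutations. These sizes were chosen as
the smallest at which the binomial noise on recall and SN/SP/ACC is well
below the thresholds being checked. Unit tests use a faster 70-sample ×
300-gene cohort where full power is not needed.

Key defaults, with units: SAM FDR cutoff q ≤ 0.1; correlation threshold
|r| > 0.5; 1000 permutations; CV k = 5; patience 10 removals;
max 10 PLS components; KPLS grid linear + RBF γ ∈ 2^{−3..3}/p; focal-peak
prominence 0.5 copies within a 25-gene window (the peak/prominence
definition is a package choice, not a reference value); Bonferroni
family-wise α = 0.05. The Methods-level constants — the per-test cutoffs
0.05/21342 ≈ 2.34×10⁻⁶ (−log10 = 5.63) and 0.05/23494 (−log10 = 5.67
exactly; 5.68 via the rounded 2.10×10⁻⁶ chain) — are both exposed; the
rounded chain is reported as such, not silently corrected.

## Degenerate inputs and tie-breaks

Zero-variance genes are dropped with a warning before (K)PLS; component
counts beyond the predictor rank are truncated with a warning; fold
changes with a zero denominator are reported missing, not infinite;
correlation-filter genes with < 3 complete pairs are skipped; a fold with
a single class cannot arise because folds are stratified and class counts
< k are rejected up front. Coefficient ties in the elimination ranking
break by ascending symbol; component-count ties by smaller A; kernel ties
by simpler kernel; equal-accuracy iterations by fewer genes. ROC curves
group tied scores at a single threshold and integrate by trapezoid.

## Known limitations

* The reference gene rosters (43/48/75 signature genes) and Table-level
  accuracies of the original cohorts require controlled-access data and a
  supplementary curated list; the package reproduces the *procedure* and
  verifies it by parameter recovery, not those rosters.
* Whether reported accuracies of the original study came from the linear
  or the kernel models is not distinguishable from its text; the pipeline
  reports both, labeled.
* The elimination stop rule is a patience heuristic; no tolerance for
  "improvement" was given in the source description, and results on
  plateaus depend on the patience value (documented above).
* Only never-vs-current classification is wired as the default contrast;
  former/ever categories are carried in the sample table and can be chosen
  via `prepare_layer(classes=...)`.
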