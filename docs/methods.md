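# Methods

## Problem and model

Two expression studies — study A, a small animal-model experiment (few
samples per group, probe-level bead-type features with per-feature detection
p-values, time points 6 h/24 h), and study B, a larger clinical cohort (two
patient conditions at 24 h/72 h plus controls, gene-centered features) — are
compared on the subset of genes linked one-to-one by a homolog map. All
statements about cross-species agreement are made on log2 fold changes
relative to each study's own controls: absolute intensities from different
platforms and species are not comparable, so the pipeline equalizes each
study's signal distribution internally (quantile normalization, repeated
after homolog merging) and then works exclusively with relative changes.

### Differential expression

Within a study, expression of gene *g* in a sample is modeled as Gaussian on
the log2 scale with gene-specific variance σ²_g. For a two-group contrast
with n₁ and n₂ samples, the pooled residual variance s²_g (d_g = n₁+n₂−2 df)
is shrunk toward a prior fitted across genes. The prior takes σ²_g as
scaled-inverse-chi-square with d₀ degrees of freedom and scale s₀², the
conjugate family under which the posterior variance is the precision-weighted
blend s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g), and the moderated t statistic
log2FC_g/(s̃_g √(1/n₁+1/n₂)) has a t reference with d₀+d_g df. Hyperparameters
are estimated by moment matching on e_g = log s²_g − ψ(d_g/2) + log(d_g/2):
the excess of var(e) over the mean sampling variance ψ′(d_g/2) estimates
ψ′(d₀/2) (inverted by Newton iteration on the trigamma, tolerance 1e−8), and
s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)). When the excess dispersion is ≤ 0 the
gene variances are more concentrated than any finite prior allows; the fit
returns d₀ = ∞ with s₀² equal to the mean sample variance, and the t
statistic then uses the common variance with a normal reference. Genes with
zero residual df are excluded from the fit and receive no p-value. The
implementation is cross-checked in the test suite against a frozen
independent empirical-Bayes oracle and against the pooled two-sample t in
the d₀ = 0 limit.

DEG status uses the MAQC dual criterion: |log2FC| ≥ log2(fold) with fold = 2
(boundary included — "twofold" is read inclusively; configurable) and
BH-adjusted p < 0.05. The dual criterion is deliberately conservative: the
fold-change arm protects against statistically significant but biologically
trivial changes at large n, the FDR arm against large but noisy fold changes
at small n. Prior fitting happens per contrast (each contrast is an
independent two-group analysis); a multi-group linear-model fit with a
single shared residual variance would pool slightly more information but
adds model structure the two-group contract does not need.

### Overlap statistics

Given DEG sets over a common m-gene universe, the two-list question "how
often would same-size random lists intersect this much?" has the exact
answer P[X ≥ k] with X ~ Hypergeometric(m, |B|, |A|). The Monte-Carlo
procedure (default 4,000 iterations) draws, per iteration, a uniform random
subset of the universe for every input set, preserving observed sizes, and
records the K-way intersection size; it generalizes to K > 2 lists. Two
empirical p-value conventions are reported: the literal strictly-greater
fraction #{null > obs}/N, and the pseudocount form (#{null ≥ obs}+1)/(N+1).
The literal form can return exactly 0 and is anti-conservative near the
tail; the pseudocount form is the calibrated estimator (it is the one shown
to be uniform under the null and to converge to the hypergeometric tail in
the tests), so tests and summaries that need calibration use it, while the
literal form is retained as the default report field for fidelity to the
strictly-greater definition.

The common DEG set is DEGC = (∪ condition-1 DEG ∪ condition-2 DEG) ∩
(∪ study-A DEG), each family first unioned over its time points. Sign
concordance compares the per-study average log2FC over that study's
control contrasts (averaging before sign comparison matches judging a gene
by its overall direction; a per-time mode is available in the API by passing
single-contrast frames); an exactly-zero average is flagged indeterminate
rather than forced into either class.

### Enrichment

One-sided Fisher's exact tests on the 2×2 classification of the annotation
universe (query ∩ set / query ∖ set / set ∖ query / neither), BH-adjusted
across the collection. The universe is the collection's own gene universe,
optionally intersected with a user-supplied detected-gene background —
enrichment must be judged against what could have been observed. The percent
column divides hits by the number of query genes mapped into the universe,
not the raw query size. The EASE variant (discount one hit before taking the
tail) is available behind a flag; the standard Fisher test is the default
because the EASE modification is a heuristic without a sampling-model
justification.

### Similarity and clustering

Pearson correlation of average log2 fold changes with the usual t-transform
p-value (n−2 df). Hierarchical clustering of the DEGC fold-change matrix
uses uncentered-correlation distance (cosine distance) with average linkage
— the convention of the classic expression-clustering tools — with centered
correlation and Euclidean distance selectable. Merge-distance ties are
resolved by the deterministic behavior of the scipy agglomeration for a
given input ordering. For display only, fold changes are clamped to [−3, 3];
all statistics use unclamped values. The dendrogram is exported as Newick,
the display matrix as TSV, the heatmap as PNG.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical* structure the analysis relies on:

- study-design asymmetry (defaults: A = 4 controls + 4×2 time points over
  ~9,325 genes expanded into 1–3 probes each; B = 18 controls + sepsis
  32/20 and shock 67/39 samples at 24 h/72 h over ~18,988 genes; 7,461
  shared homolog pairs);
- gene baselines uniform on [6, 12] log2 units; gene variances
  scaled-inverse-chi-square(d₀ = 4, s₀² = 0.05) — making the variance-prior
  fit testable against planted truth; Gaussian noise;
- planted DE classes over the shared universe: concordant (2% of shared
  genes by default), discordant (0.15%, a subset scale mirroring the ~7%
  discordant minority typically seen in the motivating comparison),
  study-exclusive (1% per study, planted *inside* the shared universe so
  overlap statistics see them), and null (effect exactly 0);
- effect persistence: 90% of DE genes carry the identical effect at both
  time points, the remainder at one random time — so late-vs-early
  "dynamics" contrasts stay largely quiet, as expected for persistent
  responses;
- probe-level structure on study A only (study B emulates re-annotated
  gene-centered probe sets): per-probe offsets N(0, 0.1²), small enough to
  exercise gene aggregation without dominating signal;
- detection dropout on study A only, and only among null genes — detection
  failure is a property of unexpressed transcripts, and planted DE genes
  are by construction expressed. Dropout (10% of null genes) is what makes
  the realized m fall below the configured n_shared, with exact bookkeeping
  kept in the truth table.

Default effect size is 2 log2 units (fourfold) — a strong but realistic
magnitude for the leading responders in whole-blood infection signatures —
chosen once for testability; the motivating data publish no effect-size
distribution.

Not modeled: bead-array optics and background, chip batch effects, globin
carryover, cell-type composition shifts, condition-specific effects within
study B (planted B effects are common to sepsis and shock), and missing
values. Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not robustness to those real-data
artifacts.

## Numerical and reproducibility choices

- Quantile normalization resolves within-column ties by averaging the
  reference values over the tied ranks: deterministic and stable under any
  permutation of equal values.
- One-to-many homolog relations are reduced to one-to-one by keeping, per
  gene, the pair whose partner id sorts first — arbitrary but deterministic,
  and real curated homolog sets are predominantly 1:1.
- Probe-to-gene aggregation is the arithmetic mean of probe log2 values
  (symmetric, stable at small n); a max-variability probe selection could be
  substituted but is not implemented.
- Merged re-normalization is applied per study, never pooled across species,
  because cross-platform absolute signals are exactly what the workflow
  refuses to compare.
- All TSV floats are written at %.6g; identical configuration + seed
  reproduces every output byte-for-byte. The pipeline seed expands into
  per-stage child seeds via `SeedSequence(seed, spawn_key=(stage,))` with a
  fixed stage numbering (0 simulation, 1 pairwise MCS, 2 K-way MCS, 3 gene
  sets), so stages rerun standalone reproduce their in-pipeline draws.
- Monte-Carlo subset draws are vectorized in iteration chunks (default 512)
  to bound memory at large m.

## Problem sizes used in the checks

The bundled tests run the generator at reduced gene counts (300–1,200 shared
homologs) and the end-to-end recovery check at effect size 3 with 10 samples
per group, where DEGC sensitivity and discordant recovery are required to
reach 0.9; Monte-Carlo calibration uses 200 replicates of 2,000-iteration
runs on a 2,000-gene universe, and BH error control 400 all-null replicates
of 1,500 genes. `scripts/acceptance.py` runs the full default-scale design.
These sizes are the package's own choice of a thorough-but-quick regression
surface; the statistics do not change with scale.

## Known limitations

- Two-group contrasts only: no multi-factor designs, paired analyses, array
  weights, or variance trends on the prior.
- The moderated-t plug-in prior ignores estimation noise in (d₀, s₀²); on
  null data the realized FDR of BH calls is slightly above nominal (≈ 0.06
  at α = 0.05 in the bundled simulations), consistent with the known small
  anti-conservativeness of empirical-Bayes plug-in inference at few arrays.
- The hypergeometric/Monte-Carlo overlap nulls assume exchangeable genes;
  correlated genes (co-regulation) would make them anti-conservative on
  real data.
- Enrichment p-values depend strongly on the chosen background universe;
  with local GMT collections the percent and hit counts are the stable
  quantities, p-values are background-relative.
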