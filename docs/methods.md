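# Methods

This note documents the model, the numerical choices, the synthetic
cohorts the package is validated on, and the known limitations. It is
the place where design decisions that were genuinely open are recorded
with their rationale.

## Overview of the procedure

Input are a gene × sample expression matrix (raw, non-negative), a CpG
locus × sample beta-value matrix (values in [0, 1], missing entries
allowed), a locus→gene map, and a clinical table (patient ID, survival
time, event indicator, and the fields needed for a cohort-specific
gold-standard risk label). The stages:

1. **Preprocessing.** Expression is transformed as `log10(x + offset)`
   (offset 1 by default; the transform only needs to avoid log 0, and 1
   keeps zero counts at zero). Loci with more than 50% missing betas
   are dropped; the rest are mean-imputed per locus, so each retained
   locus keeps its observed mean. Clinical rows without usable
   time/event are removed and the gold-standard rule labels each
   patient low/intermediate/high (lung tumor stage, AFP + Ishak score,
   Braak score, or a precomputed cytogenetics-style column).
2. **Feature election.** A gene or locus is retained iff its absolute
   Pearson correlation with survival time *or* with the event indicator
   reaches a cutoff (0.2 is the reference value for TCGA-sized cohorts,
   0.1 for weaker-signal cohorts). "Either-of-two" rather than
   "both" was chosen deliberately: it is the more inclusive reading,
   retaining features whose association shows only on one scale, and is
   configurable to "both". Zero-variance features score 0. The retained
   sets are then closed under the locus↔gene map (every selected gene
   pulls in its loci and vice versa, iterated to a fixed point so the
   expansion is idempotent even under many-to-many maps).
3. **Eigenloci.** Each gene's loci are collapsed to one value per
   sample: the first principal component of the centered (never scaled
   — betas share the [0, 1] scale, and scaling would inflate
   near-constant loci) beta rows, i.e. a weighted average of its loci.
   Genes with ≥ 6 loci are first reduced to their densest core: a
   complete graph on the loci weighted by absolute Pearson correlation
   is clustered with fast-greedy modularity maximization, and the
   community with the highest mean absolute pairwise correlation (ties:
   the smaller community) is kept; singleton communities are excluded
   unless nothing else exists. PCA signs are fixed by orienting scores
   to correlate non-negatively with the gene's mean beta profile, so
   "higher eigenloci ≈ higher methylation".
4. **Network.** `W(i,j) = (1−μ)|cor_E| + μ|cor_M|` over the union of
   genes with expression and genes with eigenloci; a gene missing one
   layer contributes only its available term (the missing term counts
   as 0 — "no evidence"), as does any pair with fewer than 3 shared
   samples. The diagonal is 0. A soft power β (candidates 1..20) is the
   smallest whose connectivity distribution passes a scale-free fit of
   R² ≥ 0.75 — log10(frequency) regressed on log10(mean connectivity)
   over 10 equal-width connectivity bins, R² signed by the negated
   slope — falling back to the best-fitting β (logged) when none
   passes, and to β = 1 when the fit is degenerate everywhere (e.g. a
   uniform network).
5. **Modules.** `A = W^β` is converted to topological overlap
   `TOM(i,j) = (Σ_u A_iu A_uj + A_ij) / (min(k_i,k_j) + 1 − A_ij)` and
   1−TOM is clustered by average linkage. The tree is cut at the level
   (over all midpoints between consecutive merge heights, plus one
   above the root) that maximizes Newman modularity of the induced
   partition on `A`; ties prefer the coarser cut, so a network of
   identical genes is one module rather than many. This adaptive cut
   is this package's stand-in for a dynamic tree cut, for which no
   maintained implementation exists in this stack; it is deterministic
   and scale-adaptive. Clusters below the minimum size (5) form module
   0; clusters whose summary eigengenes (first PC of the μ-weighted
   standardized member profiles) correlate above 0.85 are merged.
   Module labels 1..K are assigned by decreasing size, ties by the
   smallest member gene symbol, so runs are reproducible. An
   identically-zero similarity yields no modules at all.
6. **Eigengenes.** Per module (module 0 excluded): genes are
   standardized with statistics computed on a *risk-balanced* patient
   multiset — intermediate-risk patients excluded, the minority of
   {low, high} replicated wholesale plus a seeded without-replacement
   draw for the remainder until the classes are equal — and the first
   PC weights are fit on those balanced columns only. All patients
   (including intermediate-risk) receive eigengene values by projecting
   with the frozen weights and standardization statistics; nothing is
   refit. `E^em = (1−μ)E^e + μE^m` exactly. Signs: `E^e` is oriented
   toward the module's mean standardized profile; `E^m` is oriented to
   correlate non-negatively with `E^e`. The latter deviates from the
   simpler mean-profile rule on purpose: promoter-style methylation is
   anti-correlated with expression for roughly half the genes, which
   makes the module's mean methylation profile ≈ 0 and that orientation
   unstable — and an `E^em` built from discordantly oriented parts
   would cancel to noise. PCA signs are arbitrary; only a shared
   orientation makes the combination meaningful.
7. **Survival.** Candidates are all eigengenes (`<module>e/m/em`),
   restricted to patients with both data types and usable survival. An
   L1-penalized Cox path (decreasing penalty, 200 grid points) is
   walked from strongest penalty down; the first three distinct
   eigengenes to gain nonzero coefficients are the candidates
   ("first-k-to-enter" avoids a data-dependent λ choice). For each of
   the 7 non-empty subsets a Weibull AFT model
   `log T = b0 + Σ b_j x_j + σ ε` is fit (lifelines; zero-variance
   covariates excluded and reported with coefficient 0; a small ridge
   penalty is retried once if the unpenalized fit fails); the linear
   predictor is the predicted log characteristic life. Two cutoffs are
   derived on it: the high-risk cutoff flags patients *below* it and
   maximizes precision for the deceased class subject to recall ≥
   `minRecallHigh`; the low-risk cutoff flags patients *above* it for
   the alive/censored class with recall ≥ `minRecallLow`; candidate
   cutoffs are midpoints of sorted unique predictions and precision
   ties prefer the smaller group (the more conservative call). Patients
   between the cutoffs are intermediate risk. The subset with the
   smallest low-vs-high log-rank p wins (ties: fewer eigengenes, then
   lexicographic IDs). Vital status, not the gold-standard label, is
   the cutoff search's ground truth: the gold labels exist to balance
   the PCA, while the cutoffs are about predicting survival itself.
   Default recall floors are 0.2 (low) and 0.05 (high), the reference
   values for TCGA-sized cohorts; they are per-cohort configuration
   (see the recovery experiment below for why small floors saturate).
8. **Grid search and bootstrap.** Stages 4–7 are repeated over the μ
   grid (default 0.0–1.0 step 0.1; preprocessing and eigenloci are
   μ-independent and shared); the best μ minimizes the log-rank p, ties
   prefer the smaller μ (the simpler expression-weighted model). The
   bootstrap resamples *patients* with replacement (the gene/locus
   universe is fixed — the question is resilience to outlier patients),
   reruns network→survival at the fixed best μ, and reports the mean
   and variance of the per-iteration p-values; iterations may fail
   (recorded as missing), and more than 20% failures aborts. Bootstrap
   means are expected to be *larger* than the original p: a bootstrap
   sample contains fewer unique patients and carries less information.

Determinism: every stochastic step (oversampling, bootstrap, the
generator) takes an explicit seed; two runs with the same config and
seed produce byte-identical output files. Timestamps appear only in the
log stream, never in result files, precisely so that outputs can be
compared byte for byte.

## The synthetic cohort generator

`simulate_cohort` plants everything the pipeline is supposed to find.
Per module k a per-sample latent `z_k ~ N(0,1)`; a gene in module k has
expression `s_g a_g z_k + a_g τ ε` with loading `a_g ∈ [0.5, 1]`,
random sign `s_g`, and noise scaled so `|cor(gene, z_k)|` equals the
configured within-module correlation (default 0.8). The gene's
methylation latent follows the same latent with its sign flipped
relative to expression for a configurable fraction of genes (default
0.5 — this exercises the absolute values in the edge weight). Each
gene receives `1 + min(Poisson(1.5), 8)` CpG loci (≈ 93% of genes get
fewer than six); locus betas are `logistic(gene latent + locus offset +
0.3·noise)`, which guarantees (0, 1). Betas are masked missing
completely at random (default 5%). Raw expression is `10^(latent+2)`,
so the pipeline's log10 transform recovers the latent scale. Survival:
`log T = b0 + b1·z_surv + σ·Gumbel` with `z_surv` the prognostic
module's latent (module 1) or, when a multi-module hazard is
configured, a normalized weighted contrast of several module latents;
censoring is administrative at a `Uniform(0, H)` horizon with `H`
calibrated by bisection to the requested censoring rate (default 0.3).
Gold-standard labels are survival-aligned tertiles of `z_surv` with a
configurable fraction reassigned at random (default 10%). The `signal`
switch produces single-layer cohorts: the uninformative layer's module
genes collapse onto one shared co-regulation latent (correlation 0.98
with it), carrying neither module structure nor survival information.

What the generator does *not* emulate: probe-type chemistry and batch
effects, copy-number confounding, count-based expression noise
(overdispersion), non-MCAR missingness, informative censoring, and
competing risks. Passing tests therefore demonstrate correctness of
the machinery and recoverability under the planted model, not
performance on real cohorts.

## Validation experiments and their sizes

All experiment sizes below are the package's own choices, scaled so the
whole suite runs on a desk machine.

- **Module recovery**: 3 modules × 30 genes, 150 samples, within-module
  correlation 0.8, μ = 0.5, 10 seeds; mean adjusted Rand index ≥ 0.8
  against planted labels (observed: ≈ 1.0).
- **Eigengene recovery**: same cohorts; each planted module's `E^e` and
  `E^em` correlate with its latent at |r| ≥ 0.9, and `E^em` equals the
  μ-combination to 1e-12.
- **Oracle equalities**: eigenloci vs a brute-force covariance
  eigendecomposition (1e-8); the core-locus choice vs exhaustive
  scoring of the detected communities; the cutoff search vs a plain
  loop over all cutoffs (200 random instances); the log-rank p vs the
  hand O−E/V chi-square (1e-10) and vs its own permutation distribution
  (2,000 permutations); AFT recovery of a planted b1 = 0.8 within
  ±0.15 (n = 500, 20% censoring, 50 seeds).
- **Null behavior**: with b1 = 0 (200 seeded runs, 100 samples, 3 × 10
  genes, election cutoff 0.1, single-μ grid) the fraction of runs with
  final log-rank p < 0.05 is far above 0.05 (observed ≈ 0.8). This
  anti-conservatism is *by construction*: three features are selected
  from many, the best of 7 subsets is kept, and both cutoffs are
  optimized on the same data. The pipeline's p-values rank models; they
  are not calibrated significance statements. The package verifies and
  reports this property rather than hiding it.

## Integrative-factor recovery experiment

The claim "if only one layer carries survival signal, the grid search
points μ at that layer" needs carefully designed cohorts, because three
properties of the method (each verified above, and each defensible on
its own) interact against naïve designs:

1. **Saturation.** Under small recall floors (0.2/0.05) the optimized
   risk groups are small, and any eigengene correlating ≳ 0.6 with the
   survival latent reaches a near-floor log-rank p at n ≈ 150–200; the
   grid argmin then cannot rank eigengene quality. The experiment uses
   recall floors (0.5, 0.3), under which p resolves quality over
   several orders of magnitude.
2. **Balanced-PCA rescue.** Oversampling by risk label tilts the
   balanced-sample covariance toward the survival direction
   (`I + c·wwᵀ`), so with informative gold labels *any* detected module
   containing signal genes yields a survival-aligned eigengene,
   whatever μ produced it. The experiment uses nearly uninformative
   gold labels (90% reassigned) — mirroring cohorts whose clinical gold
   standard barely stratifies survival — so eigengene quality is driven
   by module coherence, which is what μ controls.
3. **Single-module hazards are μ-invariant.** If one module drives
   survival, any cluster of its genes — found at any μ — summarizes it.
   The experiment plants a hazard spread as an equal-weight ±1 contrast
   over 4 of 6 modules: it is recoverable only by jointly selecting
   three separated module eigengenes, while the merged module that the
   wrong μ produces (the uninformative layer collapses all module genes
   onto one shared latent) yields a first PC that is a random rotation
   in the six-dimensional block space, correlating weakly (~0.45 at
   best) with the contrast.

Frozen conditions: 200 samples, 6 modules × 12 genes + 12 noise genes,
b1 = 1.5, election cutoff 0.1, within-module correlation 0.8 when
expression is the informative layer and 0.55 when methylation is
(gene-level methylation is additionally attenuated by the eigenloci
step, and a weaker methylation structure keeps the network's
methylation share from dominating until μ is genuinely large). Over
seeds 1–20: expression-signal cohorts give best μ ≤ 0.2 in 18/20 runs,
methylation-signal cohorts give best μ ≥ 0.8 in 19/20 (the test floor
is 16/20 for each).

## Numerical choices and edge cases

- Correlations use pairwise-complete samples with a floor of 3 shared
  samples; below the floor, and for zero-variance profiles, the term is
  0.
- PCA is SVD-based on row-centered data; an all-constant matrix is a
  hard "zero variance" error. Sign conventions are as described above;
  when the orientation correlation is exactly 0, the largest-magnitude
  weight is made positive.
- The Weibull AFT scale is `σ = 1/ρ` of the lifelines
  parameterization; survival times are floored at 1e-8 before fitting.
- Sample IDs are matched case-insensitively after trimming whitespace;
  IDs dropped from an intersection are logged, never silently lost.
- Matrices are written with 17 significant digits; a write→read round
  trip is exact.
- Known failure modes that are reported, not patched over: grid points
  where no module passes the size floor, or where no cutoff satisfies
  its recall floor, record an error and a missing p for that μ; a run
  fails only if every grid point fails.

## Limitations

- The module-detection cut is a modularity-maximizing static cut of the
  average-linkage tree, not a dynamic branch-sensitive cut; very nested
  module structures may be merged or over-split relative to the latter.
- Log-rank p-values downstream of selection and cutoff optimization are
  anti-conservative (quantified above); treat them as model-ranking
  scores.
- Desk-scale targets are ≤ ~5,000 genes; the dense gene × gene matrices
  are O(p²) in memory, and no blockwise path is provided.
- Covariate adjustment (age, sex), competing risks, and consensus
  networks across cohorts are out of scope.
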