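# Methods

This note documents the models, parameter choices and numerical decisions
behind `coexnet`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Synthetic cohort model

The generator uses a latent-factor model: module *m* has one standard
normal factor f_m per sample, and a member gene is
x_g = λ·f_m + σ·ε_g with λ = σ·√(ρ/(1−ρ)), so the expected
within-module correlation equals ρ. Defaults (the package's study
conditions): 300 genes; 261 control / 153 case samples; four modules of
50 genes; ρ = 0.8; per-module intramodular hubs with elevated loading
(pair correlation (1+ρ)/2); noise SD 1. Three structures are layered on
top:

* **Trait-linked module.** Factor 1 is f₁ = τ·d̃ + √(1−τ²)·ε with d̃ the
  standardized diagnosis indicator and τ = 0.6, so the module eigengene
  correlates with diagnosis at ≈ 0.6.
* **Disease-specific hub.** One background gene receives
  −λ·(f₁+f₂)/√2 in **case samples only** (noise of matched variance in
  controls). In the case network it carries the strongest *negative*
  correlations (≈ −√(ρ/2) ≈ −0.63 per module gene at ρ = 0.8), which is
  precisely the edge class the signed-weight spanning tree prioritizes;
  in controls it is indistinguishable from noise. This instantiates a
  repressor-like regulator that is central in disease and absent in
  health, without being a module member itself.
* **Batch artifact.** A random `batch_fraction` (default 0.3) of samples
  gets +`batch_shift`·σ added on a random quarter of genes, and the
  metadata records the corresponding library protocol level — emulating a
  kit-level technical confound. Default shift 1 SD; detectability tests
  use 3 SD.

Values are on a log-like Gaussian scale; `2**X` gives TPM-like positives
when the log2(x+1) path needs exercising. The generator does **not**
model count noise (negative binomial), read-level artifacts, or eQTL
structure; passing benchmarks therefore demonstrates algorithmic
correctness and recoverability of block-correlation structure, not
robustness to RNA-seq count noise or annotation error.

## Preprocessing

* **Variance filter** keeps genes with sample variance strictly > 0.01,
  applied on the scale provided (before any log transform); strict `>`
  makes boundary behavior deterministic.
* **Surrogate variables** are the top right-singular vectors of the
  residuals against the *null* design (covariates only). Using null-model
  residuals — not full-model ones — is essential: it leaves
  diagnosis-correlated latent structure visible, so the retention rule
  (keep an SV only when its two-group association with diagnosis has
  p ≥ 0.05) can actually exclude components that would otherwise absorb
  the biological contrast. The number of candidate SVs is chosen by the
  same permutation parallel-analysis rule as the PCA branch, capped at
  `q_max`. On data whose dominant variance is diagnosis-orthogonal
  biology (like the synthetic modules), retained SVs can legitimately
  absorb co-expression structure; the pipeline exposes `q_max` so a known
  single technical artifact can be removed with `q_max=1`.
* **Outlier masking** cuts the average-linkage dendrogram (Euclidean
  distance on z-scored genes) at the largest merge-height gap within the
  top quartile of merges, flags clusters holding < 10% of samples, and
  never discards more than half the cohort. The cut only happens when
  that gap spans ≥ 0.3 of the full merge-height range: homogeneous
  high-dimensional Gaussian cohorts show top gaps around 0.1 of the range
  while a single 10-SD-shifted sample pushes the gap above 0.9, so 0.3
  separates the regimes with a wide margin on both sides.
* **PVCA-style decomposition** weights per-component covariate R² by the
  component's eigenvalue share and normalizes so covariate fractions plus
  residual sum to one; per-component R² sums above 1 (overlapping
  covariates) are scaled back proportionally. This is an approximation of
  the mixed-model variance-component decomposition, adequate for
  flagging dominant technical factors, not for unbiased variance
  estimates.

## Graph branch

Spearman correlation is the default (Pearson by flag). Sparsification
keeps the closed extreme tails (≥ 0.8 of the maximum positive, ≤ 0.8 of
the minimum negative, extremes over off-diagonal entries) and then the
largest connected component. Note the negative cutoff is *relative to the
observed minimum*: on data whose most negative correlation is itself
noise, the negative tail admits noise edges — one reason community
recovery is benchmarked on a graph whose negative extremes are planted
structure.

Prim's algorithm starts from the lexicographically smallest node; the edge
key is the raw signed weight (default: most-negative preferred, the
repressor-mapping mode) or 1 − |w| (absolute mode, strongest magnitude
preferred); ties break on (key, endpoint ids) so trees are deterministic.
Both modes are verified against exhaustive spanning-tree enumeration on
small graphs and an independent Kruskal implementation on 50-node graphs.

Communities and centralities use the unweighted view. Girvan–Newman
returns the maximum-modularity partition along the removal sequence;
Louvain runs at resolution 1 with a seeded sweep order. Eigenvector
centrality is power iteration (tol 1e-10, max 10 000 iterations), scaled
to maximum entry 1; betweenness counts unordered pairs; closeness is
(n−1)/Σd. Scaled centralities are per-measure min–max over the whole
tree. A caveat documented by measurement: maximum-modularity partitions
of *trees* split 50-gene module subtrees into ~3 pieces (ARI ≈ 0.55
against planted labels for both algorithms) — a resolution property of
sparse trees, so module-recovery benchmarks run community detection on
the sparsified graph, where recovery is essentially perfect (median
ARI 1.0).

Differential centrality: Δ = scaled_case − scaled_control per measure
(absentees score 0), composite = mean over the four measures; classes use
hi = 0.5, lo = 0.3 (pathology-specific: case composite ≥ hi and control
composite ≤ lo; control-specific mirrored; shared if both ≥ hi). The
thresholds are package defaults for a qualitative criterion and are
configurable.

## Module branch

Signed adjacency ((1+cor)/2)^β (unsigned |cor|^β by flag); self-adjacency
excluded from connectivity; TOM diagonal set to 1. The soft-threshold
scan bins connectivity into 10 equal-width bins and regresses
log₁₀(frequency) on log₁₀(mean k); signed R² = R²·(−sign(slope)); the
chosen β is the smallest reaching 0.9, else the argmax with a warning.
The tree cut is a simplified dynamic cut: cut at 0.99 of the maximum
merge height, then recursively split a cluster at its largest internal
merge-height gap (two levels) — but only when the gap exceeds the global
median gap *and both halves stay ≥ the minimum module size*; without the
size guard the gap rule would shatter clean modules, since within-module
merge gaps are tiny. Modules below 50 genes become background (label 0).
Eigengenes are unit-norm first right-singular vectors of the
gene-standardized submatrix, sign-oriented to positive mean member
correlation; merging fuses the closest eigengene pair while
1 − cor < 0.1, recomputing after every merge (module count strictly
decreases, so the loop terminates). GS uses |Pearson cor| with the 0/1
diagnosis (signed by flag); module–trait p-values are two-sided Student t
on n−2 df. MDS is classical Torgerson double-centering; non-positive
eigenvalues produce zero coordinates with a warning.

## PCA branch

SVD with samples as observations; deterministic sign convention (each
loading column's largest-magnitude entry is positive). The permutation
null shuffles every gene independently across samples (B = 20), which
preserves marginals and breaks inter-gene correlation; retention is the
consecutive-prefix rule with strict `>` against the mean permuted
variance at each rank. A statistical caveat, measured and documented
deliberately: on *pure noise* the observed matrix is itself an
exchangeable draw from the permutation distribution, so the first rank is
retained with probability ≈ 0.5 and P(r* ≤ 1) ≈ 0.70 — the mean-based
rule is not conservative at rank 1 (a percentile-based rule would be, but
the mean rule is this pipeline's definition). With genuine structure the
rule is sharp: planted rank-3 signal at 3:1 SD is recovered exactly in
20/20 seeds. Loading extraction keeps genes within `range_retain` of
either extreme of each component's loading range (closed inequalities,
with a 1e-9 relative tolerance so boundary genes survive floating-point
rounding).

## Enrichment and ranking

The hypergeometric upper tail is computed in log space via the survival
function; it reproduces published enrichment p-values exactly at printed
precision from their printed (k, n, K, N) inputs. Benjamini–Hochberg is
the standard step-up; Storey's q uses the single-λ estimate
π̂₀ = min(1, #{p > 0.5}/(0.5·m)) — a coarser estimate than the λ-grid
spline of dedicated q-value packages, so q-values are reported for
filtering, not as calibrated FDR estimates. The adjustment family is all
sets tested for one cluster within one collection. Type-I calibration is
benchmarked in a near-continuous regime (universe 5000, sets of 1000,
queries of 250; measured 0.042 at the 0.05 level); with small sets the
discrete test is conservative (≈ 0.027 at sets of 250/queries of 100),
which is a property of the statistic, not the implementation.

Target ranking: Rank A = pathology-specific differential class, MM > 0.80,
GS > 0.20 and tractable; Rank B = same evidence with unknown/intractable
chemistry; Rank C otherwise. The MM/GS thresholds reuse the hub rule; the
class predicates are exhaustive, mutually exclusive, and monotone in each
axis (enumerated in tests). A systems-level integration axis (protein
interaction embedding) is accepted only as an optional annotation column,
never computed — no interaction network is in scope.

## Problem sizes

Benchmarks run at desk scale by design: 300-gene cohorts for recovery
experiments (20 seeds), 100×60 and 100×40 matrices for scree behavior,
200 + 100 random graphs for the MST oracles, 2000 draws for ORA
calibration. These sizes give the binomial assertions comfortable margins
while keeping the full suite around two minutes.
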