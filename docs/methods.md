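# Methods

## Model and procedure

The pipeline targets two-class discrimination on wide omics matrices
(n samples × d variables, d ≫ n, labels −1/+1). The estimator is linear,
`f(x) = β·x`, with the offset identically zero because every design matrix
is centered column-wise on its own training part; held-out data are always
centered with the training means, the only leakage-free choice.

Fitting is a double optimization:

1. **Selection.** β minimizes the naive elastic-net functional
   `(1/n)‖y − Xβ‖₂² + τ‖β‖₁ + μ‖β‖₂²`, solved by plain ISTA:
   `β⁺ = S_{τ/C}(β − (1/C)[(2/n)Xᵀ(Xβ − y) + 2μβ])` with the soft-threshold
   operator `S` and step constant `C = 2(σ_max(X)²/n + μ)`, which bounds
   the gradient's Lipschitz constant and guarantees monotone descent. The
   `1/n` loss scaling is a convention; it only reparameterizes (τ, μ, λ).
   With this scaling the all-zero solution is optimal exactly when
   τ ≥ τ_max = max_j |(2/n)X_jᵀy|.
2. **Classification.** Ridge (RLS) on the selected support:
   `β_S = (X_SᵀX_S + nλI)⁻¹X_Sᵀy`; the class is `sign(β·x)` with ties at
   exactly zero assigned to the positive (diseased) class.

Model selection and error estimation use two nested stratified K-fold
loops. Per outer fold, the inner loop scores every (τ, λ) grid cell by the
mean validation error of the select-then-refit composite; the winner is
refit on the whole outer-training part and scored on the outer test fold
(TP/FN/FP/TN). Each variable's **frequency score** is the percentage of
outer folds whose selected list contains it; the **signature** keeps
variables with frequency ≥ threshold (inclusive — lists conventionally end
with rows sitting exactly at the cut). Signatures are reported at μ = 1,
where correlated partners of predictive variables are retained; the list at
the smallest μ on the path (the *minimal list*) fixes the cluster count for
the structuring step.

A final model refits RLS on the full training set restricted to the
signature, with λ equal to the median of the outer-fold λ\* values — a
robust summary, since the protocol itself does not single out one fold's
parameters.

Signature profiles are clustered by k-means under the correlation distance
`1 − Pearson`. Each profile is standardized to zero mean and unit norm,
after which squared Euclidean distance equals twice the correlation
distance, so standard Lloyd iteration with k-means++ restarts minimizes the
correlation-distance objective exactly; consequently assignments are
invariant to positive affine rescaling of any profile, and exactly
duplicated profiles always co-cluster.

Enrichment is the upper-tail hypergeometric test `P(X ≥ k)` for an overlap
of k signature genes with a K-gene set inside an N-gene universe, n being
the signature's size within the universe. The tail is summed in log space
(log-binomials via `gammaln`, combined with `logsumexp`), exact to ~1e-14
relative error against integer-arithmetic enumeration and stable at
p ~ 1e-26. Flags follow the over-representation convention: *significant*
means raw p ≤ α (default 0.05); *enriched* additionally requires
k ≥ min_genes (default 3). No multiple-testing correction enters the flags;
a Benjamini–Hochberg column is emitted as a clearly-labeled extra.

Late integration operates on results, not raw data: gene-level
intersections of signatures (probesets collapsed to genes, Entrez ID
primary, symbol fallback) and a pathway-level table marking each set as
enriched / significant-only / absent per signature, with all-way and
pairwise sharing summaries.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| τ grid | l1 path per training part | 20 log-spaced in [τ_max/1000, τ_max] | spans empty-to-dense selections; τ_max is data-driven |
| λ grid | ridge refit | 7 log-spaced in [1e-4, 10] | covers near-OLS to strong shrinkage |
| μ path | l2 (correlation) levels | 0.01, 0.1, 0.5, 1.0 | minimal list → full correlated modules; 1.0 is the reporting level |
| K_outer, K_inner | CV folds | 10, 10 | standard for ~100-sample cohorts; configurable (5 is sensible for larger n) |
| threshold | frequency cut, % | 40 (inclusive) | stability elbow convention of the protocol |
| α, min_genes | enrichment flags | 0.05, 3 | over-representation defaults |
| tol, max_iter | ISTA stop | 1e-6, 1e5 (final fits); 1e-5, 1e4 inside CV | CV needs supports, not 1e-6 optima; optimality is verified separately at tight tolerance |
| n_restarts | k-means inits | 20 | restarts never worsen the kept optimum |

Tie-breaks are deterministic and documented: inner-loop ties prefer larger
τ (sparser), then smaller λ; `sign(0) → +1`; signature ordering is by
descending frequency, then variable ID.

Empty selections are handled, not dropped: an inner-CV cell whose selection
is empty on a fold is scored with that fold's majority-class error, and an
outer fold with an empty selection predicts the training majority class.
This keeps error estimates defined without biasing the search toward dense
models.

## Synthetic data

The generator emulates the statistical shape of small-cohort case/control
omics studies: blocks of equicorrelated variables
(`x = √ρ·z_block + √(1−ρ)·ε`, exact pairwise population correlation ρ), an
independent-noise tail, and a planted sparse signal — the first
`n_informative` variables get a between-class mean difference of
`effect_size` within-class standard deviations. Labels are assigned first
(fixed counts from `class_balance`), so the signal is a clean class-mean
shift. One integer seed drives everything; identical spec + seed is
bitwise-reproducible. A companion gene-set generator plants one causal set
(all informative variables plus padding) among random sets so enrichment
power is testable.

The default spec (n = 100, d = 500, ten informative variables inside
ρ = 0.5 blocks of five, effect 1.5, balanced classes) is the benchmark
design used by the test suite: strong enough that a sound implementation
recovers ≥ 90 % of the planted support at the 40 % threshold with ~10 %
CV error, and paired with a null variant (no informative variables) whose
CV error must stay at chance.

What the generator does **not** emulate: platform artifacts (probe
effects, normalization residuals), heavy-tailed or skewed abundance
distributions, batch structure, label noise, or correlated blocks that
straddle the informative/noise boundary in arbitrary patterns. Passing
tests demonstrate correctness of the machinery and calibration under the
modeled conditions — not performance on any particular real cohort.

## Numerical choices

- Step constant from `σ_max(X)` (exact spectral norm; matrices are small
  enough that SVD is cheaper than safeguarding a power iteration).
- Warm starts along the decreasing τ path make grid evaluation cheap; the
  RLS grid reuses one eigendecomposition of the smaller Gram matrix across
  all λ, and the dual (kernel) form is used when the support exceeds the
  sample count. Both shortcuts are verified against direct solves.
- Non-convergence at `max_iter` is flagged (warning + `converged_`
  attribute), never silently accepted.
- Duplicated columns receive bit-identical updates under ISTA, so the
  grouping effect (equal weights at μ > 0) holds to machine precision.
- Degenerate inputs fail loudly with the offending field named: non-finite
  matrix entries, labels outside ±1, a class smaller than K, constant
  profiles under correlation distance, k above the distinct-profile count,
  inconsistent hypergeometric counts, empty signatures at refit.

## Design choices that were genuinely open

- **Joint (τ, λ) grid search** in the inner loop (rather than sequential
  tuning): simplest defensible reading of a two-parameter selection.
- **μ as an external path parameter**, not tuned by the inner loop: the
  reporting level is fixed at μ = 1 by the protocol, and the path exists
  to expose the sparsity/correlation trade-off, not to optimize it.
- **Final-model λ = median of fold λ\***.
- **Clustering on standardized profiles** (standardization is part of the
  distance, not a preprocessing option).
- **Enrichment universe = the collection/annotation gene space** by
  default, configurable; raw p-values drive the flags.
- **Label codings are declared, never inferred** — cohorts code their
  classes differently, and a silent guess would flip signs downstream.

## Bundled reference tables

Three published Alzheimer's-disease signatures produced with this protocol
(a plasma signaling-protein panel; GEO series GSE1297 and GSE5281) ship as
small TSVs with their KEGG over-representation rows. They exercise the
result-level stages with fixed expected outcomes: 21/12/39 rows retained
at the inclusive 40 % threshold, 11 unique GSE1297 genes, the four-gene
microarray intersection {RGS4, MCTP1, CD44, XIST}, and the
significant-versus-enriched distinction (k = 14 at p = 9.69e-26 enriched;
k = 2 at p = 6.66e-4 significant only; k = 1 at p = 7.59e-2 neither).
Recomputing the overlap flags strictly from the printed raw p-values
leaves *no* pathway flagged in all three signatures — the historically
reported three-way overlap (hematopoietic cell lineage, neuroactive
ligand-receptor interaction, MAPK signaling) relied on a looser reading of
the GSE5281 p-values, all of which exceed 0.05. The package reports what
the stated rule yields and notes the discrepancy rather than resolving it.
The underlying expression matrices are external downloads, so those
classification errors (e.g. the protein set's 19 % ten-fold CV error and
7/92 test error) are out of scope for automated checks here.

## Limitations

- ISTA is the plain proximal iteration; no acceleration (FISTA) or exact
  path algorithms. Adequate at d ≤ a few thousand; large d or very fine
  grids would warrant acceleration.
- Binary classification only; multi-group test sets must be binarized
  upstream (e.g. disease versus everything else).
- Enrichment ignores gene-set topology (no GO-DAG-aware algorithms) and
  reports raw p-values by design.
- The error estimate is plain nested CV; no permutation significance or
  repeated CV.
- Missing values are rejected, not imputed; inputs are expected to be
  normalized, complete matrices.
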