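# Methods

## Product tensors from multi-view matrices

The package addresses multi-view integration without view weights. Views
are features × samples matrices; they either share samples (Case I) or
features (Case II). Rather than stacking matrices (which lets the view with
more features dominate) the views are combined multiplicatively:

* Type I, m+1 modes: `x[i1..im, j] = prod_k X_k[i_k, j]` (Case I; Case II
  swaps the roles of i and j). Every mode keeps its own identity, so no
  weighting question arises.
* Type II, m modes: the Type I tensor summed over the shared mode. For two
  Case I views this is the matrix product `X1 @ X2.T`, computed directly by
  contraction — the Type I tensor is never materialized.

Type I storage grows like `M * prod_k N_k`; a configurable element cap
(default 2×10⁸) turns an over-budget request into an error that recommends
the Type II route, which is smaller by the shared-mode length.

## HOSVD

Plain higher-order SVD, no HOOI refinement: the mode-k factor is the top
left singular vectors of the mode-k unfolding; the core is the tensor
contracted with every factor transposed. Implemented directly on numpy's
LAPACK SVD. Choices that matter:

* **Unfolding**: mode-k fibers as rows, remaining modes in cyclic order.
  Left singular vectors are invariant to column permutations of the
  unfolding, so this only pins down intermediate layouts.
* **Wide unfoldings** (columns > 4 × rows) go through the Gram matrix
  `A Aᵀ` eigendecomposition instead of a dense SVD — identical leading
  vectors, far cheaper when the other modes are large. Agreement with the
  dense path is asserted in tests.
* **Sign convention**: each factor column's largest-|entry| is made
  positive (ties: first index). All selection and ranking outputs are
  invariant under column sign flips; the convention only makes runs
  byte-reproducible.
* **Truncation**: default rank min(10, mode size) per mode. Ten components
  comfortably cover the range in which core couplings are inspected; full
  ranks are used in the reconstruction/energy tests.
* Components within a mode are ordered by decreasing unfolding singular
  value; core entries are ranked by decreasing |G| with lexicographic
  tie-break, 1-based indices.

For a Type II tensor the shared-mode vectors do not exist in the
decomposition; they are recovered per view k as `U_kᵀ X_k` (Case I) or
`U_kᵀ X_kᵀ` (Case II). This yields m sets of sample (or feature) vectors —
one per view — whose cross-view correlations are the read-out for latent
correspondence.

## Chi-squared outlier extraction

Given chosen factor columns (1-based indices ℓ), each feature gets
`score_i = Σ_ℓ (u_{ℓ,i} / σ_ℓ)²` with σ_ℓ the standard deviation of column
ℓ over features (computed about the column mean, ddof = 1; the score itself
divides the raw entry, matching the outlier statistic's definition — factor
columns of centred data are near zero-mean, making the distinction
negligible there). P-values are the χ² upper tail with df = number of
components, BH-adjusted (statsmodels step-up); features with adjusted
P < α are selected. Defaults: components 1–5, α = 0.01; per-view overrides
support protocols that use fewer components or α = 0.05 for the smaller
view. Exact-zero P-values are reported as the smallest positive float so
BH and sorting stay well-defined.

The caveat that matters: with *uncentred* all-positive data the leading
factor column is nearly constant, its σ is small, and every feature scores
as an "outlier". The χ² score is meaningful on column-standardized input
(zero mean, sum of squares N per sample column — the expression-profile
normalisation applied by default in the pipeline); see Limitations for how
this plays out on the synthetic benchmark.

## Association utilities

* Class dependence of a sample vector: least-squares class-means
  (categorical regression) F-test against the intercept-only model —
  equivalent to one-way ANOVA. Affine-invariant; perfect fits report the
  minimal positive float.
* Template–profile correlations: vectorized Pearson r over the
  concatenated condition/time axis, P from the t transform
  `t = r sqrt((n−2)/(1−r²))`, BH adjustment over testable features.
  Zero-variance profiles are flagged and excluded rather than poisoning
  the adjustment. (An empirical-null FDR would be an alternative here; BH
  is used as the package-wide adjustment for consistency.)
* Scale/shift overlay: per feature, `template = a_i·profile + b_i` by least
  squares with one (a, b) shared across all conditions of that feature;
  constant profiles get a = 0, b = mean(template), flagged. Group
  differences at each time point are tested across the selected features'
  fitted values: pooled two-sided t for two groups, the class-means F-test
  for three or more.
* Cross-view pairing of singular value vectors: UPGMA (scipy average
  linkage) at distance −|Pearson r|. Distances are negative by
  construction; average linkage only needs their ordering, so they are
  used unshifted. Sign flips of any vector leave the tree unchanged.

## PCA baseline

Gram-matrix PCA on features: eigenvectors of `G = X Xᵀ` are per-feature
scores, loadings are `v_k = Xᵀ u_k`. Computed via the SVD of X (not the
N × N gram matrix) for stability; equivalence is asserted in tests.
Optional screen: keep only components whose loadings show class dependence
at P < 0.05 before the χ²/BH step. The baseline finds outlier features but
— by construction — produces per-view loadings whose cross-view pairing
fails where the tensor route succeeds; that contrast is the point of
carrying it.

## Synthetic benchmark

Two 1000 × 50 views; rows 1–50 are `c/2·g_k(j) + (1−c)·U[0,1]` with
`g1(j) = j/M + sin(πj/M)`, `g2(j) = (M−j)/M + sin(πj/M)` (j = 1..M), rows
51–1000 are raw U[0,1] draws at full weight. Defaults c = 0.8,
N = 1000, N0 = M = 50 are the benchmark's study conditions. Noise is drawn
entry-wise from one RNG stream (view 1 fully before view 2, row-major), so
a seed fixes the dataset bit-for-bit. The generator returns the base
curves and the signal index set for use as test oracles.

What the benchmark emulates: two modalities driven by a shared latent
process whose per-view expressions (opposite ramps + common sine) are
nearly uncorrelated row-by-row (raw signal-row correlation ≈ 0.06 ± 0.14
at n = 50). What it does not emulate: heavy-tailed expression
distributions, correlated noise across features, batch structure, or
unequal view sizes — passing it shows the machinery recovers a planted
cross-view correspondence, not that any real dataset behaves this way.

By default the pipeline standardizes omics-style input columns but the
benchmark is decomposed raw; the correspondence read-out (projected
components 2–3 pairing across views at |r| ≈ 0.97) rides on the raw-scale
structure, with component 1 absorbing the uniform-noise mean background.

## Problem sizes in the test suite

Property tests run at small random shapes (≤ 10 per mode). The
correspondence check runs the full N = 1000 Type II route over 10 seeds;
the Type I feature-recovery checks use N = 1000 for single-seed score
separation and an N = 300 variant for the 10-seed sweep — sizes chosen so
the whole suite completes in well under a minute on one core while keeping
the full-scale conditions where the claim depends on N.

## Known limitations

* On the benchmark at c = 0.8, χ²/BH selection at α = 0.01 on Type I
  feature factors does not cleanly isolate the 50 signal rows: raw
  (all-positive) input degenerates as described above, and on standardized
  input signal features sit at |u|/σ ≈ 2.9 — visibly outlying (their
  scores dominate the noise distribution, and they are strongly enriched
  among the top-ranked features) but short of the z ≈ 3.5 that BH at 0.01
  over 1000 features requires. The selection thresholds are calibrated for
  real expression data, where outlier features separate much more
  strongly; on the benchmark the honest statement is enrichment, not
  near-perfect recovery, and the tests assert exactly what the
  simulations show.
* Plain HOSVD is not the best low-rank approximation (no HOOI); it is
  used deliberately as the canonical, deterministic one-pass algorithm.
* Dense tensors only; no missing values, no sparse storage.
* CP/PARAFAC and higher-order GSVD are out of scope.
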