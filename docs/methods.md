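# Methods

This note documents the model, the estimation choices, the synthetic
data used to validate the pipeline, and the numerical decisions that a
maintainer or user should know about.

## Model

Each group's data are modelled as zero-mean multivariate Gaussian with
sparse precision matrix Ω; a zero ω_ij means nodes i and j are
conditionally independent given the rest, and the group *graph* is the
support of Ω. Because control and patient networks are expected to be
largely similar, the two precisions are estimated jointly with the
fused graphical lasso objective

    Σ_k n_k (−log det Θ_k + tr(S_k Θ_k))
      + λ₁ Σ_k Σ_{i≠j} |θ_ij^(k)|
      + λ₂ Σ_{k<k'} Σ_{i,j} |θ_ij^(k) − θ_ij^(k')|

over K classes (the two groups for static graphs; the windows of one
subject for dynamic estimation). The diagonal is never l1-penalised;
the fusion term includes the diagonal. Inputs are standardised to unit
variance before estimation, so the adjacency decision is
scale-invariant.

### ADMM solver

- **Splitting.** Θ_k = Z_k with scaled duals U_k. The Θ-update is the
  standard per-class eigen decomposition solve of
  ρΘ − n_k Θ⁻¹ = ρ(Z_k − U_k) − n_k S_k. The Z-update is an
  elementwise proximal problem over the K class values: the all-pairs
  fusion prox is computed exactly by sorting, subtracting the linear
  shift τ(2k − K − 1), and projecting with pool-adjacent-violators
  (the minimiser preserves the input ordering); soft-thresholding by
  λ₁/ρ afterwards gives the joint prox, exactly as in the chain fused
  lasso. A property-based test verifies the combined prox against
  random perturbations, and the K = 2 closed form against its
  analytic solution.
- **Step size.** ρ starts at the mean class sample count (the
  likelihood gradient scales with n) and is rebalanced by factor 1.5
  whenever one residual exceeds five times the other.
- **Convergence.** Relative primal and dual residuals below tol = 1e−5
  (default); non-convergence raises an error carrying both residuals.
  The default iteration cap is 1000 — a few well-posed instances need
  ~650 iterations — and 2000 for the many-class window problem, whose
  all-pairs coupling converges more slowly.
- **Reported estimate.** The sparse consensus iterate Z (its exact
  zeros define the estimated structure), falling back to the always-PD
  Θ iterate in the rare case Z is not positive definite at the
  tolerance.
- λ₁ = λ₂ = 0 shortcuts to the closed-form inverse.
- ADMM objectives are not strictly monotone in theory; on all tested
  inputs the tracked objective decreases up to a 1e−5 relative ripple,
  which is what the invariant test asserts.

### Penalty scale

`joint_graphical_lasso` takes *absolute* penalties, matching the
objective above. The pipeline entry points (`build_group_graphs`,
`window_fnc_series`) interpret their `lambda1`/`lambda2` arguments on
the per-observation scale and multiply by the mean class sample count
internally, so the defaults below behave consistently whether a group
contributes 400 or 80,000 concatenated time points.

Defaults: λ₁ = 0.1, λ₂ = 0.05 for the two-group problem. For windowed
estimation the fusion default is λ₂ = 0.005: the all-pairs penalty
couples each window to K − 1 ≈ 27 others, and at the two-group weight
it measurably flattens genuine state dynamics toward the subject mean
(state clustering degrades to chance). These values are design
defaults, not estimates; the model exposes them everywhere.

### Edge significance

Edges come from the penalised partial correlation
ρ_ij = −ω_ij/√(ω_ii ω_jj) tested with t = r√(df/(1 − r²)), df = n − p
(n samples; p − 2 variables controlled beyond the tested pair),
two-sided, Benjamini–Hochberg corrected at q = 0.05 across the upper
triangle. Entries with |ρ| < 1e−12 (structural zeros after
soft-thresholding) get p = 1. No debiasing is applied to the penalised
estimate, and for windowed data the FFT-resampled sample count is used
as n; both choices reproduce the analysis pipeline this package
implements rather than an idealised inference. The type-I error of the
test is verified by simulation under a diagonal-precision null.

## Path analysis

Disconnector detection walks the connected components of the reference
graph, finds components spread over ≥ 2 comparison-graph components,
and sieves the induced-subgraph edge differences, keeping edges whose
endpoints lie in distinct comparison components (global components, not
merely the two being combined — an equivalence test against the direct
characterisation "missing edge with endpoints unreachable in the
comparison graph" runs exhaustively over all five-node graphs and on
random 30-node instances). Component pairs separated only indirectly
contribute nothing. Connectors are the same computation with the inputs
swapped.

The covariance decomposition evaluates, per simple path, the term
(−1)^(t+1) · Π ω over the path's edges · det(Ω_∖P)/det(Ω). Determinants
of principal submatrices are computed by Cholesky in log-space (they
are positive definite by eigenvalue interlacing); the sign is carried
analytically; the empty-matrix determinant is 1. Path enumeration runs
over the significance-thresholded support graph with a hard cap
(default 10⁶ paths) — exceeding the cap is an error rather than a
truncation, because truncation would silently break the conservation
identity Σ weights = (Ω⁻¹)_xy. Paths are stored canonically (smaller
endpoint first) so path sets from different groups can be intersected;
contributions are signed percentages of the endpoint correlation, may
individually exceed 100 % or be negative, and a pair is flagged when
either group's distinct-path share strictly exceeds 50 %.

At the fitted-model level (`GroupGraphResults.decompose_pair`), the
precision is first projected onto the significant support (non-edge
entries zeroed, diagonal loaded if needed): the reported graph and the
decomposition then describe the same model and conservation is exact.
Without the projection, tiny non-significant entries outside the graph
would leave a visible residual.

## Dynamic pipeline

Windows are half-open [start, start + w) with K = ⌊(T − w)/s⌋ starts at
multiples of s — the convention that reproduces 28 windows for
(T, w, s) = (162, 20, 5); the final offset K·s is not emitted even
though it would fit. Windows are rectangular. Each window is upsampled
by Fourier zero-padding (factor 20 by default) before its covariance
enters the joint estimation across the subject's windows; the
per-window connectivity matrix is the correlation implied by the
inverse of that window's precision estimate.

States are found in two phases with L1 k-means (median centroids,
cityblock assignment): subject exemplars — windows at strict local
maxima of the across-feature variance, endpoints qualifying against
their single neighbour — are clustered with 50 random restarts, and the
resulting centroids seed a single run over all windows. Empty clusters
re-seed at the worst-fit point. The elbow criterion is operationalised
as the k maximising the second difference W(k−1) − 2W(k) + W(k+1) of
the within-cluster cost, ties toward smaller k; note this rule finds
the kink reliably when the pre-kink cost curve is roughly linear
(near-equidistant clusters) and can prefer a smaller k when coarse
merges dominate the curvature. Group tests use pooled-variance
two-sample t-tests (Welch optional) on per-subject state means. All
stochastic steps take an explicit seed (default 0); the pipeline is
reproducible byte-for-byte for a fixed seed.

## Synthetic data

The generators emulate the data regime the method targets: zero-mean Gaussian
node × time series from sparse positive-definite precisions with
planted group differences.

- **Precisions.** Erdős–Rényi support, off-diagonal magnitudes in
  [0.25, 0.45] with random signs, diagonal loaded until the smallest
  eigenvalue reaches 0.1. The magnitude range makes recovery reliable
  at desk-scale sample counts; everything is configurable.
- **Static planted scenario** (p = 15, 2000 samples/group in the
  validation suites). The control support has a connected "arena"
  block plus small auxiliary components; the patient support removes
  chosen arena bridges (each removal separates its endpoints —
  disconnectors) and chains the auxiliary components with fresh
  cross-component edges (connectors). By construction the direct
  characterisation recovers exactly the planted sets, which is checked
  at generation time.
- **Dynamic planted scenario** (p = 8, 3 states, 8 subjects/group,
  T = 162). States share one support but draw state-specific signs and
  magnitudes (0.35–0.5) — distinct sign patterns, the well-separated
  recurring profiles sliding-window analysis assumes. A designated
  pendant node hangs off the support by one bridge; the affected state's
  patient precision drops that bridge and every other state is
  identical across groups. Subjects dwell in two contiguous
  equal-length segments (one state switch per scan) whose boundaries
  sit on the window step grid, so each window is pure, a 75/25 blend,
  or an exact 50/50 tie; ground-truth labels follow the > 50 % majority
  and ties are excluded from scoring.

What passing these suites shows — and does not. The generators draw
i.i.d. samples in time with no hemodynamic autocorrelation, no site or
subject-level covariance offsets, and cleanly separated states; exact
planted-set recovery and ARI ≥ 0.95 under these conditions demonstrate
the correctness of the estimation-testing-comparison chain, not
expected performance on real fMRI, where effective sample sizes are
smaller and states mix continuously.

## Validation problem sizes

The test suite runs the planted static recovery at 20 seeds
(p = 15, 2000 samples/group) and the dynamic recovery at 20 seeds
(16 subjects, 28 windows each); calibration uses 2000 null replicates
for the edge test and 500 for the group test; decomposition
conservation covers 200 random precisions (p ≤ 10, density 0.35) at
1e−8; oracle equivalence covers all 2¹⁰ five-node graphs against
sampled counterparts plus 500 random 30-node pairs.
`scripts/acceptance.py` recomputes the same quantities at moderately
smaller replicate counts (10 static seeds, 5 dynamic seeds, 60
conservation matrices, 1000 + 500 calibration replicates), sizes chosen
to keep a complete from-scratch rerun within a few minutes.

## Known limitations

- The all-pairs fusion penalty treats a subject's windows as
  exchangeable; a chain (temporal-order) fusion might suit smooth
  dynamics better but is not the estimator implemented here.
- The significance test treats FFT-resampled points as independent
  samples, inflating the effective n for windowed graphs; this
  reproduces the analysed pipeline deliberately.
- Path enumeration is exponential; dense supports can exceed the path
  cap, which is a hard error by design.
- λ₁/λ₂ are fixed defaults; `select_penalties_aic` offers an optional
  AIC grid search, but no cross-validated or stability-based selection
  is built in.
- Exactly two groups are supported at the model layer (the solver
  itself is K-generic).
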