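# Methods

## Temporal unwrapping

Activity is z-scored per node with the **population** standard deviation
(divisor T). Under this convention the arithmetic time-mean of the
co-fluctuation tensor `values[i, j, t] = z_i(t) z_j(t)` equals the
Pearson correlation matrix exactly (to round-off), so the "unwrapping
identity" is asserted at 1e-10 rather than being off by a factor
(T-1)/T. The tensor's diagonal (squared z-scores) is retained but all
profile extractions use off-diagonal entries only. Frame amplitude is
the root-sum-square of the upper-triangle entries.

## Structural predictors

All graph measures operate on the minmax-normalized connectome. Because
the diagonal is zero, the minimum over all entries is 0 and the
normalization reduces to division by the maximum: absent edges remain
absent, and the weakest existing edge keeps a positive weight (mapping
it to zero would make its `-log` length infinite). Edge lengths are
`-log(w)`; absent edges are non-traversable (excluded from the graph,
not +inf entries in arithmetic), and zero-length edges (the
maximum-weight edge) are legal — the Dijkstra-based all-pairs search
tolerates them, and its output is tested for exact equality against an
independent Floyd–Warshall triple loop on integer-length graphs.
Weighted communicability is `expm(D^{-1/2} A D^{-1/2})` with
`D = diag(sum_k a_ik)`; isolated nodes are an error.

## The coupling model

For node i and frame t the response is the co-fluctuation profile to all
j != i, the design is `[1, dist_i, spl_i, cmc_i]`, and the fit is
ordinary least squares; coupling is the adjusted R²
`1 - (1 - R²)(n-1)/(n-p-1)` with n = N-1 observations and p = 3
predictors. For each node the design is constant over frames, so all T
regressions share one least-squares factorization (vectorised lstsq).
Frames whose profile has (numerically) zero variance across j get a
missing value and are counted — silently emitting 0 would bias the
temporal statistics. Unadjusted R² is used inside dominance analysis
(the conventional definition); total dominance averages a predictor's
incremental R² over all subsets by subset size and sums to the
full-model R² exactly. The Spearman rank coupling alternative restricts
each node's correlation to structurally connected pairs and is computed
on static FC (a frame-wise variant is a trivial extension); nodes with
fewer than 3 connections are missing with a warning.

One property of this estimator matters for everything downstream: R² is
invariant to scaling of the response, and node i's frame response is
`z_i(t)` times the activity pattern of the other nodes. The scalar
cancels, so **a node's frame-wise coupling does not depend on its own
signal at all** — it measures how well the node's structural profile
explains the *shared* activity pattern at that frame. Frame-wise
coupling is therefore a neighborhood-resolution quantity, while static
coupling (a fit of the node's own FC profile) is node-resolution. This
asymmetry is intrinsic to the method, not to this implementation.

## Dynamics statistics and conventions

Temporal standard deviations use the sample convention (ddof = 1);
percentiles use linear interpolation between order statistics;
"probability of larger" counts strict inequalities (ties are
not-larger); the robust spread is P84 - P16 (±1 sd under normality).
The coefficient of variation requires at least 2 non-missing frames and
is undefined (missing, with a warning) when the temporal mean is within
1e-8 of zero. Equal-count gradient bins distribute any remainder to the
lowest bins, with stable (node-index) tie-breaking. Pair-level contrasts
(connected vs unconnected, within vs between network) use the
pooled-variance two-sample t-test on upper-triangle pairs, so
df = N(N-1)/2 - 2. All convention switches are recorded in run
manifests.

## Spin permutations

Rotations are drawn uniformly (Haar) by QR decomposition of a Gaussian
matrix with sign correction and determinant +1, applied to the
left-hemisphere sphere coordinates and mirrored (lateral-axis sign
flip) to the right, so permutation entries never cross hemispheres.
Each parcel receives the value of the *closest rotated* parcel, hence
rows are surjections-with-repeats rather than strict permutations. The
permutation p-value `(1 + #extreme) / (n_perm + 1)` is never zero;
two-tailed by absolute value by default, one-tailed available. Type-I
error under geometry-independent maps is calibrated in the acceptance
suite. Robust correlation constants are the conventional biweight c = 9
and bend beta = 0.2; with beta = 0 and symmetric data the percentage
bend estimator reduces to Pearson, which is tested.

## The synthetic cohort

The generator's purpose is to make every pipeline stage testable with
known ground truth, emulating the features real data exhibit:

* **Geometry** — n/2 points uniform on a hemisphere of the unit sphere,
  mirrored to the other hemisphere; centroids at radius 50 (think mm).
* **Connectome** — edges sampled without replacement with probability
  proportional to `exp(-d / length_scale)`, times a within-module boost
  for a spatially contiguous partition (the analog of intrinsic
  networks); weights follow the same kernel with uniform jitter in
  [0.5, 1.5]; minimal bridging edges keep the graph connected. Cohort
  defaults: N = 100 nodes, 6 modules, density 0.2, length scale 50,
  module boost 25.
* **Covariance target** — the Gram (cosine-similarity) matrix of the
  nodes' communicability profiles. A plain rescaled communicability
  matrix is a near-identity perturbation at these sizes (off-diagonal
  about 0.015) and carries no recoverable frame-wise signal; profile
  *similarity* produces realistic FC-like structure (strong within
  modules, weak between) while staying purely structure-derived, so the
  communicability predictor can recover it by construction. Each node's
  profile may further be mixed with a random profile shared by a small
  sub-module group, weighted by `1 - q` where q is a per-node
  **structure-fidelity** map: low-q regions have functional profiles
  decoupled from their structural embedding. The Gram matrix is PSD by
  construction and is shrunk toward the identity only if its smallest
  eigenvalue falls below 1e-6.
* **Activity** — `x_i(t) = sqrt(w_i(t)) s_i(t) + sqrt(1 - w_i(t)) e_i(t)`
  with `s ~ N(0, target)`, e white, and
  `w_i(t) = baseline + alpha_i sin(2 pi t / timescale + phase)`
  (one seed-drawn phase per subject; period 150 frames, T = 600,
  baseline 0.5). Frames are temporally independent: BOLD
  autocorrelation, hemodynamics and physiological confounds are not
  modeled, so passing tests validate the estimator chain, not robustness
  to those real-data features.
* **Planted hierarchy** — fidelity q is assigned per module, graded from
  0.95 to 0.10 along the spatial principal axis (a unimodal-transmodal
  analog), and the modulation amplitude is tied to it,
  `alpha = 0.4 (q_max - q) / (q_max - q_min)`: weakly coupled regions
  are also the dynamically modulated ones. This co-organization mirrors
  the empirical finding that coupling strength and coupling variability
  are jointly arranged along the cortical hierarchy, and it is what
  makes the planted amplitude recoverable: because frame-wise coupling
  is neighborhood-resolution (see above), modulation planted
  independently of the hierarchy is only partially recoverable (rank
  correlations around 0.2–0.5 depending on the assignment), which we
  verified extensively before adopting the tied design. The annotation
  gradient is the planted hierarchy; networks are the connectome
  modules.

All subjects of a cohort share geometry, connectome, target and planted
maps; only the activity noise differs per subject (a simplification —
real cohorts have individual connectomes). Regressions are still fitted
independently per subject.

## Known limitations

* Frame-wise adjusted R² is a noisy readout (chi-square-like factor
  noise dominates its temporal variance), so cv(R²) recovers planted
  modulation at neighborhood resolution and imperfectly; on the default
  cohort the group-map rank correlation with the planted amplitude is
  about 0.4–0.7 depending on the geometry seed.
* Time-mean dynamic coupling and static coupling are different
  functionals (pattern fit vs profile fit); across nodes they correlate
  around 0.7–0.9 on this generator even with time-constant full-fidelity
  coupling, and their correspondence on real data is expected to be
  broad, not tight.
* Problem sizes used throughout (N = 100 nodes, T = 600 frames, 5
  subjects, 500–1000 spins) were chosen as the smallest cohort at which
  the group-level maps are stable; all analyses scale to larger inputs
  unchanged.
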