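# Methods

## Problem setting

Multi-subject fMRI decomposition looks for a small number of spatial
networks and their time courses in each of K subjects' scans.  After
subject-level PCA, subject k's data is modeled as a noiseless linear
mixture `x_k(v) = A_k s_k(v)` over voxels `v = 1..V`, and a demixing matrix
`W_k` is sought so that `y_k = W_k x_k` recovers maximally independent
components.  Stacking the nth component across subjects gives the *source
component vector* (SCV) `s_n(v) = (s_n^1(v), ..., s_n^K(v))`; exploiting the
statistical dependence inside each SCV is what aligns corresponding
components across subjects without any post-hoc matching.

This package implements three constrained solvers for that problem plus
the evaluation stack used to compare them:

* **ar-cIVA** — IVA under the multivariate-Gaussian SCV model (IVA-G), with
  each constrained component tied to a spatial reference template through
  an augmented-Lagrangian inequality `ε(r_n, y_n^k) ≥ ρ_n^k` whose
  threshold is chosen adaptively per component and subject.
* **tf-cIVA** — the same IVA-G core with a threshold-free regularizer
  `Σ_{n,k} [Σ_{m≠n} ε²(r_n, y_m^k) − ε²(r_n, y_n^k)]`, weighted by `λ/2`,
  which steers component n toward reference n and away from all the others
  without any threshold parameter.
* **ar-cEBM** — subject-wise constrained ICA whose entropies are estimated
  by entropy bound minimization (EBM), with the same adaptive-reverse
  constraint applied per subject (the threshold is indexed by component
  only and reset between subjects).

Similarity `ε(a, b)` is the absolute Pearson correlation: both vectors are
mean-centered before the normalized inner product, so the cosine form and
the correlation reading coincide.

## Cost functions

All costs drop the data-entropy constant (it does not depend on W).

**IVA-G.**  `J(W) = Σ_n ½ log((2πe)^K det Σ_n) − Σ_k log |det W_k|` with
`Σ_n[k, l] = w_n_k' R_kl w_n_l` and `R_kl = X_k X_l' / V`.  The
`IvaGModel` caches all `R_kl` once, so row updates never touch the
V-dimensional data.  A relative ridge `1e-12 · trace/K` keeps SCV
covariances invertible at small V or near-perfect cross-subject
dependence.

**EBM.**  Each row entropy is the tightest of several maximum-entropy
bounds.  For a measuring function `G` and measured statistic
`c = E[G(ŷ)]` of the standardized component, the bound is the entropy of
the max-entropy density `p(x) ∝ exp(a₁x + a₂x² + θG(x))` matching mean 0,
variance 1 and `E[G] = c`.  Four measuring functions are used — `x⁴` and
`|x|/(1+|x|)` (even; sub-/super-Gaussian axis) and `x|x|/(10+|x|)` and
`x/(1+x²)` (odd; skewness) — plus the variance-only Gaussian bound
`½ log 2πe` as a fallback, so the estimate is a valid upper bound for any
sample (the `x⁴` family only exists on the sub-Gaussian side `E[x⁴] ≤ 3`).
The statistic→bound maps are computed once per process by sweeping θ,
solving the moment constraints by 1-D (even) or 2-D (odd) root finding on
a `[-14, 14]` integration grid with 5601 points, and interpolating the
(c, H) pairs with a monotone cubic (PCHIP); the same interpolant's
derivative supplies `dH/dc` for the gradient.  Measured accuracy at
V = 1e5: Gaussian entropy exact to < 1e-3, uniform bound gap ≈ 0.065,
Laplace gap ≈ 0.003 nat.  The tightest-bound index is treated as constant
within a gradient step; the gradient is exact wherever the index is
locally stable.

**Constraints.**  The augmented Lagrangian adds
`(1/2γ) Σ max(0, μ + γ(ρ − ε))² − μ²` to the cost; the multiplier update is
the standard projected ascent `μ ← max(0, μ + γ(ρ − ε))`.  The
adaptive-reverse scheme re-picks every threshold from the grid
P = {0.01, ..., 0.99} each outer iteration: the *assertive* pick (smallest
grid value above the current similarity) while the multiplier is near
zero, switching to the *conservative* pick (largest satisfied value) once
the multiplier exceeds `μ_max`, with a hysteresis band in between.  The
evaluation order per accepted sweep is fixed: similarities → multipliers →
modes → thresholds.

## Optimization

All three solvers share one skeleton: decoupled row-wise gradient descent.
For row n of subject k the decoupling vector `h` (unit, orthogonal to all
other rows) gives `∂ log|det W|/∂w = h/(w'h)`, turning the matrix problem
into sequential vector updates.  Rows are kept unit-norm (the scale
ambiguity of BSS is fixed by normalization; map amplitude is carried by
z-scoring downstream), updated in order n = 1..N with subjects k = 1..K
inner for the IVA methods.  The objective is evaluated once per sweep; a
sweep that raises it is reverted and all live step sizes decay by 0.95.
An accepted sweep whose relative improvement is below 1e-9 also counts as
"failed to decrease" for step adaptation — without this stagnation rule
the steps never shrink on a plateau and the stopping test cannot trigger.
Steps start at 0.1 and rows whose step falls below 1e-8 are frozen, which
guarantees termination.  A run stops when the maximum sign-invariant
change of any normalized demixing row falls below the tolerance (1e-6
default), at `max_iter` (1024 default), or when all rows freeze; the
adaptive-reverse methods often use the full budget because the moving
thresholds keep the augmented objective in motion — the result is flagged
`converged=False` but the demixing is typically long settled (the descent
on the separation cost itself has plateaued).

All solvers draw their initial demixing matrices from one shared
initializer (unit-norm standard-normal rows); subject k's initialization
depends only on (seed, k), so runs are comparable across algorithms and
ar-cEBM's per-subject results are independent of batch composition.

## Synthetic cohorts

The generator emulates the study conditions the solvers face: K subjects,
N components of which the first M are tied to references, V voxels.

* **Marginals**: each SCV is a correlated K-variate Gaussian multiplied by
  a shared per-voxel random scale with `g² ~ Exp(1)` — a Gaussian scale
  mixture with Laplacian-like tails (excess kurtosis 3), emulating sparse
  fMRI spatial maps while preserving the Pearson correlation of the
  underlying Gaussian exactly.  All components, free ones included, get
  this law: a pair of exactly Gaussian free components would be
  unseparable by any single-subject ICA, making subject-wise evaluation
  ill-posed rather than merely hard.
* **SCV dependence**: compound-symmetric per SCV, with the per-SCV level
  spread multiplicatively (±20%, mean-preserving) around the configured
  `scv_corr`.  Two Gaussian SCVs with *identical* covariance profiles are
  not identifiable for IVA-G (the cost is invariant under a joint rotation
  of the pair), so the spread is what makes the ground truth recoverable
  at all; it also mimics the heterogeneous consistency of real networks.
* **Mixings**: standard-normal N×N matrices, resampled above condition
  number 1e3.
* **References**: reference n is `c·t̂ + √(1−c²)·ê` with `t̂` the unit-norm
  centered subject-mean of source n and `ê` orthonormalized noise, so the
  similarity to the mean source equals `ref_corr` exactly.
* **Group effect**: an optional additive Hann-window bump (5% of voxels,
  deterministic position per component) on selected source maps of
  group-2 subjects before mixing, producing localized spatial group
  differences.

What passing tests on these cohorts does **not** show: robustness to
observation noise (the mixture is noiseless), hemodynamic or smoothing
structure, site/scanner effects, or realistic V (thousands here vs tens of
thousands of voxels in real data).  The cohorts probe the estimation
machinery, not fMRI preprocessing.

Default study sizes used by the test suite and the acceptance script —
K=10, N=8, V=5000, M=6, `scv_corr` 0.5, `ref_corr` 0.9 for single-run
quality; K=5, N=6, V=2000, M=4 with R=5 repeats for reproducibility — are
chosen as the smallest cohorts on which the three methods' behavior
(separation below ISI 0.05, the reproducibility ordering) is stable.

## Evaluation stack

* **ISI / joint-ISI**: the inter-symbol-interference score of a global
  matrix `G = W A`, zero iff `|G|` is a scaled permutation; the joint
  version applies it to the mean absolute global matrix over subjects.
* **cross-joint-ISI**: reproducibility across R repeated runs.  Run i's
  estimated mixing `inv(W_i_k)` plays the role of ground truth for run j:
  `P_ij_k = W_j_k · inv(W_i_k)`.  (The opposite product order is a
  similarity transform of the permutation, not a permutation, and scores
  catastrophically even for equivalent runs.)  The *partial* variant
  applies the ISI to the leading M×M block — the constrained components.
* **FNC**: temporal FNC is the Pearson matrix of detrended/despiked time
  courses (linear least-squares detrend; clipping at 3 normal-consistent
  MADs from a 7-point running median); spatial FNC correlates z-scored
  maps thresholded at |z| = 2.  Correlations are clipped at 1 − 1e-12
  before the Fisher z-transform so statistics stay finite.
* **Modularity**: FNC matrices are stripped of negatives and
  self-connections, binarized at link densities 20–70% (largest positive
  entries, ties by index), and Newman's Q with the 2m normalization is
  maximized by seeded multi-level (Louvain) search with random-start
  single-node-move refinement; an exhaustive enumerator doubles as the
  test oracle for graphs of ≤ 10 nodes (0 mismatches over 250 random
  graphs).
* **Statistics**: pooled-variance two-sample t, paired t and one-sample t
  (scipy), the two-sample KS statistic, and Benjamini–Hochberg FDR at
  q = 0.05 (statsmodels).  Under a simulated null the two-sample stack
  rejects at 5.0% per entry (1000 reps), confirming calibration.
* **t-maps**: voxel-wise one-sample t across subjects; zero-variance
  voxels get t = 0 (all-zero) or ±1e6 (identical non-zero).  The summary
  statistic is the mean |t| over voxels whose z-scored |t| exceeds each
  threshold in 0.5..3.0.

## Numerical choices and edge cases

* Convergence is measured sign-invariantly (`min(‖w−w'‖, ‖w+w'‖)` on
  unit-norm rows) because BSS rows are defined only up to sign.
* Constrained components are returned first, in reference order, signs
  flipped so the centered inner product with the matching reference is
  nonnegative; free components follow, ordered by descending mean map
  variance.  Time courses are back-reconstructed as columns of
  `basis_k · inv(W_k)`.
* Degenerate inputs raise: constant vectors in `similarity` or
  `entropy_bound`, rank-deficient row-deleted matrices in the decoupling,
  edgeless graphs in modularity, zero rows/columns in ISI.
* Reports are JSON with sorted keys, seeds and a config hash, and no
  timestamps; reruns with the same master seed are bitwise identical.
  Per-run seeds derive from the master seed through a seeded generator.

## Known limitations

* The optimizer is first-order; on large K, N a Newton-type IVA-G update
  would converge in far fewer sweeps.
* ar-cEBM's subject loop is serial here; the algorithm is embarrassingly
  parallel over subjects by construction.
* The EBM bound tables are built for the four stock measuring functions;
  swapping in others is supported by `MeasuringFunctionSet` but no
  adaptive augmentation of the set is attempted.
* Temporal FNC on synthetic cohorts uses T = N reconstructed time points
  (the generator has no explicit time dimension), so temporal statistics
  there are mechanical checks, not physiological ones.
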