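# Methods

## Connectome eigenmodes

A structural connectome SC (symmetric, nonnegative, zero diagonal) is
eigendecomposed as SC = V Λˢ Vᵀ with eigenvalues sorted descending. The
eigenvalue of a mode equals its Rayleigh quotient VⱼᵀSC Vⱼ, a graph-Fourier
notion of spatial frequency: positive values mean connected nodes carry
values of the same sign (the pattern follows the anatomy), negative values
mean connected nodes oppose (the pattern deviates from it). Because the
diagonal is zero the spectrum sums to zero, so every connectome has both
aligned and deviated modes. SC is decomposed raw — no normalization or
Laplacian transform — so eigenvalues keep their alignment interpretation.

A functional connectome FC (symmetric; a Pearson-correlation matrix when it
comes from data) is decomposed the same way, except eigenvalues below zero
are treated as estimation noise and clipped to 0; the stored mode set then
reconstructs the clipped FC exactly. `n_positive` counts eigenvalues above
1e−10, and values in (−1e−10, 0) are treated as zero. Eigenvector sign is
fixed by making each column's largest-magnitude element positive, and ties
in the descending sort are broken by original index; both choices only
stabilize outputs across runs — every downstream quantity uses squares or
outer products and is sign-invariant. With degenerate eigenvalues individual
eigenvectors are arbitrary within the eigenspace, so comparisons should be
made between subspace projectors; the tests do this.

Projection weights mᵢⱼ = VⱼᵀUᵢ express functional mode i in the structural
basis; since V is a complete orthonormal basis and ‖Uᵢ‖ = 1, each row of
squared weights sums to exactly 1, making mᵢⱼ² a fractional contribution.

Alignment can also be resolved by connection length: existing edges are
sorted by Euclidean distance and split into bins of equal edge count (±1;
10 bins by default), and each bin accumulates SC(n₁,n₂)v(n₁)v(n₂) over its
unordered edges, so twice the bin total recovers the full Rayleigh quotient.

## The K-mode projection mapping and its benchmarks

The mapping predicts FC ≈ Σ_{i≤K} λᵢᶠ(Σⱼ mᵢⱼVⱼ)(Σⱼ mᵢⱼVⱼ)ᵀ with closed-form
parameters. K = 1 keeps only the dominant functional mode (the default
throughout); K = n_positive reproduces the clipped FC exactly, and both the
cumulative eigenvalue coverage and the reconstruction residual are monotone
in K. Fits are evaluated in-sample by default; passing a second empirical
FC (`evaluate_against`) gives out-of-sample evaluation in the two-session
style (parameters from session 1, R against session 2). Predicted matrices
are mode-built, so their diagonal is near but not exactly 1; all accuracy
metrics exclude the diagonal, whole-brain R over the strictly upper
triangle and regional R over matrix rows with the diagonal entry removed.

Benchmarks:

* **Diagonal eigenmode fit** (Tewarie-style): FC ≈ ΣⱼaⱼVⱼVⱼᵀ. By
  orthonormality the Frobenius least-squares solution is aⱼ = VⱼᵀFC Vⱼ.
  Identical structural inputs and parameter count to the K = 1 projection
  mapping, but no cross-mode terms — the comparison isolates the value of
  non-diagonal interactions.
* **Spectral rotation fit** (Becker-style): FC ≈ R(Σ_{l≤L} aₗSCˡ)Rᵀ with
  R = UVᵀ. In the rotated eigen-domain this reduces to fitting a degree-L
  polynomial p with p(λⱼˢ) ≈ λⱼᶠ by least squares, mathematically equivalent
  to the matrix-domain Frobenius fit and numerically stabler; Vandermonde
  columns are scaled by the spectral radius to limit conditioning, and
  rank-deficient designs (duplicate eigenvalues saturating degrees) fall
  back to the pseudoinverse with a warning. The coefficients aₗ are
  unconstrained. The fit connects to the projection mapping through
  VᵀRV = Mᵀ, which the tests verify exactly.
* **Communication model**: OLS of the empirical FC upper triangle on an
  intercept plus Q = 20 SC-derived predictors. Predictor upper triangles
  are z-scored before regression — their raw scales differ by orders of
  magnitude, raw coefficients would be meaningless, and R is invariant to
  the rescaling. Directed measures (mean first passage time, search
  information) are symmetrized by averaging with their transpose since FC
  is symmetric. Collinear stacks are solved by pseudoinverse with a warning.
* **Reference mapping**: predicts every subject's FC by the cohort mean —
  the no-structure baseline any subject-specific mapping must beat to claim
  it captures individual information.

Constant predictions (e.g. an identity-matrix FC under the diagonal fit, or
a cancelling two-subject mean) make Pearson R undefined; the standalone
metric raises a typed error, while fit results flag the value as NaN with a
warning rather than failing the whole pipeline.

## Communication predictors

Defaults follow the standard grids: flow-graph times t ∈ {1, 2.5, 5, 10}
and weight-to-cost exponents γ ∈ {0.25, 0.5, 1, 2} in SC^(−γ), giving
4 + 1 + 1 + 1 + 4 + 4 + 4 + 1 = 20 predictors.

* **Flow graph**: continuous-time random walk with random-walk Laplacian
  L = I − D⁻¹SC; the matrix diag(s)·exp(−tL)/Σs holds joint source–target
  probabilities (total mass 1 for every t, stationary outer product as
  t → ∞). This is the canonical flow-graph construction; it is isolated in
  one function so an alternative Laplacian is a one-line change.
* **Mean first passage time**: discrete-time walk, fundamental matrix
  Z = (I − P + 1πᵀ)⁻¹, MFPT(i→j) = (Zⱼⱼ − Zᵢⱼ)/πⱼ. Columns are z-scored
  over off-diagonal entries only (including the structural zeros on the
  diagonal would bias the moments), then symmetrized.
* **Communicability**: exp(SC) via `scipy.linalg.expm`.
* **Matching index**: Jaccard similarity of binarized neighbor sets
  excluding the pair itself; empty unions give 0. A weighted variant is out
  of scope.
* **Shortest paths / search information / path transitivity**: γ-cost
  Dijkstra distances; paths are reconstructed backwards choosing the
  lowest-index predecessor among ties, so degenerate shortest paths resolve
  deterministically across platforms (a warning notes the degeneracy).
  Search information is −log₂ of the probability that a walker with
  weight-proportional transitions follows the shortest path, averaged over
  the two directions. Path transitivity averages the matching index over
  ordered node pairs of the path.
* **Euclidean distance** between node centroids (mm).

All predictors require a connected graph; disconnected inputs raise.

## Functional diversity and structure–function liberality

Functional diversity over the M positive functional eigenvalues (shares
pᵢ = λᵢ/Σλ) is FD = 1 − N_M⁻¹ Σ|pᵢ − 1/M| with N_M = 2(M − 1)/M, which maps
a one-mode spectrum to 0 and a uniform spectrum to 1 and is Schur-concave
in the shares. M counts eigenvalues above 1e−10 after clipping by default;
a fixed-M option supports sensitivity analysis. M = 1 is defined as FD = 0.

The leading functional mode splits into a structure-aligned component
(first L_A structural modes) and structure-deviated component (last L_D),
with L_A = L_D = 10 by default and a built-in sensitivity sweep over
{5, 10, 15, 20}². Component intensity is reported as the Euclidean norm,
and "energy" in the liberality ratio means the squared norm. The ratio is
oriented deviated/aligned — so a decline in liberality corresponds to
shrinking anatomy-deviated energy with preserved aligned energy — and the
reciprocal orientation is exposed as an option since the convention is not
fixed in the literature. The aligned and deviated energies plus the middle
band sum to 1 (the unit-row property of the projection weights), which the
tests use as a bookkeeping invariant. Zero aligned energy flags the ratio
as infinite rather than erroring.

Age associations are plain Pearson correlations with two-sided p from the
t-distribution (n − 2 df); shares λᵢᶠ/Σλᶠ rather than raw eigenvalues are
correlated with age by default so subjects of different spectrum scales are
comparable (raw values remain available). Nonlinear age models and
covariate adjustment are out of scope.

## Spin tests and supporting statistics

Node centroids are projected to a unit sphere per hemisphere (centered on
the hemisphere centroid, radially normalized); each permutation draws one
uniform random rotation from SO(3), applies it mirrored across hemispheres,
and maps original to rotated positions by greedy nearest-neighbor without
replacement, guaranteeing a bijection. This is a documented stand-in for
surface-based spins — volumetric parcellations have no native sphere — with
the same exchangeability contract; vertex-level spins and variogram
surrogates are out of scope. p-values use the (1 + k)/(1 + N) convention so
they never reach zero, with N = 10,000 by default (tests run at 500 for
speed). Map similarity uses |Pearson R| because eigenmode maps are defined
up to sign. Network enrichment compares each network's mean statistic to
the spin-null distribution two-sidedly and BH-corrects across networks
(`statsmodels` implementation). Under an independent-maps null the spin p
distribution is approximately uniform; the suite checks a Kolmogorov–
Smirnov distance below 0.15 over 200 simulated experiments.

## Synthetic data

The generator is mode-first: it plants the quantities the statistics
measure, so ground truth is exact rather than estimated.

* `gen_sc`: nodes uniform in a 140 mm-diameter ball split into hemispheres
  at the sagittal plane; a fixed edge count (density × pairs, default
  density 0.35) sampled without replacement with probability ∝
  exp(−d/45 mm); weights exp(−d/45 mm) with lognormal jitter (σ = 0.3);
  resampled until connected. This emulates the distance dependence of
  tractography connectomes — short connections denser and stronger — not
  their topology in detail.
* `gen_fc_planted`: leading mode U₁ = Σⱼ wⱼVⱼ with chosen unit-norm weights
  w; remaining modes complete an orthonormal basis; eigenvalues are planted
  shares scaled to trace n (default: geometric decay with ratio 0.65 over
  12 modes, leading share ≈ 0.36, matching the empirical dominance of a few
  modes). The result is a covariance-like FC whose diagonal is near but not
  exactly 1: forcing a unit diagonal would perturb the eigenvectors and
  destroy exact recovery, which is the generator's purpose. An optional
  time-series route samples Gaussian signals with the planted covariance
  and returns a true Pearson-correlation FC for exercising the strict path.
  Symmetric Gaussian entry noise (sd `noise_sd`) is added before clipping.
* `gen_cohort`: shared SC topology with per-subject lognormal weight jitter
  (σ = 0.1); ages uniform (default 4–85 years). The leading eigenvalue
  share moves linearly with age (default +0.001/yr around a base of 0.40)
  and liberality moves linearly (default −0.006/yr around 0.8), planted
  exactly by holding the aligned-band energy fixed (0.35) and moving the
  deviated-band energy. At zero noise the recovered age correlations are
  ±1 by construction; FC noise degrades them monotonically.

Passing tests on these cohorts shows the estimators recover what they claim
to measure under the model's own assumptions; it does not certify behavior
under tractography biases, parcellation effects, motion artifacts, or
non-Gaussian BOLD noise, none of which the generator emulates.

## Numerical choices and problem sizes

Symmetry tolerance for inputs is 1e−6 (readers reject beyond it);
orthonormality, reconstruction, and unit-row identities hold to 1e−8;
eigenvalue clipping tolerance is 1e−10. The test suite and the acceptance
script run at desk scale — 8–60 nodes, 10–60 subjects, 3 seeds, 500
permutations — sizes chosen so every check completes in seconds to a few
minutes on one CPU while remaining large enough to exercise the asymptotic
identities.

## Known limitations

No imaging I/O (matrices enter as delimited text); no biophysical
simulation behind the synthetic FC; the spin projection is a volumetric
stand-in rather than a surface spin; the communication stack omits
navigation, diffusion efficiency, and weighted matching variants; the
Riemannian benchmark family is not implemented.
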