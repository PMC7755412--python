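# Methods

## Model

Given m samples x₁…x_m ∈ ℝᵈ, t-SNE defines conditional input-space
affinities around each sample with a Gaussian kernel,

    p_{j|i} ∝ exp(−‖xᵢ−xⱼ‖² / 2σᵢ²),   p_{i|i} = 0,  Σⱼ p_{j|i} = 1,

symmetrized into the joint p_ij = (p_{j|i} + p_{i|j}) / (2m), and
output-space affinities with a Student-t kernel with one degree of freedom,

    q_ij = w_ij / Σ_{k≠l} w_kl,   w_ij = (1 + ‖yᵢ−yⱼ‖²)⁻¹,

and minimizes C = KL(P‖Q) = Σ_{ij} p_ij log(p_ij/q_ij) over the embedding
Y ∈ ℝ^{m×e} (e = 2 by default). The exact gradient is

    ∂C/∂yᵢ = 4 Σⱼ (p_ij − q_ij) w_ij (yᵢ − yⱼ).

All entropies and divergences are in natural log (nats) and perplexity is
defined as exp(H); a base-2 convention would rescale σ–π curves but not the
embedding. Distances are Euclidean. Everything is dense O(m²): the point of
the package is the exact objective, not an approximation of it, so the
practical ceiling is m of a few tens of thousands on one core.

## Bandwidth calibration

Each sample's entropy H(σᵢ) = −Σⱼ p_{j|i} log p_{j|i} is continuous and
non-decreasing in σᵢ, rising from 0 (unique nearest neighbor takes all mass)
to log(m−1) (uniform). `bandwidth_for_perplexity` brackets the target
exp(H) = π by doubling/halving σ from the row's median distance and bisects
in log σ to relative tolerance 1e-5 (≤ 64 steps). The vectorized variant
runs the same scheme for all rows simultaneously. Numerical guards: the
scaled exponents are shifted by their row minimum before exponentiation, and
probabilities are floored at 1e-300 inside logarithms. Duplicate samples
(all-zero distance rows) get a uniform conditional row at σ = 1 with a
warning — no finite bandwidth can meet a perplexity target there.

## Quasi-Newton optimizer

`lbfgs_minimize` implements limited-memory BFGS with the standard two-loop
recursion over the last `rank` (s, y) = (step, gradient-change) pairs
(default rank 11; rank 5 is a reasonable economy setting). Pairs with
sᵀy ≤ 1e-12·‖s‖‖y‖ are discarded to keep the approximation positive
definite; the initial Hessian scaling is γ = sᵀy/yᵀy from the newest
retained pair. The line search is backtracking Armijo (c₁ = 1e-4, factor ½,
≤ 30 backtracks) starting from the Newton-natural step 1; accepted steps
therefore never increase the objective. On line-search failure the iteration
falls back to a steepest-descent step with a warning. Stopping: gradient
max-norm ≤ 1e-7, or relative objective decrease ≤ 1e-9 over a 10-iteration
window, or `max_iter` (default 1000).

With *empty* curvature history the direction is −g scaled to unit max-norm
rather than raw −g. This matters: from the SD-1e-4 random initialization the
t-SNE gradient has max-norm ~1e-7, so raw −g steps change coordinates by
~1e-7 and the objective by less than float64 resolution — the optimizer
would sit numerically frozen in the flat saddle around the origin (the same
regime classical gradient descent escapes only via its large fixed learning
rate). Scaling the first trial step to O(1) in coordinate space lets the
line search find real decrease immediately, after which curvature pairs set
the scale. On quadratics this still reproduces textbook behavior (a sphere
is solved in ≤ 3 iterations; with full-rank history an n-D quadratic
terminates in about n iterations).

The momentum baseline `momentum_gd_minimize` is the classical heavy-ball
update v ← βv − αg, y ← y + v with α = 200, β = 0.8 (the traditional t-SNE
settings); it stops early with a `diverged` flag if the objective rises for
50 consecutive iterations. Both optimizers record identical per-iteration
traces (objective, gradient max-norm, step length, cumulative function
evaluations) so runs can be compared level-by-level:
`iterations_for_equal_progress` pairs each iteration of one trace with the
first iteration of the other reaching an objective at least as low
(restricted to the overlapping objective range, using running minima), and
`fit_convergence_exponent` fits the log–log slope of those pairs. On the
built-in m = 1000 benchmark at perplexity 100 the quasi-Newton run reaches
every common objective level in no more iterations than momentum GD, the
post-warm-up slope is ≈ 2.7 (superlinear; the optimizer needs ~rank
iterations of curvature collection before that regime), and the iteration
ratio grows to ≳ 30× in the last decade of the common range. Heavy-ball GD
is genuinely competitive through the easy early expansion at this problem
size, so the order-of-magnitude advantage is a tail property here, not a
uniform one.

Early exaggeration (×12 for 250 iterations) is available behind a flag but
off by default — the quasi-Newton runs do not need it to separate clusters
on the built-in benchmarks.

## Automatic perplexity selection

`entropy_curves` traces every sample's H over a log-spaced σ grid (default
64 points spanning [1e-3, 1e3] × the median pairwise distance) and
differentiates it to the sensitivity sᵢ(σ) = dHᵢ/d log σ ≥ 0. Plateaus of
the staircase (sᵢ ≈ 0) are bandwidth ranges where the neighbor structure is
insensitive; transitions mark the data's scales.

`locate_insensitive_optimum` minimizes the aggregate sensitivity
S(π) = medianᵢ |sᵢ(σᵢ(π))| over a user-given perplexity range, where σᵢ(π)
inverts each sample's (monotone) entropy curve by grid interpolation. The
median aggregate is robust to outlier samples. The search is a 17-point
log-spaced scan followed by golden-section refinement to 1e-2 absolute in
log π (≤ 50 evaluations). Degenerate cases are deterministic: an exactly
flat aggregate returns the geometric midpoint of the range; if a second
local minimum competes with the global one (within 10% of the scanned
spread) the best scan point is returned with a warning — the range is
supposed to bracket a single optimum.

`tune_per_sample` then refines each sample independently within the factor
window [w_lo, w_hi] around the pivot (default [½, 2]) by a vectorized
per-sample golden section on the sample's own |sᵢ|; the winning targets are
solved exactly by bisection, and σᵢ*, H(Pᵢ*), πᵢ* = exp(H(Pᵢ*)) are
recorded. Pivot location runs first, per-sample refinement second. On data
with uniform group sizes the πᵢ* distribution is tight around one value; on
mixtures of different cluster sizes it is multimodal, with each sample
attracted to its own cluster's scale — note a factor-[½, 2] window can only
express scale ratios up to 4, so hierarchies with larger scale gaps (such as
the built-in benchmark, whose plateaus sit at π ≈ 39 and ≈ 199) resolve one
scale per run, selected by the range given to the pivot search.

## Quality of a mapping

H(Pᵢ*) is the nats needed to encode sample i's neighbor relations in the
source space; the cross-entropy H(Pᵢ*) + KL(Pᵢ*‖Q̂ᵢ) is the cost of
encoding them through the embedding model, where Q̂ᵢ is the row-normalized
Student-t kernel around sample i (a proper conditional distribution,
comparable to Pᵢ* per sample; divergences are computed per sample and then
summed). The loss statistic

    q = 1 − Σᵢ H(Pᵢ*) / (Σᵢ H(Pᵢ*) + Σᵢ KL(Pᵢ*‖Q̂ᵢ))

is 0 for a lossless mapping and → 1 as divergence → ∞, and is independent
of the log base (it is a ratio). Because "q" alone is ambiguous between
loss and retention, the API reports both `q_lost` = q and
`retained_fraction` = 1 − q under those explicit names.

`jaccard_retention` is the model-free cross-check: the mean over samples of
|NNₙ(X,i) ∩ NNₙ(Y,i)| / |NNₙ(X,i) ∪ NNₙ(Y,i)|. Neighbor ranking ties are
broken by sample index (stable sort), so the metric is deterministic.
`retention_vs_information_curve` sweeps inherent dimension and perplexity on
the embedded-Gaussian generator and reports both metrics per configuration;
retained information and neighbor retention decrease together as the
inherent dimension grows past the embedding dimension.

## Synthetic benchmarks

* `hierarchical_gaussian`: cluster centers ~ N(0, sd_cluster²·I) in 10-D
  (default 5), subcluster centers around them ~ N(0, sd_sub²·I) (default 5
  each), samples around those ~ N(0, sd_sample²·I), balanced membership
  (default 1000 = 5×5×40). Defaults sd 1 / 0.25 / 0.01. The center
  distributions and the balanced assignment are the minimal reading of
  "k clusters of SD s"; the per-sample SD is noise about subcluster centers,
  not a third center level.
* `embedded_lowdim_gaussian`: m×k standard-normal scores pushed through a
  seeded random orthonormal k-frame into 10-D, so the data have exactly k
  nonzero singular values (inherent dimension exactly k; default m = 5000,
  scaled to 1000 in the routine benchmark sweeps to keep run times in
  seconds-to-minutes on one core).

Both generators are pure functions of their spec including the seed:
reruns are bit-identical. What they do *not* emulate: measurement noise
floors, zero inflation, heavy-tailed marker distributions, batch effects, or
unbalanced population sizes of real cytometry/scRNA-seq data — passing
benchmarks here demonstrates correctness of the machinery and the claimed
convergence/selection/quality properties, not performance on any particular
real dataset.

## Numerical and design choices

* Entropy base: natural log everywhere; perplexity ≡ exp(H).
* Self-affinity p_{i|i} = 0; joint symmetrization (p_{j|i}+p_{i|j})/(2m).
* Output kernel degrees of freedom fixed at 1; q_ij floored at 1e-300 in
  logs so coincident points cannot produce −∞.
* Embedding initialization: isotropic Gaussian, SD 1e-4, seeded; optional
  PCA initialization (deterministic full SVD, rescaled to the same SD).
* One seed drives all randomness of a run; identical seeds give
  bit-identical traces, embeddings and reports (outputs are written with
  fixed numeric formatting, and logs carry the timing information instead of
  the report files).
* The perplexity range for pivot search is the user's statement of the
  desired level of detail; the benchmark scripts use (10, 150) for the
  subcluster scale and (120, 600) for the cluster scale of the built-in
  hierarchy, chosen from the generator's group sizes (40 and 200).
* Scan grids must span the scales of interest: the staircase tests use
  σ ∈ [5e-4, 5e3] with 96 points because the benchmark's per-sample noise
  scale sits below the default median-distance-derived lower bound.

## Known limitations

* O(m²) memory and time per gradient evaluation; no sparse/approximate
  affinities by design.
* The sectioning assumes the given perplexity range brackets one sensitivity
  minimum; ranges spanning several scales produce a warning and a
  best-grid-point answer rather than a multi-optimum enumeration.
* The convergence-order advantage over momentum GD is measured on the exact
  objective at benchmark sizes; wall-clock comparisons are hardware-bound
  and deliberately out of scope.
* Non-Gaussian input kernels, alternative output kernels, and
  heteroscedastic output adaptation are not implemented.
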