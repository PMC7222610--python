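# Methods

This note documents the models and algorithms implemented in `fastrbf`,
the default parameter choices and why they were made, what the synthetic
phantom does and does not emulate, and the numerical decisions that
affect results.

## Feature pipeline

Each case consists of four co-registered 2-D Dixon channels (fat, water,
in-phase, opposed-phase). Every channel is correlated with the fixed
normalised 3×3 kernel (0.1 everywhere, 0.2 at the center) before
sampling; borders use replicate-edge padding so no artificial zeros
enter tissue intensities and the output keeps the input shape.
Internally the correlation uses the integer-scaled kernel divided by 10
once, which keeps constant regions bit-exact. A pixel at (row, col)
contributes the feature vector

    (fat_s, water_s, ip_s, op_s, x, y),  x = col·col_mm, y = row·row_mm,

i.e. coordinates are physical millimetres (0-based pixel indices times
spacing). Coordinates are attached per pixel on the regular grid; no
coarser super-pixel pooling is performed. All six columns are z-scored
with training-set statistics stored in the model — unscaled millimetre
coordinates would otherwise dominate the Gaussian hidden units.

## Hidden layer (fuzzy C-means)

Centers and widths of the M Gaussian hidden units come from fuzzy
C-means on the standardized training features: cᵢ is the
membership-weighted mean, δᵢ = Σⱼ uⱼᵢ‖xⱼ − cᵢ‖² / Σⱼ uⱼᵢ the
membership-weighted mean squared radius. δᵢ therefore carries squared
units and enters the activation as exp(−‖x − cᵢ‖²/δᵢ), un-squared.
Widths are floored at 10⁻⁸ times the mean pairwise squared distance of
the data to guard singleton clusters.

**Fuzzifier.** The default is m = 1.5, not the textbook default 2.0.
On standardized pixel features, whose class structure is a few strongly
overlapping blobs, FCM with m = 2 reliably converges to the degenerate
uniform fixed point: all memberships tend to 1/M and every center
collapses onto the grand mean, leaving duplicated centers and an
effectively one-dimensional hidden layer. m = 1.5 keeps memberships
crisp enough that the centers spread over the data while retaining soft
assignments. Initial centers are M distinct sample rows drawn by the
run's seed; iteration stops when the largest membership change falls
below 10⁻⁵ or after 300 sweeps. M defaults to 10; M, λ, μ and σ² are
the natural axes for a grid search when tuning on new data.

## Output-weight training

Targets are encoded y ∈ {+1, −1} so the ε-insensitive regression
program doubles as a binary classifier trainer. The dual is a QP over
the probability simplex in 2n variables (see README for the matrix
form). Both solvers reduce to simplex-constrained QPs, which are solved
by a primal active-set method (`simplex_qp.py`) to a bound-multiplier
KKT tolerance of 10⁻⁸ (10⁻¹⁰ for the inner core-set subproblems); the
solver contract is the tolerance, not the algorithm.

* `solve_dual_direct` materialises the dense 2n×2n augmented kernel and
  solves exactly. It is guarded to n ≤ 5000, past which a dense solve
  is no longer sensible; it serves as the correctness oracle for the
  core-set path and as the "traditional" full-data trainer.
* `solve_coreset` recasts the dual as a center-constrained minimum
  enclosing ball. η is the smallest shift making all augmentation
  distances Δ non-negative (min Δ = 0); the dual argmax is invariant to
  η. The core set is initialised with the farthest pair among 100
  seeded random candidates; each iteration re-solves the restricted
  dual warm-started from the previous weights, then searches for a
  violator — a point with squared distance beyond (1+ε_tol)²R² — first
  in a random probe of `sample_size` points (default 59; 0 forces
  exhaustive scans), and, if the probe is clean, in one exhaustive scan
  that doubles as the termination certificate. Kernel entries are
  generated lazily from the hidden representations; the 2n×2n matrix is
  never materialised. ε_tol defaults to 10⁻⁶; `max_iter` defaults to
  min(5000, 10·√(1/ε_tol)). Radius radicands down to −10⁻¹⁰ are clamped
  to zero; anything more negative raises.

The recovered quantities follow the simplex structure exactly:
ξᵢ = αᵢμn, ξᵢ* = αᵢ*μn, hence Σ(ξᵢ + ξᵢ*)/n = μ identically, and the
prediction function is f(x) = λΣ(αᵢ − αᵢ*)k(x̃ᵢ, x̃) with k the *base*
Gaussian kernel — the (μn/λ)I term is a training-only regularizer on
the diagonal blocks and never applies to test points. f > 0 (including
exactly 0) predicts the positive tissue. An implied ε (the smallest
tube half-width consistent with the recovered solution) is reported in
the direct solver's diagnostics; it is derived, not optimised over.

**The balance factor μ and core-set size.** μ is the mean per-sample
slack; it enters the dual only through the diagonal term c = μn/λ. That
term gives every augmented point a private orthogonal component of
squared length ~c, so a *certified* (1+ε_tol)-cover must keep
max βⱼ ≲ ε_tol·R²/c, i.e. a core set of at least ~c/(ε_tol·R²) points.
Any size-independent μ therefore makes the certified core set grow
toward min(2n, ~1/ε_tol) — incompatible with compact core sets at
ε_tol = 10⁻⁶. `TrainConfig` consequently parameterises μ by the
size-invariant ratio `dual_ridge` = μn/λ (default 10⁻³), from which
μ = dual_ridge·λ/n is derived; an explicit μ can still be passed. All
slack identities hold for the derived μ. The base-kernel bandwidth σ²
defaults to the median heuristic (median pairwise squared distance of
hidden representations on a seeded subsample of ≤ 2000 rows), and
λ defaults to 10.

## One-vs-one classification

Three binary classifiers are trained on label-restricted subsets:
liver–kidney, liver–other, kidney–other (the first label of each pair
is the positive class). Each pairwise winner casts one vote and the
most-voted class wins. With three classifiers the only possible tie is
the cyclic 1-1-1 pattern; it is broken by the largest sum of absolute
decision values over the two classifiers involving each class, and a
residual tie falls back to the fixed priority liver > kidney > other.
The traditional-RBF baseline shares the FCM hidden layer and fits its
output weights by ridge-regularized least squares — the fixed point of
gradient descent on the squared output error (ridge 10⁻⁸ for
conditioning).

## Synthetic phantom

`generate_phantom` rasterizes one large liver ellipse and two small
kidney ellipses on an "other tissue" background of a 128×128 image
(pixel spacing 1.5 mm); each channel is a tissue-dependent mean plus
i.i.d. Gaussian noise (default σ = 10). The frozen channel means give
every tissue pair a clear contrast on the fat and water channels and
near-overlap on in-phase/opposed-phase; they were calibrated once —
after fixing the fuzzifier — so that the default benchmark's ten-seed
mean test accuracy lands in the mid-0.9 range (0.955 measured, minimum
0.940) rather than at a trivial 1.0, and were not revisited.
`default_benchmark` pools enough geometry-jittered cases to hold the
requested training rows plus a fixed 16,896-pixel disjoint hold-out
(20% of the pool when fewer rows remain), sampling uniformly without
replacement; all draws flow from one generator stream per operation.

What the phantom does *not* emulate: partial-volume effects beyond the
smoothing halo, bias fields, anatomical texture, registration error
between channels, and inter-subject intensity variation. Passing tests
therefore demonstrate the solver and pipeline mechanics and the
qualitative accuracy/scaling regime, not clinical performance.

**Boundary halo.** The 3×3 smoothing mixes tissue intensities within
one pixel of an organ boundary, so even a noiseless phantom has a thin
band of intrinsically ambiguous pixels. Noiseless phantoms are
classified perfectly on interior pixels (3×3 neighbourhood entirely one
tissue); overall noiseless accuracy is ≈ 0.99, not 1.0, by
construction.

## Problem sizes used in the checks

The test suite and acceptance script run entirely on generated data:
solver-equivalence checks use 20 random binary problems with n up to
200 (exhaustive violator scans); the scaling check compares mean
pairwise core-set sizes at 2,000 vs 20,000 training pixels and trains
one 30,000+-sample pairwise classifier where the dense solver's guard
refuses; the accuracy-regime check trains on 4,000 pixels per seed for
ten seeds; the full-scale run in `scripts/acceptance.py` uses the
59,904-pixel benchmark. These sizes were chosen to make every result
reproducible in minutes on a single CPU while spanning the regimes the
method is about.

## Known limitations

* The decision function carries no bias term; with heavily overlapping
  classes and a vanishing dual ridge the expansion can nearly cancel,
  making signs sensitive near the boundary. The shipped defaults avoid
  that regime; extreme class imbalance may still warrant a larger
  `dual_ridge`.
* The certified-cover requirement ties `dual_ridge` and ε_tol together
  (see above); raising `dual_ridge` beyond ~10⁻² at ε_tol = 10⁻⁶ makes
  core sets grow into the hundreds.
* FCM is a local method: different seeds give different hidden layers.
  All training is deterministic given the seed.
* Only three tissue classes and 2-D slices are supported; channels are
  assumed co-registered, as in Dixon acquisitions.
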