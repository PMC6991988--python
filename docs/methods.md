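# Methods

## The model

`adashape` finds *archetypal shapes* in an ensemble of 3D landmark
configurations.  A specimen is a k × 3 matrix **X** of landmark
coordinates in mm; its *shape* is the equivalence class of **X** under
translation, rotation and positive scaling.  The analysis has two layers:

1. **Shape-space geometry.**  Translation is removed with the
   (k−1) × k Helmert sub-matrix H (orthonormal rows summing to zero) and
   scale by dividing by the centroid size S(X) = ‖HX‖, giving the
   pre-shape Y = HX/‖HX‖, a point on the unit sphere in R^{3(k−1)}.
   Rotation is quotiented out by optimal SO(3) alignment (SVD-based, with
   the reflection branch excluded by sign-flipping the smallest singular
   vector — a left foot is not a right foot).  The full Procrustes
   distance between two shapes is

       d_F = √(1 − (λ₁ + λ₂ ± λ₃)²),

   the λ's being the singular values of Y₁ᵀY₂, the smallest negated when
   det(Y₁ᵀY₂) < 0.  The full Procrustes (Fréchet) mean is estimated by
   iterative align–average–renormalize (generalized Procrustes analysis),
   and every pre-shape is mapped to Kent partial tangent coordinates at
   the mean pole S:

       v = (I − vec(S)vec(S)ᵀ) vec(YΓ̂),

   a vector orthogonal to vec(S) with ‖v‖ = sin ρ, ρ the Procrustes angle
   to the pole.  The exponential map
   Y_v = vec⁻¹(√(1 − vᵀv)·vec(S) + v) and the reconstruction X = HᵀY
   take tangent vectors back to configurations.

2. **Archetypoid analysis (ADA).**  On the n × 3(k−1) tangent matrix the
   mixed-integer least-squares problem

       min Σᵢ ‖vᵢ − Σⱼ αᵢⱼ uⱼ‖²,   Σⱼ αᵢⱼ = 1, αᵢⱼ ≥ 0,
       uⱼ ∈ {v₁, …, v_n} distinct

   selects p actual specimens (archetypoids) whose convex hull best
   approximates the data, and expresses every specimen as a mixture of
   them.  Because archetypoids are cases, mapping them back to
   configuration space is a lookup.  Archetype analysis (AA), where the
   extreme profiles are convex mixtures of cases rather than cases, is
   implemented as well — both because it is the natural baseline and
   because the ADA search uses it for initialization.

Tangent coordinates enter ADA at full dimension, unreduced and
unstandardized: the coordinates are commensurate (all in pre-shape units)
and archetypes are not in general recoverable from principal-component
subspaces, so no PCA pre-reduction is applied.

## The optimizer

The inner problem — project a point onto the simplex spanned by p
archetypes — is a simplex-constrained least squares.  The public
`fit_alphas` uses the classical penalty device (append a row of ones
weighted by M = 200 × data scale, solve by NNLS, renormalize exactly).
The combinatorial outer search uses an exact solver on the Gram matrix:
the simplex minimizer lies in the relative interior of some face of the
simplex, where it equals that face's equality-constrained KKT solution,
so enumerating the 2^p − 1 faces (batched and vectorized over all n
points) yields the exact per-point projection.  Face enumeration is used
for p ≤ 10; beyond that a Cholesky-reduced penalty NNLS takes over.

The mixed-integer search is BUILD + SWAP, the same pattern as PAM
k-medoids:

- **BUILD**: candidate index sets from a fitted AA model — the nearest
  case to each archetype, the case with maximal α per archetype, the case
  with maximal β per archetype — plus `n_restarts` seeded random sets.
- **SWAP**: steepest descent; each pass evaluates all p·(n−p) single
  exchanges (a seeded random subsample of 2000 when n > 2000) and accepts
  the best improving one, until none improves.

All randomness flows from one explicit seed; ties break toward the lowest
index; translation of the data changes neither indices nor alphas (convex
combinations commute with translation — covered by a test).

The RSS screeplot (`rss_profile`) uses a nested-restart protocol: the
best set at p, greedily padded with the case whose addition most lowers
RSS, seeds the search at the next p.  This makes the profile provably
non-increasing, which is what an elbow reading presumes.  The largest
second difference of the profile is reported as an elbow *diagnostic*
only; the choice of p is left to the analyst, because on real data the
elbow is rarely sharp and domain constraints (how many design cases a
practitioner can use) matter as much as the curve.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| GPA tolerance | 1e−9 | pole movement (Frobenius) to declare convergence |
| GPA max_iter | 100 | beyond this a non-convergence warning is issued |
| AA tol / max_iter | 1e−6 / 200 | relative RSS improvement per outer iteration |
| `n_restarts` | 10 | random ADA starting sets on top of the AA-derived ones |
| penalty M | 200 × data scale | simplex sum-to-one weight in `fit_alphas` |
| swap sample limit | 2000 | exchanges per pass above n = 2000 |
| `outlier_quantile` | off | optional pre-filter on d_F to the mean |

GPA starts at the first specimen's pre-shape, so a fit is deterministic
given the input order; an order-invariance test checks that permuting the
ensemble moves the mean by less than 1e−6 in d_F for concentrated data.

## The synthetic generator

`make_archetypal_shapes` builds K template shapes by deforming one common
landmark cloud drawn uniformly in a 240 × 90 × 60 mm foot box along
distinct smooth modes (elongation, widening, arch-height change; taper,
toe lift and seeded random smooth quadratic fields for K > 3).
`simulate_ensemble` then mixes the templates' tangent coordinates at
their Procrustes mean with Dirichlet(1.0) weights (the first K specimens
are the pure templates, so the planted archetypoids exist as cases),
exp-maps back, rescales to mm, applies a random similarity transform
(uniform SO(3) rotation, log-uniform scale in [0.8, 1.25], uniform
translation) and adds iid Gaussian landmark noise (default 0.5 mm,
roughly scanner-landmark accuracy).

Mixing happens in tangent space so the generator matches the model class
the estimator assumes; parameter recovery then tests the estimator, not
model misspecification.  A `mixing="raw"` mode (convex mixtures of raw
template coordinates) is available to probe robustness to that choice.

**Deformation amplitude.**  The template deformation amplitude defaults
to 4.0 (a simulation-calibrated value, fixed once): it is the smallest
setting at which, under the default conditions (K = 3, k = 60, n = 100,
0.5 mm noise, random similarity transforms), the pipeline recovers the
planted pure-case indices in ≥ 90% of seeds.  The reason smaller
amplitudes fail is identifiability, not optimization: with Dirichlet(1.0)
weights some mixtures land very close to a corner of the simplex, and
when template separation is small relative to the landmark noise such a
specimen can genuinely become more extreme than the planted pure case —
the optimizer then correctly prefers it.  A consequence worth stating
plainly: the default synthetic shape variation (pairwise template d_F of
roughly 0.6–0.8) is far larger than real anthropometric variation within
a human population.  Passing recovery tests therefore shows the estimator
works when archetypes are unambiguous; it does not show that archetypes
of real feet are identifiable at 0.5 mm noise, where the data-driven
answer may legitimately place an archetypoid at a different extreme
specimen.

Other features of real scan data the generator does not emulate:
template-registration error correlated along the foot surface (noise here
is iid per landmark), measurement-protocol artifacts, and any
size–shape correlation (allometry) — scale is drawn independently of the
mixture weights.

## Numerical choices

- d_F is evaluated as the aligned residual ‖Y₂ − cos ρ · Y₁Γ̂‖ rather than
  √(1 − cos²ρ): identical algebraically, but immune to the catastrophic
  cancellation that makes the closed form return ~1e−8 for identical
  shapes.
- Helmert products use O(k) cumulative-sum recurrences; the explicit
  (k−1) × k matrix (≈250 MB at k = 5626) is never materialized inside the
  pipeline.
- Face-enumeration QP adds a 1e−12-scaled jitter to each face's Gram
  block so duplicate data points cannot make a KKT system singular;
  alphas are clipped at 0 and renormalized exactly before the final RSS
  is recomputed from them.
- The AA alternating loop rolls back and stops if an iteration would
  raise the RSS (the constrained beta step is a projection, not an exact
  minimizer), which keeps the reported trace non-increasing.
- Degenerate inputs: coincident landmarks raise a degenerate-configuration
  error before any pre-shape is formed; an all-identical data matrix
  returns RSS 0 with a warning and indices 1..p.

## Known limitations

- The tangent approximation degrades as shapes disperse (‖v‖ → 1); the
  pipeline reports max ‖vᵢ‖ as a diagnostic but does not refuse dispersed
  data — the synthetic defaults themselves run at max ‖v‖ ≈ 0.5.
- The SWAP search is a local descent; global optimality is verified
  exhaustively only on small instances (and holds there in ≥ 95% of
  cases by test).
- Percentile profiles depend on the rank-percentile convention
  (round(100·(r − 0.5)/n), mean rank on ties, half-up rounding); other
  software using a different convention will differ by a point or two
  near the extremes.
- `stability_check` reports subsample agreement rather than guaranteeing
  it: near-corner specimens can swap under landmark resampling.
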