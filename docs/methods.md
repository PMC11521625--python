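# Methods

This note documents the statistical machinery, the numerical choices, and
what the synthetic data do and do not establish.

## Superimposition

Generalized Procrustes analysis centres every configuration at the origin,
scales it to unit centroid size, and then alternates two steps until the
consensus stabilizes: rotate each configuration to the current consensus
(Kabsch solution — SVD of the cross-covariance with the sign of the last
singular vector flipped when needed, so rotations are always proper), and
recompute the consensus as the plain coordinate-wise mean. The consensus is
deliberately *not* renormalized inside the loop: alignment targets and the
reported consensus are then the same object, and the summed squared
deviation from the consensus is provably non-increasing across iterations
(each rotation is optimal for the current target; updating the target to
the mean can only reduce the sum). Convergence is declared when the squared
change in the consensus falls below `tol` (default 1e-8, default cap 100
iterations; non-convergence is a logged warning, not an error).

Centroid size is recorded before scaling; all models use its natural log
(LCS). Configurations with coincident points (CS = 0) or collinear points
(3D rotation unidentifiable) are hard errors. Semilandmarks are carried as
a flag in the scheme but treated as fixed points: no sliding criterion is
applied anywhere, and none is emulated by the generators.

Local superimposition runs an independent full GPA on each bone's landmark
subset starting from the raw coordinates, with its own CS/LCS per specimen.
Bones with fewer than three points are skipped with a warning. Locally
aligned bones are never re-assembled into a composite configuration — the
relative scaling such a re-assembly would require is underdetermined — so
whole-configuration analyses always use the global GPA.

Species means average aligned coordinates arithmetically; the species CS is
the arithmetic mean of specimen CS and the species LCS is ln(mean CS), not
the mean of ln CS — the size a species carries into the evolutionary model
is its average size, transformed once.

## Linear models and RRPP

All models are an intercept plus ordered term blocks (continuous LCS,
drop-first group dummies, their products). Sums of squares come from model
comparison on rank-revealing orthonormal bases (SVD, tolerance
`max(n,p)·eps·σ₁`): sequential (each term against the terms before it) for
the single-covariate and stacked ANCOVA fits, Type II (each main effect
against all other mains; the interaction against the full main-effects
model) for the PGLS fits. Negative sums of squares arising from floating
point cancellation are floored at zero.

Residual randomization (RRPP): for each term, the residuals of *its*
reduced model are permuted across observations and added back to the
reduced-model fitted values; the term's F is recomputed with the full
model's residual mean square in the denominator. One permutation stream is
drawn per ANOVA and shared by all terms. Conventions, fixed and documented
rather than configurable:

* p = (1 + #{F\* ≥ F_obs}) / (1 + iters): the observed arrangement always
  counts, ties count toward exceedance, so p ∈ [1/(iters+1), 1].
* Z = (ln F_obs − mean ln F) / sd(ln F) over the permutation distribution
  *including* the observed value (sample sd, ddof = 1). F values are
  floored at 1e-300 before the log. For angle statistics Z uses the raw
  angles, not logs — angles are bounded and roughly symmetric under the
  null.
* Default 999 permutations plus the observed arrangement. Exhaustive
  enumeration is supported by passing explicit permutation index vectors.
* A reduced model with (numerically) zero residual variance makes the
  permutation distribution degenerate; p is then reported at its minimum
  with a warning. A saturated full model (zero residual MS) reports
  F = ∞, which the counting convention handles without special cases.

Permutation refits are batched (chunks capped near 2·10⁷ elements) so the
199-permutation × 1000-dataset calibration runs in seconds on one core.

## Phylogenetic GLS and Pagel's λ

The Brownian covariance of a rooted tree has Cᵢⱼ = root-to-MRCA shared path
length, computed as (tᵢ + tⱼ − dᵢⱼ)/2 from root-to-tip depths and patristic
distances — valid for non-ultrametric trees. Pagel's λ multiplies the
off-diagonal entries; the equivalent branch-length operation multiplies
internal branches by λ and extends each pendant edge by (1 − λ) times its
parent's depth, preserving tip depths exactly (the two routes agree to
1e-10 in tests). λ is restricted to [0, 1].

Because jointly maximizing λ with the regression parameters of a
3k-dimensional shape model is impractical, the package uses a two-stage
estimate: (i) fit shape ~ LCS by OLS at the species level; (ii) PCA-reduce
the residuals — default rule keeps components with eigenvalue above
1e-12 × the largest, capped at s − 1 (a "95% of variance" rule is available
and recorded in the output); (iii) profile the Gaussian likelihood of the
retained columns, treated as independent with a single common λ and a
per-column σ² profiled out and the mean estimated by GLS, over λ ∈ [0, 1]
with bounded scalar minimization (xatol 1e-6); both endpoints are also
evaluated and the reported optimum is never worse than either; (iv) rescale
the covariance once by λ̂ and fit the GLS model. λ is *not* re-estimated
jointly with the final fit, and each analysis dataset (whole configuration,
each bone) gets its own λ̂.

GLS whitening uses the inverse symmetric square root from an
eigendecomposition; eigenvalues at or below 1e-10 trigger a ridge of 1e-10
with a warning. The whitened intercept column replaces the constant, so the
same ANOVA machinery serves OLS and GLS; RRPP permutes the whitened
residuals. GLS coefficients are reported with fitted values formed in the
original space (X β̂_GLS), so fitted + residuals always reconstructs the
input data.

## Trajectory comparison

The observed angle is taken between the per-group slope vectors of the
stacked interaction model `data ~ LCS * group`; the null permutes residuals
of the common-slope model `data ~ LCS + group` and recomputes the angle.
Reported: r, angle (degrees), the 95th percentile of the null angle
distribution (observed included), Z without log transform, and both
p-values — divergence (angle ≥ observed) and similarity (angle ≤ observed).
Because the same distribution serves both, p_greater + p_similar ≥
1 + 1/(iters+1).

Both the angle test and the combined ANCOVA operate on the models'
*reconstructed data* — fitted values plus residuals, each in its own
model's coordinate frame. Predicted values alone are exactly linear in LCS
within each group, so the stacked interaction model would fit them with
identically zero residual and the F statistic would be undefined; carrying
the residuals keeps the residual term meaningful (its df is n_A + n_B − 4
for the two-group model) and gives the permutation null the spread of the
actual estimation noise. The combined ANCOVA is always fitted by plain OLS
with sequential SS, whatever estimator produced the inputs. PredLine scores
for the combined plot are PC1 of the combined model's fitted values,
sign-aligned to correlate positively with LCS.

Comparing slope vectors across two separately superimposed datasets is only
meaningful when the datasets share a coordinate convention. The pipeline
relies on specimens being digitized in a consistent anatomical orientation
(as μCT-derived landmarks are); the synthetic study writes both datasets
with a shared base configuration and no nuisance rotation for exactly this
reason.

## Synthetic data: what it emulates

The generators reproduce the structure the analysis assumes, at the study's
sample sizes, with defaults chosen once:

* **Ontogenetic series** — n = 54 specimens; LCS uniform on [0, 3]
  (the ~19-fold total-length range of the series corresponds to ≈3 natural-
  log units); shape = slope·LCS + iid Gaussian noise per coordinate; slope
  norm 0.05 and noise sd 0.009, set by the variance identity
  E[R²] ≈ ‖β‖²Σ(x−x̄)² / (‖β‖²Σ(x−x̄)² + n·3k·σ²) to put the
  whole-configuration allometric R² near 0.42 (replicate means land in
  0.43–0.48). Shape dimension k = 10 points for statistical work.
* **Species dataset** — a Yule tree scaled to unit depth (pendant edges
  extended by one exponential waiting time so no two tips coincide);
  n = 219 tips named deterministically, the first 57 (sorted) labelled
  "parrotfish" and the remaining 162 "wrasse"; species shape =
  slope·LCS + residual with residual columns drawn from N(0, σ²C(λ)),
  σ = 0.02; the evolutionary slope is constructed at an *exact* planted
  angle to the ontogenetic slope in the plane spanned by that slope and a
  random orthogonal complement.
* **Adult sample** — 259 specimens over the 219 species (83 parrotfish,
  176 wrasse), extras assigned round-robin within each group, for
  exercising species-mean aggregation at the study's sample structure.
* **Landmark fixtures** — a base configuration plus per-specimen similarity
  transforms and optional shape noise; at k = 200 the scheme reproduces the
  full schema (10 skeletal units, 83 fixed + 117 semilandmarks).

Every generator is a pure function of its seed (byte-identical reruns).

What passing tests on these data show: the estimators recover what they are
pointed at — GPA consensus, OLS/PGLS slopes, λ at both bounds, planted
trajectory angles — and the permutation tests are calibrated (type-I error
at α = 0.05 inside the binomial 99% CI over 1000 null datasets). What they
do not show: behaviour under digitizing error structure, sliding-
semilandmark covariance, non-isotropic residuals across coordinates,
measurement units, or model misspecification (e.g. curvilinear allometry) —
real μCT data have all of these and the synthetic data none.

## Known limitations

* No sliding semilandmarks, missing-landmark estimation, or bilateral
  symmetry handling.
* Designs are limited to LCS, one two-or-more-level group factor, and their
  interaction.
* λ is a single common value across retained residual components; per-
  component λ or other tree transformations (κ, δ, OU) are out of scope.
* The tables round to 3 decimals to match the conventional presentation;
  machine-precision values live in the sidecar score/data files.
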