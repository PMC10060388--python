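# Methods

## Superimposition

Configurations are aligned by partial generalized Procrustes analysis: each
is centered and scaled to unit centroid size, then iteratively rotated onto
the running consensus, which is recomputed each round as the re-normalized
mean of the aligned shapes. With all shapes at unit size, the unit-size
consensus minimizing the summed squared distances *is* the normalized mean,
so the recorded objective trace is monotone non-increasing by construction.
Convergence is declared when the root-sum-square consensus change falls
below 1e-8 (default), with a 100-iteration cap that sets a warning flag
rather than raising.

Reflections are never allowed in the rotation step (determinant forced +1):
faces have a left/right identity, and a reflected alignment would destroy
asymmetry signal.

GPA fixes shapes only up to one joint rotation of the whole solution. The
gauge is pinned by rotating the converged solution so the consensus'
principal axes lie on the coordinate axes (major axis on y, faces upright),
with the residual 180° ambiguity resolved by requiring a non-negative sum of
third coordinate moments. This makes the fit invariant — to numerical
tolerance — under arbitrary similarity transforms of any input and under
specimen reordering, which the test suite asserts at 1e-6.

### Sliding semilandmarks

Semilandmarks slide along the chord between their flanking landmarks *of the
current specimen* (not the consensus) — the standard formulation; the
alternative is a one-line change. Two criteria are provided:

- `bending_energy` (default, the tpsRelw behaviour): per specimen, the
  vector of slide distances λ solves the linear system minimizing
  vₓᵀBvₓ + v_yᵀBv_y of the residual to the consensus, where B is the
  bending-energy matrix of the consensus. A singular system triggers a
  logged per-specimen fallback to tangent projection.
- `procrustes_distance`: each semilandmark's residual is orthogonally
  projected onto its tangent (closed form, never increases the distance).

Each slide pass is followed by a full GPA re-fit; five outer cycles (or
consensus change < tol). Non-semilandmark points never move.

## Thin-plate spline and bending energy

The TPS kernel is U(r) = r² log r² with affine block [1, x, y]; the
bending-energy matrix is the upper-left k×k block of the inverted bordered
system, symmetrized. It annihilates affine displacement fields exactly and
is validated in the tests against a quadrature oracle: the quadratic form
equals ∫(f²ₓₓ + 2f²ₓᵧ + f²ᵧᵧ)/16π for the interpolating spline (16π is the
constant for this kernel convention; with U = r² log r it would be 8π).
Deformation grids use scipy's thin-plate-spline RBF interpolator, which is
exact at landmarks and exactly affine for affine shape changes.

## Relative warps

With α = 0 (default) relative warps are an ordinary PCA of the
tangent-projected coordinates — consistent with treating the relative-warp
analysis as a PCA. The tangent projection is the orthogonal projection
removing each aligned row's component along the consensus direction; at
convergence the projected rows are mean-centered to within the GPA
tolerance, so "consensus-centered" and "mean-centered" coincide. For α ≠ 0
the rows are re-expressed with principal-warp weights λ^(−α/2) (affine
subspace unweighted) before the decomposition, so α = 1 emphasizes
large-scale variation; eigenvectors then live in the weighted coordinates
and shape reconstruction is only meaningful at α = 0.

Eigenvalues below 1e-12 × the largest are reported trivial; on generic data
the non-trivial count is min(n − 1, 2k − 4), the four lost dimensions being
the similarity degrees of freedom removed by GPA plus the tangent
projection. PC signs are fixed so that infant mean scores are ≥ adult mean
scores when age labels are available (making "A < I" directions
reproducible), else so the largest-magnitude loading is positive.

## Classification

Four models: LDA, linear SVM at cost 1, and linear/RBF SVMs tuned by
exhaustive search over integer powers 2⁻¹⁰…2¹⁰ (21 values per
hyperparameter; the conventional reading of the grid range), maximizing mean
stratified fourfold cross-validated accuracy with ties broken toward smaller
cost then smaller gamma. Scikit-learn provides the estimators and fold
splitter; everything around them (grid, metrics, selection) is explicit so
the contracts are testable.

Reported accuracy/AUC are cross-validated, pooled over held-out folds —
training metrics for a tuned RBF SVM trivially approach 1.0 and are emitted
separately, labeled. Features are z-scored per column with the scaler fit on
training folds only (raw PC scores have wildly different variances, which
would break a shared gamma grid); toggleable. AUC uses the rank-sum
(Mann–Whitney) formulation over pooled out-of-fold decision scores, ties at
half credit, positive class "infant". Model selection maximizes accuracy,
then AUC, then prefers the simpler model. Tuning is non-nested by default
(tune, then evaluate with the same fold structure).

## Permutation inference

p = (1 + #{null ≥ observed}) / (B + 1) (the add-one estimator; p can never
be exactly 0, and at B = 1000 resolves values like p = 0.01 cleanly). By default a
tuned classifier is *re-tuned inside every permutation* — freezing the
observed hyperparameters would leak label information into the null and be
anti-conservative; `fast_perm=True` freezes them for speed and is what the
acceptance script and the heavier simulations use, with B scaled to the
occasion (999 in the script, 49–199 in calibration tests) so the suite runs
in minutes on one CPU. Per-species rows reuse the PC scores of the pooled
decomposition rather than re-decomposing per species. Raw p-values are
reported with significance bands (<.005, <.01, <.05, <.10); a
Benjamini–Hochberg column is added for transparency but not used for the
bands.

## Reliability

ICC(A,1) — two-way random effects, single measure, absolute agreement — per
landmark and axis across two sessions, computed from the two-way ANOVA mean
squares. Absolute agreement is the right form for coordinate
reproducibility (a systematic session offset should count against
agreement); the consistency form ICC(C,1) is available. Cells with no
between-specimen variance are undefined and reported as missing with a
warning. The implementation is validated against pingouin as an independent
oracle and against the closed-form expectation σ²ₛ/(σ²ₛ + σ²ₑ/2) for
one-session jitter.

## Synthetic data generator

The generator emulates what the analysis assumes about real data:

- a bilaterally symmetric 97-point template (brow 17, eyes 2×10, pupils 2,
  nose edges 2×8, nasion/nose-tip/nostrils/philtrum 5, mouth 22, chin 15),
  centered at unit centroid size, with 76 sliders on the outline curves;
- species mean-shape offsets drawn once from a seeded isotropic Gaussian in
  shape space, norm 0.03 — deliberately modest so the dominant variance
  axis is the age effect (as in the empirical data, where the leading PC is
  the age axis), since species realism is not needed to test the inference
  machinery;
- three named infant effect axes — eye enlargement + lowering (magnitude
  0.12), vertical compression with first-order size-preserving widening
  (0.04), and top-heaviness (0.02) — all unit vectors orthogonal to the
  similarity subspace, in unit-centroid-size shape units. The dominant
  magnitude is of the order of real adult–infant mean-shape Procrustes
  distances and makes recovery of the planted axis by PC1 strong but not
  trivial (|r| ≈ 0.9–0.98 across seeds);
- isotropic Gaussian digitization noise, sd 0.01 per coordinate in shape
  units, and nuisance similarity transforms (rotation ±15°, scale 0.8–1.2,
  translation ±0.1) removed by GPA.

What the generator does **not** emulate: structured, low-dimensional
individual variation within species. Real facial variation concentrates in
a few smooth deformation modes, which is why real data can pack >95 % of
variance into 11 PCs; isotropic noise instead spreads variance over all
~190 tangent dimensions, so the synthetic default conditions put ≈ 56 % of
variance in PC1–11. Passing tests therefore demonstrate correctness of the
machinery and calibration of the inference, not that real faces are
low-dimensional. Likewise the planted effects are exactly linear in shape
space, while real ontogenetic change need not be.

## Problem sizes and numerical choices

Simulation-based checks use the study-sized configuration (80 specimens, 97
landmarks) with replicate counts chosen to keep the whole suite within a
few minutes per file on one CPU: 50 replicates for planted-signal recovery
(B = 49 per PC, frozen linear SVM), 200 null datasets for type-I-error
calibration (B = 199, n = 32), 100 replicates for the ICC expectation.
GPA tolerance 1e-8, 100 iterations, 5 slide cycles — far below landmark
noise for these sizes. Ties in the power-of-two grid resolve to the
smallest values; permutation p-values can never be 0; degenerate inputs
(coincident landmarks, collinear TPS references, single-class folds,
zero-variance ICC cells) raise typed errors or warnings rather than
propagating NaNs.

## Known limitations

- 2-D landmarks only; no 3-D sliding, surface semilandmarks, or missing
  -landmark estimation.
- α ≠ 0 relative warps return weighted-space eigenvectors (no back-mapping).
- Per-species inference reuses pooled PC scores by design; species-specific
  decompositions are out of scope.
- The permutation default (re-tuning inside each permutation) is expensive;
  use `fast_perm` for exploratory runs and report which was used.
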