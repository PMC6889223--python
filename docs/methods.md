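# Methods

## Problem

Dense facial shape analysis needs many corresponding (homologous) points
per face, but only a handful of points on a face have an anatomical
definition a human can digitize reliably. This package implements the
multi-point warping approach to that problem: a 500-point *template*
(16 anatomical anchors + 484 surface semi-landmarks) is built once on a
reference face and transferred to every target face by a thin-plate-spline
(TPS) warp driven by the anchors alone; the semi-landmarks are then *slid*
along local tangent structures to minimize the TPS bending energy between
template and target, re-projecting onto the target surface after every
step. The resulting configurations are treated as homologous and feed the
standard geometric-morphometrics chain: generalized Procrustes analysis
(GPA), Procrustes ANOVA for digitization error, PERMANOVA for group
differences, PCA for feature reduction, and multi-class LDA (canonical
variates) for expression classification.

## Thin-plate spline (tps_warp)

A map h : R^3 -> R^3 through M control points decomposes as
h(p) = Psi(p) K + p Gamma in homogeneous coordinates, with radial kernel
psi_w(p) = ||p - s_w|| (the 3D biharmonic kernel). Coefficients solve the
bordered system [[Psi - beta I, S], [S^T, 0]] [K; Gamma] = [T; 0].

Numerical points worth recording:

* **Kernel sign.** ||r|| is conditionally negative definite, so the
  bending-energy quadratic form is the *negated* kernel form:
  E = -trace(K_xyz^T Psi K_xyz) >= 0, zero exactly for affine maps, and
  the smoothing ridge beta enters with a minus sign on Psi (equivalently
  +beta on the negated kernel). With the naive signs, beta would
  *anti*-smooth: residuals and bending energy both grow. The physical
  constant (8 pi) is dropped consistently; only ratios and comparisons of
  energies are ever used.
* `bending_energy_matrix` returns B = -(upper-left block of the inverse
  bordered system); B is PSD with an exactly 4-dimensional affine null
  space, and u^T B u reproduces `bending_energy` for any displacement u
  (both identities are tested).
* beta = 0 (exact interpolation) is the default; the solve is a single
  LU-factorized bordered system, with a warning above condition 1e12.
  Degenerate control sets (M < 5, coplanar, duplicate points) are
  rejected up front.

## Template and sliding (semilandmarks)

* **Template.** Semi-landmarks are seeded by Euclidean farthest-point
  sampling over mesh vertices starting at the pronasale (nose tip — the
  most protrusive, expression-invariant point), then spacing-repaired to a
  minimum pairwise gap (default 1.5 mm). A hexagonal-packing bound turns
  an impossible request into a capacity error before sampling.
* **Transfer.** Anchor-driven TPS (16 anchors, beta = 0) maps the 484
  semi-landmarks to the target; each is then projected to the exact
  nearest point of the target surface. Projection handles the
  vertex/edge/interior triangle cases exactly, breaks ties by lowest
  triangle index, and prunes candidates with a KD-tree bound that
  provably cannot discard the nearest triangle (tested identical to the
  full scan).
* **Sliding.** Six iterations. Each iteration estimates a tangent plane
  per surface semi-landmark (barycentric interpolation of area-weighted
  one-ring vertex normals; curve semi-landmarks get a polyline tangent
  from neighbours in homology order), solves the linear minimization of
  the template bending-energy form over tangent displacements with
  anchors pinned at zero, scales the step by a geometric decay from 100%
  to 5% ([1.0, 0.549, 0.302, 0.166, 0.091, 0.05]), and re-projects onto
  the surface. E_i (before iteration 1) and E_f (after iteration 6) are
  recorded.
* **Monotone-descent guard.** Sliding along tangents is a linear solve
  and always lowers the energy, but re-projection onto a curved surface
  can restore more energy than the step released (observed on noisy,
  full-resolution targets). Each iteration therefore halves its step (up
  to 5 times, then reverts) until the *post-projection* energy does not
  exceed the pre-update energy. This preserves the fixed six-iteration
  schedule while guaranteeing E_f <= E_i.
* The solve adds a 1e-12-relative ridge so it stays a Cholesky
  factorization even when curve tangents leave zero columns; an exact
  QP oracle test bounds the distortion at < 1e-6.

## Procrustes statistics (procrustes_stats)

* GPA is partial-Procrustes: configurations are centered and scaled to
  unit centroid size once, then rotation-only aligned to the iterated
  consensus (tolerance 1e-10, max 100 iterations). This keeps every
  aligned shape at centroid size exactly 1. The final pose is normalized
  to the consensus principal axes with a deterministic sign convention,
  making results invariant to input order and to similarity transforms of
  the inputs (to ~1e-8). Reflections are never used (determinant-corrected
  SVD): anatomical handedness.
* Procrustes ANOVA: balanced nested design expression > individual >
  replicate; sums of squares are squared deviations at each nesting level
  over all 3k coordinates; DF multiply the factor df by the shape-space
  dimension 3k - 7 (3 translations, 3 rotations, 1 scale removed). For
  k = 500, g = 6, n = 18, r = 2 this gives Expression DF 7465 and Error
  DF 26,874. F tests are Goodall-type ratios of adjacent strata.
  Tangent-space projection after GPA is omitted: at the digitization
  noise levels modelled here, aligned deviations are far inside the
  linear regime.
* PERMANOVA: Anderson pseudo-F from squared distances,
  p = (#{F_perm >= F_obs} + 1) / (n_perm + 1), seeded permutations.
  Cross-checked against scikit-bio on fixtures; the null rejection rate
  at alpha = 0.05 calibrates to [0.03, 0.07] over 500 simulations.
* The per-group one-way ANOVA treats the 3k flattened coordinates as
  factor levels (df = 1499 for 500 landmarks), reproducing the field's
  reporting convention for this test.

## PCA and retention (features)

Covariance-matrix PCA via SVD of the centered data (never standardized:
Procrustes-aligned coordinates share a scale). Components carry a
deterministic sign (largest-magnitude loading entry positive). Two
retention rules:

* **Broken stick:** keep the leading run of components whose variance
  proportion is at least b_i = (1/p) sum_{j>=i} 1/j. The comparison is
  `>=` so a lone component (proportion exactly b_1 = 1) is retained.
* **Bartlett:** sequentially test equality of the trailing p - m
  eigenvalues with the chi-square statistic
  (n - m - (2q+1+2/q)/6)(q ln(mean) - sum ln), df (q+2)(q-1)/2; retain
  the first m not rejected at alpha = 0.05.

Broken stick is deliberately conservative (exploratory use); Bartlett is
the default for the classification route.

## LDA classification (classify)

Within- and between-class scatters are the unnormalized sums
Sigma_w = sum_i sum_{x in c_i} (x - m_i)(x - m_i)^T and
Sigma_b = sum_i m_i-count (m_i - m)(m_i - m)^T; discriminants solve the
generalized eigenproblem Sigma_b phi = lambda Sigma_w phi (at most g - 1
non-trivial for g classes). Classification is nearest projected centroid
(equal priors) under Euclidean or cosine distance; projections are
centered at the grand mean, without which cosine distance degenerates in
a one-dimensional two-class discriminant space. Cross-validation offers
leave-one-out and a stratified 70/30 split (seeded); every fold refits
the model. A fold with no within-class variation falls back to a
negligible ridge (1e-8 of the scatter scale) instead of failing.

The pipeline caps retained PCs at 80% of the training fold's within-class
degrees of freedom (n_train - g): Bartlett retention on strongly
structured cohorts would otherwise keep nearly all PCs and make the fold
scatter singular — the very problem the PCA reduction exists to prevent.

## Synthetic faces (synthetic_faces)

Real expression-scan collections are license-restricted, so all testing
runs on a parametric stand-in: a domed height field (~120 x 160 mm) with
a nose bump (the global protrusion maximum, giving the pronasale an
unambiguous ground truth), eye sockets and a mouth hollow; 16
anthropometric anchors at fixed canonical positions snapped to mesh
vertices. Expression classes displace fixed cosine-window regions along
the height axis (mouth for Surprise; cheeks for Happy; mouth+eyes with
distinct sign patterns for Angry/Disgust/Fear; a global low-frequency
droop for Sad) with peak magnitude = `expression_amplitude`; a smooth
random subject field (windowed to the same region, sd =
`subject_variation_sd`) individualizes subjects; digitization replicates
add isotropic Gaussian noise (sd = `digitization_sd`) with optional
surface re-projection. Defaults: 6 classes x 40 subjects, amplitude 3 mm,
subject sd 1 mm, digitization sd 0.1 mm, 2 replicates, ~2000-vertex
meshes, mandatory seed.

What the generator does **not** emulate: texture, occlusion, hair,
eyeball/eyelid geometry, acquisition artifacts (holes, spikes), head-pose
variation beyond what GPA removes, or non-height-field anatomy (ears,
nostril undersides). Passing tests therefore demonstrate correctness of
the algorithms and calibration of the statistics under controlled
conditions, not scanner-grade performance on real faces.

## Problem sizes used by the acceptance script

The error-assessment design is exactly the printed study design
(6 expressions x 3 subjects x 2 digitizations, 500 landmarks,
~2000-vertex meshes). The classification cohort uses 8 subjects per class
(48 faces) with amplitude 6 mm over 0.5 mm subject sd — the separable
(amplitude >> noise) condition — plus 25 label-shuffled re-runs for the
chance-level check. Statistical calibration suites use 20 simulated
cohorts (ANOVA ratio) and 500 null simulations with 199 permutations each
(PERMANOVA type-I error).

## Known limitations

* Sliding minimizes energy against the template, not a sample mean; no
  Procrustes-distance sliding criterion is offered.
* The curve/surface partition of semi-landmarks defaults to all-surface;
  curve support exists but no curve topology builder is provided.
* Unbalanced or crossed Procrustes-ANOVA designs are rejected, not
  approximated.
* The OBJ reader is geometry-only (no materials/texture) and triangles
  only.
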