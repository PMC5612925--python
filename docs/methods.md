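# Methods

This note records the models, conventions and numerical choices behind
`lvtraj`, and what the synthetic tests do and do not establish.

## Shape spaces and Procrustes machinery

A configuration is a `(k, d)` matrix of homologous landmarks (`d = 3` for
cardiac surfaces; the trajectory-shape analysis reuses the same code with
`d` = number of PC axes).  Two quotients are supported: size-and-shape
space (SSS; translation and rotation removed, size retained) and shape
space (SS; additionally scaled to unit centroid size).  All shape vectors
are row-major landmark-by-(x, y, z) flattenings.

**Ordinary Procrustes alignment** uses the SVD solution for the optimal
rotation with the smallest-singular-value sign correction, so only proper
rotations (det = +1) are produced: anatomical homology must not mirror.
Whether the original cardiac analyses permitted reflections is not
documented; excluding them is the standard choice for anatomical data and
we fix it.  In SS mode the target is scaled to the source's centroid size
before rotation (alignment "with scaling at unit size"), rather than given
the full-Procrustes optimal scale; this matches how the transport step
uses OPA, where frames are expressed against a unit-size local template.
Degenerate cross-covariances are tie-broken toward the rotation closest to
the identity (exactly for rank-0, via the minimal geodesic rotation for
rank-1) with a logged warning.

**Generalized Procrustes analysis** iterates rotate-to-reference /
re-average with the objective Σᵢ‖xᵢ − x̄‖².  Because each rotation step
maximizes the alignment of every configuration with the current reference,
the mean norm cannot decrease and the objective trace is monotone
non-increasing; this is asserted by tests.  Convergence: relative
objective change below 1e-10; iteration cap 500.  The high cap matters
only for near-planar trajectory configurations, whose rotation about the
degenerate axis moves through a shallow valley and can need a few hundred
(cheap, batched 3×3 SVD) iterations; typical surface GPAs converge in
under ten.  In SS mode inputs are scaled to unit size once and the
rotation reference is re-normalized each iteration; the reported consensus
is always the arithmetic mean of the aligned shapes.

**PCA** is an SVD of the mean-centered data; `variances` are ddof-1 score
variances.  Component signs follow the convention that each component's
largest-magnitude entry is positive, making score signs reproducible
across BLAS implementations.

## Temporal registration

Raw cycles carry a case-specific frame count and an expert-marked (here:
generator-provided) end-systolic phase.  The piecewise-linear warp maps
0 → 0, ES → 35%, 1 → 1; it is a strictly increasing bijection, so cycle
topology is preserved.  The frame convention is: frame *t* of *n* occupies
phase (t−1)/n, ED = frame 1; the frame *containing* the 35% target under
the floor convention is frame 11 of 30, which is the nominal ES index used
for ED→ES trajectory angles.  Because the warp stretches the post-ES
branch whenever the raw ES phase exceeds 35%, the *sampled* volume minimum
of a registered cycle falls on frame 11 or 12; detection breaks exact ties
toward the earlier frame.

Harmonic representation: each landmark coordinate is a 1-periodic signal.
The default coefficient estimator is least-squares trigonometric
regression at the warped sample phases.  For any signal within the
harmonic budget (≤ 5 harmonics) and ≥ 11 distinct samples this is exact to
machine precision, which the registration contract (band-limited inputs
reproduced to 1e-6) requires.  The classical alternative — interpolate a
periodic cubic spline through the samples, densify to 512 points, project
onto harmonics by DFT — is provided as `fourier_method="spline"`; it is
useful as a smoother but attenuates harmonic h of a T-sample signal by
roughly (2πh/T)⁴/384 (≈0.3% for h = 5, T = 30), so it is not the default.

Cavity volume is the divergence-theorem sum of signed tetrahedra over a
closed triangulation; open basal rims are closed by a fan to the rim
centroid (affine-equivariant, so volume ratios under affine deformations
are exact).  The function is unit-agnostic (mm → mm³); the clinical
indicator layer divides by 1000 to report ml.  Real datasets must supply
the triangulation; the simulator emits its rings×meridians grid
(triangulated quads, apex fan, basal cap).

## Linear-Shift transport

The composition is: whole-sample GPA (used *only* to define the common
template CT = grand mean) → per-case GPAs (local templates LT) → OPA of
each LT onto CT → OPA of each frame onto its CT-aligned LT, subtraction,
addition to CT → common GPA of all transported shapes → joint PCA over all
case-frames (so per-frame scores share axes across the cycle).  Exact
properties asserted by tests: transporting the LT itself yields CT;
‖transported − CT‖ equals ‖frame − LT‖ (addition of a constant); and two
cases built with different templates but an identical deformation field
produce coinciding transported trajectories.  The final GPA re-estimates
its consensus rather than keeping CT fixed (the procedure is ambiguous on
this point); its rotations are near-identity and the maximum rotation
angle plus the consensus drift are logged as diagnostics.

The canonical nulling fixture (`generate_null_transport_pair`) places both
cases in a common orthonormal coordinate frame Q (QR basis of a centered
LV template) with templates `Q·diag(a)`, `Q·diag(b)` and displacements
`Q·diag(c_t)`.  Every cross-covariance the SSS pipeline forms is then
symmetric positive definite, all Procrustes rotations are exactly the
identity, and the transported trajectories coincide to machine precision
by construction.  The guarantee is stated for SSS; SS unit-size
normalization makes it approximate there.

## Trajectory attributes and tests

Trajectory *size* is the centroid size of the 30-point score path;
*orientation* is the four-quadrant angle of the ED→ES score vector,
reported in [0°, 360°) degrees (the convention is ours; sign/unit were
otherwise unspecified).  Angles are compared by plain ANOVA, as in the
original analyses; a circular-variance diagnostic is exposed because a
linear ANOVA on angles is distorted when group distributions straddle the
0/360 wrap, and users should check it.  The ED→ES vector uses the nominal
frame-11 ES (times are homologous after registration); a per-case
minimum-volume ES is available via the `es_index` argument.

Trajectory *shape*: paths are superimposed as configurations of 30
"landmarks" in m dimensions by GPA **with** scaling — size is analyzed
separately, so it must not leak into shape — then PCA'd; the leading 15
scores (clipped to the informative rank, and to the MANOVA's error
degrees of freedom) enter a one-way MANOVA.  Wilks' Λ with Rao's F
approximation is implemented in-package and verified against statsmodels'
MANOVA in the tests.  The ANOVA effect size is the adjusted
R² = 1 − (1−R²)(n−1)/(n−g), which can be negative under the null — the
natural reading of reported negative "R-squared" values in this kind of
table.  Multivariate dispersion differences are tested by the
distance-to-group-centroid permutation F test with p = (1 + #{F* ≥
F})/(n_perm + 1), an exact test under exchangeability.  Per-frame score
ANOVAs report raw p-values plus Benjamini–Hochberg flags; the correction
choice is a reporting decision, stated in the output.

## Classification protocol

1,000 stratified random splits (200 + 200 train / 100 + 100 test per class
at full size; two-thirds / one-third per class for smaller cohorts, with a
warning), linear SVM with C = 1, features z-scored on the training portion
only, AUC from continuous decision values, Control = negative / MI =
positive.  Kernel and C are exposed (`kernel="rbf"` available) but the
linear default keeps the protocol deterministic and matches the use of
PCA-reduced deformation scores.  `null_permutation=True` permutes labels
independently before every split — the exact permutation null of the whole
protocol, used for calibration.  Each report records its seed; identical
seeds reproduce metrics bit for bit.

## Synthetic data: what it emulates, and what it does not

Each case is a pair of nested half-spheroid surfaces (default 9 rings × 12
meridians + apex = 109 landmarks per surface; the pipeline is
size-agnostic and runs identically at 1,089) with an open base.  The
cyclic activation g(φ) = sin²(π·warp(φ; ES→½)) is 0 at ED and peaks at
the case's raw ES phase, drawn from U(0.4, 0.6); raw frame counts are
drawn from 20–35 so registration always does real work.  Contraction
scales radii by 1 − A·g and the long axis by 1 − 0.15·A·g.  Group
conditions: endocardial amplitude A = 0.55 (Control) vs 0.30 (MI); the
epicardial amplitude ratio is 0.45 (Control) vs 0.55 (MI) of the
endocardial one, reflecting that subendocardial infarction impairs
endocardial excursion disproportionately while epicardial motion is
relatively preserved — this is also why endocardial effect sizes exceed
epicardial ones on simulated data.  A sphericity-change coefficient
(Control 0.0 vs MI 0.3, per-case SD 0.15) modulates radial contraction
along the long axis; the per-case jitter encodes heterogeneity of
remodeling, without which a deterministic coefficient would make the
ED→ES angle an unrealistically perfect classifier.  Inter-individual
variation: 7%/6% size/length jitter, 5° orientation and 5 mm position
jitter, amplitude SD 0.05; per-frame rigid jitter (0.5°, 0.5 mm) and
0.5 mm i.i.d. landmark noise.  An optional angular-sector damping mask
models septal akinesia (off by default).

Ground-truth EDV/ESV integrate the noise-free ED and peak-contraction
surfaces over the generator's own mesh, so truth and measurement share
discretization and EF recovery isolates registration/noise error.
`SimulationSpec.with_target_ef` disables the non-affine effects and solves
1 − (1−A)²(1−βA) = EF for the amplitude, making the programmed EF exact
for any closed mesh (affine maps scale volumes by their determinant).

The generator emulates the *statistical structure* the analysis assumes —
homologous landmarks, cyclic smooth motion, group effects on amplitude and
shape-change, nested surfaces, realistic volumes (EDV ≈ 125 ml) — not
myocardial mechanics: wall thickness is uniform, the base stays in its
plane, contraction is a smooth separable field, noise is i.i.d. isotropic,
and there are no segmentation artifacts or isovolumetric-phase volume
noise.  Passing tests therefore validate the machinery and its
calibration, not performance on real cine-MR data; in particular the
near-perfect SVM accuracies on the default contrast reflect the clean
synthetic separation, not expected clinical performance.

## Problem sizes and determinism

Default analysis cohorts are 30 + 30 cases at 109 landmarks per surface;
the test suite uses 4–6 rings × 8–10 meridians and 3–30 cases per group,
and the null-calibration study runs 200 fresh exchangeable cohorts at
4 × 8 landmarks — sizes chosen so the full suite exercises every path at
desk scale.  All pipeline randomness flows from one root seed through
`numpy.random.SeedSequence` children (simulation, dispersion permutations,
SVM splits, in that order); outputs embed the configuration hash and stage
seeds, and rerunning a configuration reproduces every CSV byte for byte.

## Known limitations

- Angle ANOVAs are linear statistics on circular data (see above).
- The Linear Shift is the small-deformation Euclidean approximation of
  parallel transport; it is not a Riemannian (geodesic) transport and is
  not intended for large shape excursions.
- MANOVA requires error degrees of freedom to exceed the score dimension;
  with few cases the trajectory-shape dimension is clipped and reported.
- `cavity_volume` requires a closed, consistently oriented triangulation
  and raises otherwise; no mesh repair is attempted.
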