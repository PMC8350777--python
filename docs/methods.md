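# Methods

## Purpose and scope

`corticosim` studies how reliably vertex-wise surface statistics recover a
known, induced cortical lesion. It deliberately replaces the two components
that dominate the cost and opacity of real validation studies — the MRI data
and the corticometry pipeline — with controllable stand-ins: a geometric
phantom with closed-form ground truth, and reference thickness metrics
simple enough to reason about. The lesion simulator, in contrast, is the
genuine article: a Jacobian-determinant-constrained deformation of the kind
used in deformation-based morphometry, with hard spatial support
guarantees.

## Lesion simulation

### Target determinant and free region

A lesion is parameterised by an ROI (cube, or the ellipsoid inscribed in its
bounding box; the box is anchored by its low corner in world mm and voxels
belong to it when their centre falls in the half-open box) and a volume
contraction ratio `r ∈ (−∞, 1)`. The target determinant is `1 − r` inside
the ROI and `1` outside. Displacement may be nonzero only on the *free
region*: the ROI plus a tolerance ring obtained by 26-connected dilation of
width `pad_mm`. Everywhere else the displacement is identically zero by
construction — locality outside the free region is exact, not approximate.

The ring is necessary and necessarily deforms: a warp that is the identity
on the ring's outer boundary cannot remove volume from the ROI while keeping
`det = 1` throughout the ring (the integral of the determinant over the free
region is fixed). For this reason the solver's data term covers the ROI
only; the ring is shaped by the smoothness penalty alone and absorbs the
compensating expansion. Penalising the ring toward `det = 1` would instead
bias the achieved ROI determinant away from the target.

### Solver

Damped gradient descent on

```
L(u) = Σ_ROI (det(I + ∇u) − D)² + λ Σ_i,j (∂u_i/∂x_j)²
```

Gradients of the determinant use the cofactor identity
`∂det(J)/∂J_ij = cof(J)_ij` with the adjoint of the spacing-aware
central-difference operator; the regulariser contributes `−2λ Δu`. After
each step the displacement is re-clamped to zero outside the free region. A
backtracking line search (initial step `step = 0.1`, doubled on acceptance,
halved on rejection) accepts a step only if the mean absolute ROI
determinant error does not increase and the determinant stays positive
everywhere, so the logged error is non-increasing and the warp remains
diffeomorphic by construction. Defaults: `λ = 0.01`, `tol = 0.01` (mean
absolute ROI determinant error), `max_iter = 500`. Non-convergence warns
and reports the log; a determinant sign flip is a hard error.

For the canonical geometry (10 mm cube, 20% volume contraction, 5 mm pad,
1 mm voxels) the solver reaches the tolerance in well under the iteration
cap and the achieved mean ROI determinant, measured by the independent
finite-difference `jacobian_determinant`, is 0.80–0.81.

### Application convention

`u` is the displacement of the forward warp `φ: x ↦ x + u(x)`, and the
reported Jacobian is `det(I + ∇u)` (central differences, one-sided at
borders, in mm). Resampling goes through the exact numerical inverse,
`out(y) = in(φ⁻¹(y))`, with `φ⁻¹` obtained by fixed-point iteration
`v ← −u(y + v)` (converges in a few iterations for the sub-voxel
displacements produced here). This is the orientation in which a
determinant below one is a volume *loss* of the anatomy: pulling the input
back directly through `φ` would magnify, not shrink, the ROI content.
Because `φ` is the identity outside the free region and maps the free
region onto itself, the inverse is also the identity there and the output
equals the input bit-for-bit outside the free region.

## Phantom

Spherical-shell anatomy: WM ball (default radius 12 mm), GM ribbon of
uniform thickness (default 3 mm, the scale of adult mean cortical
thickness), CSF outside, on a 52³ grid of 1 mm voxels. Class probabilities
ramp linearly over one voxel across each interface; intensities are
probability-weighted class means (30/70/110 for CSF/GM/WM — equal 40-unit
contrasts at both boundaries) plus i.i.d. Gaussian noise. The default noise
SD of 5 propagates through classification and boundary-finding to a
per-vertex scan–rescan thickness noise of roughly 0.15–0.2 mm, the scale at
which within-subject repeat-scan studies operate. The mid-surface is a
subdivision-3 icosphere (642 vertices, ≈3.6 mm² per vertex — comparable
sampling density to ~80k vertices over a whole cortex).

Cohorts: repeated scans share geometry and redraw noise (seed offset `+i`);
between-subject cohorts additionally draw each subject's ribbon thickness
from `Normal(T, 0.5 mm)` truncated positive, matching the between-subject
spread of mean thickness in healthy adult cohorts. All subjects share the
grid and sphere centre so ROI world coordinates transfer across the cohort,
the phantom analogue of stereotaxic registration. Every derived seed is a
documented offset from the single master seed.

In the paired experiment designs the deformed condition is measured on a
fresh-noise re-scan of the same anatomy (seed offset `100000 + i`). A
measured thickness difference always carries noise from both measurements;
re-using one scan for both conditions would make the toy pipeline's paired
differences exactly zero away from the lesion, and the scale-free t
statistic would then amplify numerically tiny interpolation effects into
arbitrarily large values.

What the phantom does *not* model: cortical folding, Rician noise and bias
fields, registration error, surface-extraction error (the mid-surface is
taken from the known geometry, isolating thickness-metric behaviour), or
spatially correlated measurement noise. Consequences: detection here is
noticeably easier than on real data (no anatomy-induced variance
components), and smoothing shrinks noise faster than it would with
correlated errors. Passing tests demonstrate the internal consistency of
the simulation-and-detection machinery, not field performance of any real
pipeline.

## Thickness metrics

Both metrics locate tissue boundaries as 0.5-probability crossings along
the outward vertex normal, marching in quarter-voxel steps with linear
interpolation between samples (search capped at 12 mm by default): WM
probability rising inward marks the WM/GM boundary, CSF probability rising
outward marks the pial boundary. `tlink_ray` reports the distance between
the two crossings; `tnear_avg` reports the symmetric nearest-point distance
between the two boundary point sets, averaged both ways. On a perfect
spherical shell the two coincide. Vertices where a boundary is not found
are flagged as failures and carry NaN — never interpolated. The
inverse-distance soft classifier places the 0.5 crossing slightly off the
true interface on the partial-volume ramp, so noiseless thickness runs
~0.1 mm above truth; this bias is constant and cancels in all paired and
group contrasts.

## Statistics

- **Smoothing**: iterated symmetric diffusion `v ← v + (w/d_max)(A − D)v`
  on the mesh graph (`w = 0.5`), a doubly stochastic step that conserves
  the vertex sum and fixes constants. The iteration count
  `round(σ²/(h̄² w(1 − w/2)))` (mean edge length `h̄`,
  `σ = FWHM/2.355`) matches the variance accumulation of iterated local
  averaging; the constant is a declared convention, validated by the
  impulse-width and variance-reduction tests rather than by an exact
  Gaussian equivalence.
- **CoV**: per-vertex sample SD over mean across scans; zero means are
  flagged undefined.
- **Paired GLM** `1 + condition + subject`: the condition contrast equals
  the paired t-test on per-subject differences (`df = n − 1`), verified
  against a dense least-squares fit of the full design matrix. Two-tailed
  uncorrected p-values. Vertices with (relatively) zero residual variance
  are flagged; t is 0 or signed infinity there.
- **Independent GLM**: pooled-variance two-sample t (`df = n₁ + n₂ − 2`).
- **Thresholding**: Bonferroni over mesh vertices,
  `t* = T⁻¹(1 − α/2N; df)`. Fixed literature thresholds (e.g. 7.5) can be
  supplied explicitly; they are never derived.
- **Detection**: a vertex is significant when `|t| ≥ t*` (two-tailed — the
  conservative choice, since both thinning inside the ROI and
  ring-compensation thickening are real effects). Labels are
  vertex-centre-in-ROI. Sensitivity and specificity follow the standard
  confusion-matrix definitions; scattergrams pair each vertex's signed t
  with its Euclidean distance from the deformation centre; ROC sweeps |t|.

## Experiment designs and problem sizes

The driver sweeps (ROI × contraction × FWHM) cells and writes t-maps,
detection reports, scattergrams, ROC curves and a JSON manifest carrying
every parameter, seed, solver log and output path; identical config and
seed reproduce the outputs byte for byte. Default desk-scale sizes — 20
subjects (paired cohort), 5–21 repeated scans (within-subject), 52³ voxel
grids, 642-vertex meshes — keep a full four-ratio sweep around a minute of
CPU while leaving all effects well resolved; they are configuration, not
limits.

A known behaviour worth stating: at the nominal Bonferroni threshold the
paired design flags a handful of vertices *just outside* the ROI
(specificity ≈0.95 rather than exactly 1). These are not numerical
artefacts: a vertex a millimetre outside the cube measures thickness along
a ray that traverses deformed voxels, and the tolerance ring genuinely
thickens slightly (its determinant must exceed one to absorb the ROI's
volume loss). With the conventional higher fixed threshold of 7.5 these
vertices fall below significance and specificity is exactly 1.

## Limitations

- The ray-cast metric is a stand-in for streamline (Laplacian) thickness;
  no claim is made that it ranks real pipelines.
- Uniform per-voxel target determinants only; no tapered lesion profiles.
- Isotropic contraction only (per-axis ratios are not exposed).
- Bonferroni only; no random-field or FDR correction, no covariates, no
  mixed-effects designs beyond the two implemented contrasts.
- NIfTI-1, ASCII OFF and TSV are the only interchange formats.
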