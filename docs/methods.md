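# Methods

## Scope and model

`osteoseg` builds per-bone 3D mesh templates from MRI-like volumes and
validates them geometrically. The segmentation model is a 2D U-Net applied
slice by slice ("2.5D"): knee MRI stacks are strongly anisotropic (0.4 mm
in-plane, 1 mm between slices), so a 2D network on the finely resolved
plane captures most of the usable context at a fraction of the memory and
compute of a 3D network. One *binary* network is trained per bone;
cartilage labels are discarded during binarisation rather than modelled.

The network is a classic encoder–decoder: `depth` levels of two 3×3
convolutions + ReLU, 2×2 max-pooling between levels, nearest-neighbour
upsampling with skip concatenation on the way back, and a 1×1 convolution
through a logistic sigmoid producing one foreground probability per pixel.
Biases start at zero and weights at He-scaled Gaussians under a fixed seed.
The implementation is a self-contained numpy CNN with explicit
forward/backward passes (unrolled 9-offset 3×3 convolutions); gradients are
verified against central finite differences in float64 in the test suite.
Inputs must be divisible by 2^(depth−1); the volume predictor pads
non-conforming slices with edge replication and crops afterwards, which
also makes the optional tri-axis fusion mode (average of probability
volumes predicted along each grid axis) work on non-cubic grids.

## Geometric validation

Dice is reported as a percentage, with the both-empty case defined as 100 %
(perfect agreement) — empty slices are the norm at the ends of a bone's
extent and must not poison slice-averaged scores.

Surfaces are extracted with marching cubes on the (optionally smoothed)
binary indicator, zero-padded by one voxel so objects touching the grid
border still close, with vertices mapped to millimetres through the
volume's spacing and origin; faces are oriented outward. Smoothing the
indicator with a spacing-aware Gaussian before extraction (default 0.6 mm
in the evaluation paths, ~1 mm in the analytic oracles) suppresses the
voxel staircase, whose raw surface-area overestimate is ≈ 8–15 %; the cost
is a curvature-dependent bias of order σ²·κ, well under 0.1 mm for bone-
scale structures. With σ = 1 mm a digital 20 mm ball reproduces the
analytic sphere area within 0.6 % and volume within 1.3 % on both isotropic
and 1 × 0.4 × 0.4 mm grids.

Surface distances are one-directional by definition: every sample point on
the segmented surface ∂S (mesh vertices by default; face centroids
optionally) contributes its exact minimum Euclidean distance to the
reference surface ∂R. ASD is their mean, RSD the root mean square — RSD is
stated as a *root* mean square and therefore always ≥ ASD; both are
reported. Point-to-triangle minima are computed exactly (clamped-
barycentric closest point) over a candidate set pruned with two KD-trees
(nearest reference vertex distance + largest triangle circumradius bound),
which is conservative; a brute-force all-triangles scan is kept in the test
suite as the oracle. Signs use angle-weighted pseudonormals at the closest
feature (face / edge / vertex), negative inside the reference — on a
non-watertight reference this degenerates to a plain normal side test and
a warning is emitted. A `symmetric=True` option averages the two
directional ASD/RSD values; the default stays one-directional, and the
asymmetry is exercised explicitly in the tests. Cohort statistics are the
mean and *population* variance over cases, with the standard deviation
reported alongside because ± conventions differ between publications.

Registration uses trimmed point-to-plane ICP: centroid initialisation, up
to 2000 source vertices (subsampled under a seed), exact closest points on
the target surface, the worst `trim_fraction` (default 0.1) of
correspondences discarded each iteration, and the linearised 6-DOF update
solved by least squares; iteration stops when the trimmed RMS residual
changes by < 1e-6 relative or the update is numerically zero, with a
best-so-far transform and `converged=False` returned otherwise. Meshes
evaluated on the same voxel grid are already co-registered; ICP is still
run as a sanity stage and must return near-identity there.

## Threshold calibration

The final-layer threshold sweep binarises each probability volume at each
grid value, meshes prediction and reference identically, and records cohort
mean Dice, ASD and RSD per threshold; `select_threshold` returns the
minimal-ASD (or -RSD) row, breaking ties toward 0.5 and then toward the
lower threshold. Cases whose mask empties at some threshold are flagged and
excluded from that row rather than aborting the sweep. Calibration is run
on the validation split only, never the held-out test split. Per-bone
thresholds are supported; a single global value is the default reporting
mode.

## The phantom generator

The generator emulates the features of multi-centre sagittal knee MRI that
drive this pipeline's behaviour: the anisotropic grid (default 64×128×128
voxels at 1 × 0.4 × 0.4 mm), a femur (superellipsoid condyle block +
cylindrical shaft), tibia (plateau + shaft) and patella (small ellipsoid),
thin cartilage shells in the joint gap (present only so the
discard-cartilage step is exercised), a bright cortical rim (intensity 220)
around a darker marrow interior (80) on a darker background (40), rim
thickness 1.2 mm via a spacing-aware distance transform, Gaussian boundary
blur in millimetres (default 0.8 mm), additive Gaussian noise (default
SD 8; the "hard" condition uses 16, leaving only 2.5 SD of
background/marrow contrast), and a per-scanner linear gain drawn from
[0.85, 1.15] in cohorts. Superellipsoids were chosen over anatomical
atlases because their closed-form volumes give analytic oracles for the
meshing and metric code. Everything is deterministic under the spec seed;
cohort generation spawns per-case seeds and jitters anatomy (±2 % position,
0.93–1.05 scale).

What the phantom does *not* model: MRI physics (bias fields beyond linear
gain, Rician noise, sequence-dependent contrast inversions), anatomical
shape variability beyond affine jitter, and realistic cartilage geometry.
Passing tests therefore demonstrate that the pipeline machinery — metrics,
meshing, registration, calibration, training dynamics — is correct on data
with known truth; they do not certify segmentation accuracy on clinical
MRI.

`make_biased_probability` is the calibration oracle: blurring the true
foreground indicator with a Gaussian of σ mm and adding a constant bias b
produces a field whose 0.5-crossing along the boundary normal sits exactly
on the true surface, so the threshold that recovers the truth is 0.5 + b by
construction. A network that systematically under-calls bone is emulated
with b < 0. On curved boundaries the blurred field at the true surface sits
slightly below ½ (a mean-curvature correction of order σ·κ), which shifts
the empirical optimum about one 0.02 grid step below 0.5 + b for the
default femur — visible in the calibration outputs as τ* = 0.40 for
b = −0.08.

## Study conditions and problem sizes

The packaged studies are desk-scale by design:

- **Calibration study**: 3 noise-free phantoms at 64×160×160, blur
  σ = 0.8 mm (two in-plane voxels), bias −0.08, sweep grid 0.36–0.50 in
  steps of 0.02. Under these conditions the analytic boundary shift at
  threshold τ is σ·Φ⁻¹(τ − b), giving ≈ 0.19 mm at τ = 0.5 versus
  ≈ 0.01 mm at the optimum (a >10× reduction), while the predicted Dice
  change, ≈ A·δ/(2V) for a structure with surface area A and volume V,
  stays under two points across the grid for the default femur geometry.
- **Training smoke study**: 8 phantoms at 32×64×64 (noise SD 8), case-level
  70/30 split, depth-3 U-Net with 8 base filters, Adam (lr 1e-3),
  BCE + soft-Dice loss, batch 8, 12 epochs — reaching ≈ 96 % held-out Dice
  in about a minute on one CPU. The library defaults for `NetConfig`
  remain the classic configuration (depth 4, 32 filters, momentum SGD,
  soft Dice, 70 epochs); the compact Adam variant is the pipeline demo's
  choice because plain momentum SGD needs far more epochs than a smoke
  test budget allows at this scale.

## Numerical choices and degenerate inputs

- Min–max normalisation uses one shared min/max across the training cohort
  (test volumes are clipped into [0, 255] with the training statistics); a
  constant cohort is an error.
- Normalised images are stored as floats in [0, 255]; quantising to bytes
  before training would discard boundary gradients irreversibly.
- Label resampling is nearest-neighbour (bicubic would invent non-integer
  labels); morphological opening runs per slice in 2D with a radius-1 disc
  by default, both configurable.
- Soft-Dice loss carries a +1 smoothing term so empty-target slices have a
  finite, empties-preferring gradient; training aborts with a diagnostic on
  a non-finite loss.
- Thresholding uses `p ≥ τ`, making masks exactly nested over τ.
- The "slice axis" is always the first array axis; anatomical plane names
  are metadata. Oblique direction cosines are rejected at load time rather
  than silently re-sliced.
- Tie-break in threshold selection: nearest 0.5, then the lower τ.

## Known limitations

- The numpy U-Net trains networks of desk scale (≈ 10⁵ parameters, 64–128 px
  slices); it is not a substitute for GPU-scale training runs and makes no
  attempt at data augmentation, dropout, or batch normalisation.
- Signed distances on non-watertight references fall back to a local normal
  test and can mis-sign points near holes.
- ICP assumes rough overlap (centroid initialisation); it will find a local
  optimum for grossly misaligned or highly symmetric shapes.
- PLY is the only scalar-carrying mesh format; STL export drops scalars.
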