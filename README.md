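# osteoseg

Knee-bone segmentation from MRI-like volumes to 3D mesh templates, with a
geometric validation suite and threshold calibration.

## The problem

Tracking knee kinematics in bi-planar fluoroscopy requires per-bone 3D
templates (femur, tibia, patella). Templates are classically segmented from
CT, which adds ionising radiation on top of the fluoroscopy itself; building
them from MRI instead removes that dose, but MRI bone boundaries are noisy
and protocol-dependent, and the usual segmentation quality score — the Dice
overlap

    DSC(S, R) = 2|S ∩ R| / (|S| + |R|) × 100%

— can remain high while the extracted *surface* is systematically offset by
a millimetre or more. For template-based pose tracking the quantity that
matters is surface error, measured from the segmented boundary ∂S to the
reference boundary ∂R:

    ASD = (1/Ns) Σᵢ  inf_{y ∈ ∂R} ‖sᵢ − y‖          (average surface distance)
    RSD = sqrt( (1/Ns) Σᵢ inf_{y ∈ ∂R} ‖sᵢ − y‖² )   (RMS surface distance)

reported over a cohort of M cases as mean ± variance (and SD).

`osteoseg` implements the full pipeline around that observation:

- **phantom** — synthetic knee-like MRI volumes (superellipsoid bones with a
  bright cortical rim, anisotropic 1 × 0.4 × 0.4 mm grids, diffuse
  boundaries, per-scanner gain/noise) with exact ground-truth labels, so
  every stage is testable against closed-form oracles;
- **preprocess** — case-level 70/30 splits, per-slice bicubic resampling to
  m × m (nearest-neighbour for labels), cohort-wide min–max normalisation to
  [0, 255], per-bone binarisation (cartilage discarded), per-slice
  morphological opening to remove one-pixel labelling artefacts;
- **model** — a slice-wise ("2.5D") 2D U-Net (numpy implementation with
  explicit backprop: encoder–decoder, skip connections, logistic output),
  momentum-SGD or Adam, soft-Dice/BCE losses, per-epoch Dice monitoring,
  slice-stack prediction with optional tri-axis fusion;
- **geometry** — marching-cubes surface extraction in mm coordinates,
  exact point-to-triangle surface distances with signs from angle-weighted
  pseudonormals (negative inside the reference), trimmed point-to-plane ICP,
  cohort statistics, colour-coded signed-distance meshes (PLY);
- **calibrate** — sweep the network's final-layer probability threshold
  against mesh-based ASD/RSD and select the geometric optimum instead of
  the standard 0.5.

## Worked example

```python
import numpy as np
from osteoseg.phantom import PhantomSpec, generate_cohort, make_biased_probability
from osteoseg.preprocess import binarize_bone
from osteoseg.calibrate import threshold_sweep, select_threshold

# three noise-free phantoms; probability fields that systematically
# under-call the femur by 0.08 — emulating a miscalibrated network
spec = PhantomSpec(grid_shape=(64, 160, 160), noise_sd=0.0, boundary_blur_sigma_mm=0.0)
refs = [binarize_bone(lab, "femur") for _, _, lab in generate_cohort(3, spec, seed=1)]
probs = [make_biased_probability(r, blur_sigma_mm=0.8, bias=-0.08) for r in refs]

sweep = threshold_sweep(probs, refs, taus=np.round(np.arange(0.36, 0.501, 0.02), 10))
tau = select_threshold(sweep, "min_asd")
print(f"tau* = {tau}")
print(f"ASD at 0.5:  {sweep.row(0.5)['mean_asd_mm']:.3f} mm")
print(f"ASD at tau*: {sweep.row(tau)['mean_asd_mm']:.3f} mm")
print(f"Dice range across sweep: "
      f"{sweep.table['mean_dice'].max() - sweep.table['mean_dice'].min():.2f} points")
```

prints

```
tau* = 0.4
ASD at 0.5:  0.186 mm
ASD at tau*: 0.009 mm
Dice range across sweep: 1.85 points
```

The constructed optimum is 0.5 − 0.08 = 0.42; the sweep lands one grid step
away (a small curvature correction from the blurred boundary), cuts the mean
surface error twenty-fold relative to the standard 0.5 cut — while Dice
moves by under two points across the whole sweep. Overlap scores simply do
not see a sub-millimetre boundary offset that surface metrics expose; that
is why the threshold is calibrated geometrically.

The same study end to end, including U-Net training on phantoms, from the
shell:

```
osteoseg run --out runs/demo --seed 7
```

writes `runs/demo/report.json` (per-bone training curve, Dice, ASD ± var,
RSD ± var at τ = 0.5 and τ*) and colour-coded signed-distance meshes under
`runs/demo/meshes/` (blue = inside the reference, red = outside).

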