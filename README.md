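# pcs3d

3-D reconstruction of the kidney pelvicalyceal system (PCS) from
**non-contrast** CT.

Excretory-phase CT urography fills the collecting system with contrast and
makes 3-D models of the renal pelvis and calyces easy to extract with a
global density threshold — but it costs extra radiation and excludes
patients with impaired renal function or contrast allergy. On a native
(non-contrast) scan the urine-filled PCS sits at 0–15 HU inside parenchyma
at 30–45 HU: a contrast too small for global thresholding, but large enough
for a locally calibrated region grower. `pcs3d` implements such a
semi-automatic workflow, aimed at endourological planning (PCNL/RIRS
access), patient counselling, 3-D printing and virtual endoscopy:

1. **Footprints.** The user marks the lumen with 2–3 small circles on axial
   slices. A *smart brush* keeps only circle voxels within
   median ± k·MAD of the circle's HU distribution, so a sloppy circle does
   not contaminate the seed; voxels at stone density (≥ 100 HU) are set
   aside.
2. **Density-adaptive growing.** The mean seed density μ calibrates an
   acceptance band [μ − 20, μ + 15] HU; growth is an 8-connected flood fill
   per axial slice, propagated to neighbouring slices by direct overlap and
   fused into a single 3-D component. The +15 HU ceiling encodes the
   empirical boundary of the PCS on native scans: lumen density increases
   by more than 15 HU at the parenchymal border. Footprints can be added
   incrementally; the result is bit-identical to batch recomputation.
3. **Stone harvesting.** Enclosed high-density components are folded into
   the model geometry but never into the density statistics.
4. **Mesh.** Marching cubes at the 0.5 level of the (lightly presmoothed)
   mask, Taubin λ|μ smoothing (volume-preserving, so areas stay
   comparable), surface-area measurement, STL export and a printability
   report (watertight / manifold / orientation / Euler characteristic).
5. **Virtual endoscopy.** A skeleton centerline graph rooted in the pelvis,
   with resampled camera waypoints for any root→calyx fly-through.

A classical global-threshold baseline (+200 HU default, suitable for bone
and stones; lower for contrast-filled lumen) reconstructs the paired
excretory phase for comparison.

Because patient data cannot ship with the package, a **synthetic phantom
generator** produces paired native/excretory volumes of a branching PCS
(ellipsoidal pelvis, capsule infundibula, calyceal cups, optional stone at
720 ± 210 HU) with per-voxel ground truth, partial-volume blur and CT
noise. A `dilation_factor` sweeps the anatomy from collapsed (sub-voxel
limbs — where native reconstruction legitimately fails) to hydronephrotic.

## Worked example

```python
import numpy as np
import pcs3d as p

spec = p.PhantomSpec(seed=1, dilation_factor=1.5)      # dilated phantom
native, excretory, gt = p.generate_phantom(spec)

fps  = p.auto_footprints(gt, 3)                        # 3 "clicks"
mask = p.segment_native(native, fps)                   # native-phase model
print(mask.seed_stats.mean_hu, mask.n_voxels)          # 8.29 HU, 3869 voxels

gt_lumen = np.isin(gt.labels.labels, (2, 3))
print(p.dice(mask.mask, gt_lumen))                     # 0.944

mesh = p.smooth_mesh(p.extract_surface(mask, native))
print(p.surface_area(mesh))                            # 715.9 mm^2
print(p.printability_report(mesh).watertight)          # True
```

The seed density μ = 8.29 HU sits mid-urine-range; the native model overlaps
ground truth at Dice 0.94 despite 5 HU noise, and its smoothed surface
(715.9 mm²) is within 1% of the contrast-phase model of the same kidney
(709.0 mm² via the +172.5 HU excretory threshold). On a 20-phantom cohort
(`run_cohort`, seed 7) the contrast vs native areas are 684 ± 75 vs
673 ± 70 mm² — a small, statistically non-significant native deficit
(Student's t, p = 0.66), while collapsed phantoms (dilation 1) fail native
reconstruction entirely; both behaviours mirror what is seen clinically.

The same pipeline is scriptable from the shell:

```sh
pcs3d phantom --seed 1 --dilation 1.5 --out-dir work/
pcs3d segment --volume work/native.nii.gz --footprints work/footprints.json --out work/mask.nii.gz
pcs3d mesh --mask work/mask.nii.gz --out work/model.stl --report work/report.json
pcs3d flythrough --mask work/mask.nii.gz --tip 0 --out work/path.json
pcs3d cohort --n 20 --dilation 1.5 --seed 7 --out work/cohort.csv
```

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, what
the phantom does and does not emulate, numerical choices and known
limitations.
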