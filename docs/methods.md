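# Methods

## Segmentation model

The native-phase PCS is modelled as a connected pocket of near-water
density (urine, 0–15 HU) embedded in soft tissue of slightly higher density
(renal parenchyma, 30–45 HU) and surrounded at larger distance by
perinephric fat (≈ −100 HU). The separating contrast is only ~20–40 HU, so
a *locally calibrated* criterion is used instead of a global threshold:

- **Seed calibration.** Every user circle ("footprint") on an axial slice
  is refined by a robust band: circle voxels within median ± k·MAD
  (k = 3 by default) of the circle's non-stone HU values. The median voxel
  always survives, so a footprint that intersects any soft tissue yields a
  non-empty label. Voxels at or above `stone_threshold_hu` (100 HU) are
  *excluded* from the label and recorded separately: stones must shape the
  model but never the density statistics. μ is the plain arithmetic mean of
  HU over the union of labelled voxels, recomputed whenever the footprint
  set changes; no other parameter adapts.
- **Acceptance band.** A voxel may join the region iff
  μ − `delta_low` ≤ HU ≤ μ + `delta_up`, with `delta_up` = 15 HU — the
  empirical density increase that marks the PCS border on native scans —
  and `delta_low` = 20 HU, which admits the full urine range below μ while
  excluding fat. Both are configurable; HU are compared after rounding to
  integers, since CT samples are integral, making results independent of
  float layout.
- **Growth and fusion.** Growth is 8-connected within each axial slice;
  a slice's segmented area seeds its two neighbours by direct overlap,
  iterated to a fixed point. This per-slice-with-overlap scheme equals
  connected-component labelling of the acceptance band under an anisotropic
  structure (full 3×3 in-plane, single voxel across slices), which is how
  it is implemented; tests verify equivalence against a literal queue-based
  flood fill. Seed voxels start the fill even if their own HU falls outside
  the band (they are user-asserted lumen). The fused model is the single
  component containing the footprints; footprints landing in mutually
  disconnected regions raise an error rather than producing a two-kidney
  model. `min_region_voxels` (10) suppresses speckle components in the
  seedless classical mode; a footprint-anchored component is never
  discarded, however small, because the user explicitly marked it.
- **Incremental updates.** `add_footprint` is contracted to be bit-identical
  to recomputation from scratch on the extended footprint set, and is
  implemented exactly that way — growth takes ~15 ms on a 96³ grid, so an
  incremental shortcut would buy nothing and risk divergence.
- **Stone harvesting.** Connected components of stone-density voxels lying
  entirely inside the filled hull of (mask ∪ footprint disks) are added to
  the mask and to a stone sub-mask; any partial-volume shell cavity around
  a harvested stone is hole-filled so the printed model has no internal
  void there.

The classical baseline keeps all voxels at or above a global threshold
(default +200 HU, the conventional bone/stone setting). For excretory-phase
reconstruction the default threshold is the midpoint between the brightest
parenchyma and the opacified lumen, (45 + 300)/2 = 172.5 HU, which places
the recovered boundary at the 50% level of the blurred edge — the same
level the native band's μ + 15 ceiling selects when μ ≈ 7.5 HU, so the two
reconstructions of one geometry are commensurable by construction.

## Phantom generator

The generator is the package's test bed: it must make the *conditions* of
the clinical problem reproducible, not mimic any particular kidney.

- **Geometry.** An ellipsoidal pelvis (base semi-axes 3.5 × 5.0 × 3.0 mm)
  feeds 2–4 infundibula (capsules, base radius 0.6 mm, length 9–14 mm),
  each ending in 1–3 minor calyces (short capsules, base radius 0.55 mm,
  with spherical cups of base radius 1.1 mm). `dilation_factor` scales
  every radius linearly and nothing else, sweeping from the collapsed state
  (factor 1: limb diameter ≲ 1 in-plane voxel, which partial volume erases
  on the native phase — these phantoms are *meant* to defeat
  reconstruction) to hydronephrosis (factor ≥ 1.5, robustly
  reconstructible). Minor calyces are spheres rather than anatomical
  cups: the geometry is a stand-in chosen for exact rasterization and
  closed-form volumes, not a shape model.
- **Densities.** Urine U(0, 15) HU, parenchyma U(30, 45) HU, fat
  U(−120, −80) HU, stone N(720, 210²) HU clipped to [300, 3000] so no stone
  voxel masquerades as soft tissue, contrast-filled lumen 300 HU (typical
  opacified urine; configurable — the excretory phase's exact value is a
  modelling choice, not a measurement).
- **Imaging.** Grid 96³ at (0.5, 0.7, 0.7) mm — a 0.5 mm slice step with
  routine in-plane resolution. Partial volume is modelled as a Gaussian
  blur of the rendered HU field (σ = 0.7 voxels), then white Gaussian noise
  (σ = 5 HU) is added. Both phases of one spec share the tissue and noise
  random fields (seed-derived substreams), so before blurring they differ
  only at lumen voxels — the paired design has no hidden confound.
- **Ground truth.** The label map is rasterized analytically (voxel-centre
  membership, priority stone > lumen > parenchyma > fat; parenchymal shell
  = 7 mm around the lumen). The reference lumen volume is the closed form
  for single-primitive geometries and a fixed-seed Monte-Carlo quadrature
  (400k points) for unions, where no closed form exists.
- **Auto-footprints** stand in for user clicks: greedy maxima of the lumen
  distance transform, radius capped at 0.9× the local boundary distance,
  with a suppression neighbourhood so successive footprints sample distinct
  pockets.

What the phantom does **not** emulate: oblique/curved anatomy, vessels and
sinus fat abutting the PCS, beam hardening and streak artifacts, contrast
pharmacokinetics, respiratory motion. Passing tests therefore demonstrate
correctness of the algorithmic pipeline under the stated density/geometry
conditions — not clinical performance.

## Cohort experiment and statistics

`run_cohort` draws n phantom seeds from one master seed, reconstructs the
excretory phase with the classical threshold and the native phase with
3 auto-footprints, meshes and smooths both identically, and compares
surface areas. A native reconstruction counts as successful when its mask
is non-empty and overlaps ground truth at Dice ≥ 0.5 (the clinical
success/failure judgement has no published numeric criterion; 0.5 cleanly
separates the observed bimodal outcomes). Failures are recorded, never
raised.

Two comparison designs are provided. The primary report is the two-sample
workflow used in the clinical literature this package targets:
Shapiro–Wilk normality gate, then Student's t-test or Mann–Whitney. The
paired variant (Shapiro–Wilk on differences, paired t / Wilcoxon
signed-rank) is computed alongside. On synthetic cohorts the paired test
should be interpreted with care: both reconstructions derive
deterministically from the same geometry, so within-pair variance is tiny
(SD of differences ≈ 2% of the mean area) and the paired test flags even a
sub-percent systematic bias of the *pipeline* as significant — a statement
about numerical asymmetries of the two reconstruction routes, not about
model quality. At default settings (n = 20, dilation 1.5, noise 5 HU) the
areas agree to ≈ 2% on average, the two-sample test is far from
significance (p ≈ 0.66), and the paired test resolves the ≈ 1.6% residual
bias.

## Meshing and numerical choices

- Marching cubes runs at level 0.5 on the zero-padded binary mask,
  optionally presmoothed with a σ = 0.7-voxel Gaussian to round the slice
  staircase; vertices are scaled to mm and winding is flipped if needed so
  normals point outward.
- Smoothing is Taubin's two-step filter (λ = 0.5, μ = −0.53, 10
  iterations): unlike plain Laplacian smoothing it does not shrink the
  model, keeping the contrast/native area comparison unbiased (enclosed
  volume changes < 0.1% on a voxelized sphere, bounded at 2% by contract).
- Mesh coordinates are kept at single precision — the native precision of
  the marching-cubes extractor and of the STL format — so export/import
  round-trips are bit-exact; area/volume accumulation is double precision.
- The centerline is the 3-D thinning skeleton as a 26-connected voxel
  graph with physical edge lengths; spurs shorter than 2 mm (skeleton
  noise at these voxel sizes) are pruned; the root is the node of maximal
  inscribed-sphere radius, which lands in the pelvis. A compact blob whose
  skeleton voxels are mutually adjacent collapses to a single node.
- Degenerate inputs: empty masks, all-stone footprints, unreachable
  thresholds, and footprints outside the grid raise typed errors with
  stable messages; out-of-grid world coordinates are permitted and
  flagged, not rejected.

## Problem sizes

The default 96³ grid (48 × 67 × 67 mm) holds one kidney's collecting
system with margin and keeps a full two-phase reconstruction under ~1 s,
so the 20-phantom cohort — the package's standard experiment — runs in
well under a minute. All sizes are configurable through `PhantomSpec`.

## Known limitations

- Only axis-aligned volumes are supported; oblique gantry series are
  rejected rather than resampled.
- The grower's per-slice connectivity can leak through sub-voxel apertures
  in heavily noisy data; `min_region_voxels` and the two-sided band limit
  but do not eliminate this.
- Footprints on disconnected density regions are an error by design;
  bridging a noise-severed limb requires a footprint *path* rather than a
  mark on each side.
- No claim is made about a morphometric threshold separating
  reconstructible from non-reconstructible collecting systems;
  `dilation_factor` parameterizes the phantom, not a clinical criterion.
- The virtual-endoscopy module exports camera geometry only; rendering is
  left to external viewers.
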