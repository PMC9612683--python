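"""Footprint-seeded, density-adaptive segmentation of the PCS on native CT.

The workflow mirrors how a urologist annotates a collecting system:

1. Place a few circular *footprints* inside the lumen on axial slices.
2. Each footprint is refined by a "smart brush": within the circle, only
   voxels whose HU falls inside median ± k·MAD of the circle's non-stone
   voxels are kept, so a circle straddling a boundary does not pollute the
   seed.  Voxels at or above ``stone_threshold_hu`` are excluded from the
   label (stones are harvested later, never averaged).
3. The mean HU μ over all labelled voxels calibrates a two-sided acceptance
   band: a voxel joins the region iff μ − delta_low ≤ HU ≤ μ + delta_up.
   The default ``delta_up`` of 15 HU encodes the observation that the lumen
   boundary is marked by a density increase of more than 15 HU over urine.
4. Growth is per axial slice (8-connected flood fill) with the segmented
   area projected onto adjacent slices by direct overlap, then all slices
   are fused into one 3-D component containing the footprints.

All HU comparisons use integer-rounded values — CT samples are integral —
so results are bit-stable across float layouts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .volume_io import CTVolume

ALGORITHM_VERSION = "pcs3d-0.1"


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Footprint:
    """A user circle on an axial slice: ``center_mm`` is (y, x) in mm."""

    slice_index: int
    center_mm: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise SegmentationError("footprint radius must be positive")


@dataclass
class FootprintLabel:
    """Edge-refined voxel label of one footprint.

    ``labeled`` and ``excluded_stone`` are (n, 3) integer index arrays into
    the volume; they are disjoint subsets of the circle's voxels.
    """

    footprint: Footprint
    labeled: np.ndarray
    excluded_stone: np.ndarray


@dataclass
class SeedStats:
    """Density statistics of the union of labelled seed voxels."""

    mean_hu: float
    sd_hu: float
    n_voxels: int
    n_stone_excluded: int


@dataclass
class SegmentationConfig:
    delta_up: float = 15.0          # HU increase over mu that stops expansion
    delta_low: float = 20.0         # allowed HU decrease below mu
    stone_threshold_hu: float = 100.0
    brush_mad_k: float = 3.0
    in_slice_connectivity: int = 8
    min_region_voxels: int = 10

    def __post_init__(self) -> None:
        if self.delta_up <= 0 or self.delta_low <= 0:
            raise SegmentationError("delta_up and delta_low must be positive")
        if self.in_slice_connectivity not in (4, 8):
            raise SegmentationError("in_slice_connectivity must be 4 or 8")


@dataclass
class SegmentationMask:
    """Binary PCS mask plus harvested-stone sub-mask and full provenance."""

    mask: np.ndarray
    stone_mask: np.ndarray
    footprints: list[Footprint]
    seed_stats: Optional[SeedStats]
    config: SegmentationConfig
    method: str = "footprint_region_growing"
    version: str = ALGORITHM_VERSION

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.stone_mask = np.asarray(self.stone_mask, dtype=bool)
        if self.mask.shape != self.stone_mask.shape:
            raise SegmentationError("stone sub-mask must match the mask shape")
        if np.any(self.stone_mask & ~self.mask):
            raise SegmentationError("stone sub-mask must be a subset of the mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# footprints and seed statistics
# ---------------------------------------------------------------------------

def footprint_circle_indices(vol: CTVolume, fp: Footprint) -> np.ndarray:
    """(n, 3) indices of voxels whose centres fall inside the circle."""
    nz, ny, nx = vol.shape
    if not 0 <= fp.slice_index < nz:
        raise SegmentationError("footprint out of bounds: slice index outside volume")
    dz, dy, dx = vol.spacing
    oy, ox = vol.origin[1], vol.origin[2]
    y_mm = oy + np.arange(ny) * dy
    x_mm = ox + np.arange(nx) * dx
    cy, cx = fp.center_mm
    inside = ((y_mm[:, None] - cy) ** 2 + (x_mm[None, :] - cx) ** 2) <= fp.radius_mm ** 2
    jj, kk = np.nonzero(inside)
    if jj.size == 0:
        raise SegmentationError("footprint out of bounds: circle covers no voxel centre")
    ii = np.full(jj.shape, fp.slice_index, dtype=np.intp)
    return np.column_stack([ii, jj, kk])


def refine_footprint(vol: CTVolume, fp: Footprint, cfg: SegmentationConfig | None = None) -> FootprintLabel:
    """Smart-brush refinement of a circle footprint.

    Keeps circle voxels within median ± k·MAD of the circle's non-stone HU
    distribution; voxels at or above the stone threshold are set aside as
    excluded stone voxels (they never enter density statistics).
    """
    cfg = cfg or SegmentationConfig()
    idx = footprint_circle_indices(vol, fp)
    hu = vol.hu_int()[idx[:, 0], idx[:, 1], idx[:, 2]]
    is_stone = hu >= cfg.stone_threshold_hu
    if np.all(is_stone):
        raise SegmentationError("footprint on stone: every circle voxel is at stone density")
    soft_hu = hu[~is_stone]
    med = np.median(soft_hu)
    mad = np.median(np.abs(soft_hu - med))
    keep = (~is_stone) & (np.abs(hu - med) <= cfg.brush_mad_k * mad)
    return FootprintLabel(footprint=fp, labeled=idx[keep], excluded_stone=idx[is_stone])


def _union_rows(arrays: Sequence[np.ndarray]) -> np.ndarray:
    stacked = np.vstack([a for a in arrays if a.size] or [np.empty((0, 3), dtype=np.intp)])
    if stacked.size == 0:
        return stacked.astype(np.intp)
    return np.unique(stacked, axis=0)


def seed_statistics(labels: Sequence[FootprintLabel], vol: CTVolume) -> SeedStats:
    """Mean/SD of HU over the union of labelled voxels across footprints.

    Stone-excluded voxels never contribute; overlapping labels count each
    voxel once.
    """
    union = _union_rows([lab.labeled for lab in labels])
    if union.size == 0:
        raise SegmentationError("no seed voxels: all footprints refined to empty labels")
    excluded = _union_rows([lab.excluded_stone for lab in labels])
    hu = vol.hu_int()[union[:, 0], union[:, 1], union[:, 2]].astype(float)
    return SeedStats(mean_hu=float(hu.mean()), sd_hu=float(hu.std()),
                     n_voxels=int(union.shape[0]), n_stone_excluded=int(excluded.shape[0]))


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def _fusion_structure(in_slice_connectivity: int) -> np.ndarray:
    """Per-slice flood fill + direct overlap projection onto z±1, expressed as
    one 3-D connectivity structure: full in-plane neighbourhood, single-voxel
    column across slices."""
    s = np.zeros((3, 3, 3), dtype=bool)
    if in_slice_connectivity == 8:
        s[1] = True
    else:
        s[1] = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    s[0, 1, 1] = s[2, 1, 1] = True
    return s


def grow_region(vol: CTVolume, labels: Sequence[FootprintLabel], stats: SeedStats,
                cfg: SegmentationConfig | None = None) -> SegmentationMask:
    """Density-band region growing from the footprint seed voxels.

    A voxel joins iff μ − delta_low ≤ HU ≤ μ + delta_up; growth is
    8-connected within each axial slice, propagating to adjacent slices by
    direct overlap until no slice gains voxels; the fused mask is the single
    connected component containing the footprints (footprint-labelled voxels
    are always included, even if individually outside the band).  The result
    depends only on the footprint *set*, not its order.
    """
    cfg = cfg or SegmentationConfig()
    seeds = _union_rows([lab.labeled for lab in labels])
    if seeds.size == 0:
        raise SegmentationError("no seed voxels")
    hu = vol.hu_int()
    band = (hu >= stats.mean_hu - cfg.delta_low) & (hu <= stats.mean_hu + cfg.delta_up)
    if not band.any():
        raise SegmentationError("empty segmentation: no voxel passes the density band")
    # flood-fill semantics: seed voxels start the fill even when their own HU
    # falls outside the band (they are user-asserted lumen), so label the
    # band augmented with the seeds
    band[seeds[:, 0], seeds[:, 1], seeds[:, 2]] = True
    comp, _ = ndi.label(band, structure=_fusion_structure(cfg.in_slice_connectivity))
    seed_ids = np.unique(comp[seeds[:, 0], seeds[:, 1], seeds[:, 2]])
    seed_ids = seed_ids[seed_ids != 0]
    if seed_ids.size > 1:
        raise SegmentationError(
            "disconnected footprints: the footprint set spans multiple regions; "
            "segment them separately")
    mask = np.isin(comp, seed_ids)
    if not mask.any():
        raise SegmentationError("empty segmentation: no voxel passes the density band")
    return SegmentationMask(mask=mask, stone_mask=np.zeros_like(mask),
                            footprints=[lab.footprint for lab in labels],
                            seed_stats=stats, config=cfg)


def segment_native(vol: CTVolume, footprints: Sequence[Footprint],
                   cfg: SegmentationConfig | None = None) -> SegmentationMask:
    """Full native-phase pipeline: refine every footprint, pool seed
    statistics, grow, fuse."""
    cfg = cfg or SegmentationConfig()
    labels = [refine_footprint(vol, fp, cfg) for fp in footprints]
    stats = seed_statistics(labels, vol)
    return grow_region(vol, labels, stats, cfg)


def add_footprint(vol: CTVolume, current: SegmentationMask, new_fp: Footprint,
                  cfg: SegmentationConfig | None = None) -> SegmentationMask:
    """Add a footprint and update the segmentation.

    Contract: the result is bit-identical to running the whole pipeline from
    scratch on the extended footprint set (μ is recomputed over all labels),
    which is exactly how it is implemented — the growing step is cheap enough
    that no incremental shortcut is needed.
    """
    cfg = cfg or current.config
    return segment_native(vol, [*current.footprints, new_fp], cfg)


# ---------------------------------------------------------------------------
# stone harvesting
# ---------------------------------------------------------------------------

def _footprint_disk_volume(vol: CTVolume, footprints: Iterable[Footprint]) -> np.ndarray:
    disks = np.zeros(vol.shape, dtype=bool)
    for fp in footprints:
        idx = footprint_circle_indices(vol, fp)
        disks[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return disks


def harvest_stones(vol: CTVolume, mask: SegmentationMask,
                   footprints: Sequence[Footprint] | None = None,
                   cfg: SegmentationConfig | None = None) -> SegmentationMask:
    """Fold enclosed stones into the model without touching seed statistics.

    Every connected component of stone-density voxels (HU ≥ threshold) that
    lies entirely inside the region enclosed by mask ∪ footprint circles is
    added to the mask and recorded in the stone sub-mask; any cavity left
    around a harvested stone (partial-volume shells) is filled so the model
    has no internal void at the stone site.  Stones outside the mask and all
    circles are untouched.  Seed statistics are left exactly as computed.
    """
    cfg = cfg or mask.config
    footprints = list(footprints) if footprints is not None else mask.footprints
    hu = vol.hu_int()
    candidates = hu >= cfg.stone_threshold_hu
    if not candidates.any():
        return mask
    disks = _footprint_disk_volume(vol, footprints)
    enclosure = ndi.binary_fill_holes(mask.mask | disks)
    comp, n = ndi.label(candidates, structure=np.ones((3, 3, 3), dtype=bool))
    harvested = np.zeros_like(candidates)
    for i in range(1, n + 1):
        c = comp == i
        if np.all(enclosure[c]):
            harvested |= c
    if not harvested.any():
        return mask
    new_mask = ndi.binary_fill_holes(mask.mask | harvested)
    return SegmentationMask(mask=new_mask, stone_mask=mask.stone_mask | harvested,
                            footprints=mask.footprints, seed_stats=mask.seed_stats,
                            config=cfg, method=mask.method, version=mask.version)


# ---------------------------------------------------------------------------
# classical global-threshold baseline
# ---------------------------------------------------------------------------

def classical_threshold_segmentation(vol: CTVolume, threshold_hu: float = 200.0,
                                     seed_point: Sequence[int] | None = None,
                                     cfg: SegmentationConfig | None = None) -> SegmentationMask:
    """Classical 3-D reconstruction: keep every voxel at or above a global
    attenuation threshold.

    The +200 HU default is the conventional choice for bone and urinary
    stones; lower thresholds reconstruct softer tissue (e.g. the
    contrast-filled lumen of an excretory phase).  With ``seed_point`` the
    result is the 26-connected component containing the seed; without it,
    all components of at least ``min_region_voxels`` voxels are kept.
    """
    cfg = cfg or SegmentationConfig()
    if not np.isfinite(threshold_hu):
        raise SegmentationError("threshold must be finite")
    hu = vol.hu_int()
    above = hu >= threshold_hu
    if not above.any():
        raise SegmentationError("empty segmentation: no voxel reaches the threshold")
    structure = np.ones((3, 3, 3), dtype=bool)
    if seed_point is not None:
        seed = tuple(int(v) for v in seed_point)
        if not above[seed]:
            raise SegmentationError("seed not in mask: seed voxel is below the threshold")
        comp, _ = ndi.label(above, structure=structure)
        mask = comp == comp[seed]
    else:
        comp, n = ndi.label(above, structure=structure)
        counts = np.bincount(comp.ravel())
        keep = np.flatnonzero(counts >= cfg.min_region_voxels)
        keep = keep[keep != 0]
        mask = np.isin(comp, keep)
        if not mask.any():
            raise SegmentationError("empty segmentation: all components below min_region_voxels")
    return SegmentationMask(mask=mask, stone_mask=np.zeros_like(mask), footprints=[],
                            seed_stats=None, config=cfg, method="classical_threshold")
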