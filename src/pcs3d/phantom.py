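"""Synthetic CT phantom of a branching pelvicalyceal system (PCS).

The generator builds a geometric stand-in for the renal collecting system —
an ellipsoidal pelvis feeding 2–4 infundibula, each ending in 1–3 minor-calyx
cups — embeds it in a parenchymal shell surrounded by perinephric fat, and
renders paired native / excretory CT volumes of the *same* geometry:

* urine (native lumen) 0–15 HU, parenchyma 30–45 HU, fat −120 to −80 HU,
  contrast-opacified urine (excretory lumen) a constant, configurable HU;
* an optional stone: density drawn from Normal(720, 210) HU, ~9 mm across;
* partial volume modelled as a Gaussian blur, then additive Gaussian noise.

A ``dilation_factor`` scales every lumen radius, moving the phantom from
the collapsed state of a normal kidney (thin, sub-voxel limbs that defeat
native-phase reconstruction) to an obstructed, hydronephrotic one.

Everything is reproducible bit-exactly from ``PhantomSpec.seed``; the two
phases share the tissue and noise random fields, so before blurring they
differ only at lumen voxels.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .volume_io import (
    CTVolume,
    LabelVolume,
    LABEL_BACKGROUND,
    LABEL_LUMEN,
    LABEL_PARENCHYMA,
    LABEL_STONE,
    voxel_to_world,
)
from .segmentation import Footprint


class PhantomError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Densities follow the ranges observed on clinical CT: urine 0–15 HU,
    parenchyma 30–45 HU, stones 720 ± 210 HU and about 9 mm in size.
    The grid default is a 0.5 mm slice step with 0.7 mm in-plane pixels.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.5, 0.7, 0.7)
    urine_hu_range: tuple[float, float] = (0.0, 15.0)
    parenchyma_hu_range: tuple[float, float] = (30.0, 45.0)
    fat_hu_range: tuple[float, float] = (-120.0, -80.0)
    stone_hu_mean: float = 720.0
    stone_hu_sd: float = 210.0
    stone_hu_clip: tuple[float, float] = (300.0, 3000.0)
    stone_diameter_mm: float = 9.0
    stone_present: bool = False
    contrast_lumen_hu: float = 300.0
    n_major_calyces: tuple[int, int] = (2, 4)
    n_minor_per_major: tuple[int, int] = (1, 3)
    dilation_factor: float = 1.0
    parenchyma_shell_mm: float = 7.0
    ureter_stub: bool = False
    noise_sd_hu: float = 5.0
    blur_sigma_voxels: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("urine_hu_range", "parenchyma_hu_range", "fat_hu_range", "stone_hu_clip"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise PhantomError(f"{name} must be ordered (lo <= hi)")
        if self.dilation_factor < 1.0:
            raise PhantomError("dilation_factor must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise PhantomError("spacing must be positive")
        lo, hi = self.n_major_calyces
        if not (1 <= lo <= hi):
            raise PhantomError("n_major_calyces bounds must satisfy 1 <= lo <= hi")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        for key in ("shape", "spacing", "urine_hu_range", "parenchyma_hu_range",
                    "fat_hu_range", "stone_hu_clip", "n_major_calyces", "n_minor_per_major"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# --- geometric primitives (all coordinates (z, y, x) in mm) ----------------

@dataclass
class Sphere:
    center: tuple[float, float, float]
    radius: float


@dataclass
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


@dataclass
class Capsule:
    """A cylinder with hemispherical caps: segment p0→p1 swept by ``radius``."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float


@dataclass
class PCSGeometry:
    """Primitive tree of the collecting system, rooted at the pelvis."""

    pelvis: Optional[Ellipsoid]
    infundibula: list[Capsule] = field(default_factory=list)
    minor_branches: list[Capsule] = field(default_factory=list)
    calyx_cups: list[Sphere] = field(default_factory=list)
    ureter: Optional[Capsule] = None
    stone: Optional[Sphere] = None
    tips: list[tuple[float, float, float]] = field(default_factory=list)

    def lumen_primitives(self) -> list:
        prims: list = []
        if self.pelvis is not None:
            prims.append(self.pelvis)
        prims.extend(self.infundibula)
        prims.extend(self.minor_branches)
        prims.extend(self.calyx_cups)
        if self.ureter is not None:
            prims.append(self.ureter)
        return prims


@dataclass
class GroundTruth:
    """Per-voxel labels plus analytic references for validation."""

    labels: LabelVolume
    lumen_volume_mm3: float
    tips: list[tuple[float, float, float]]


# base (dilation_factor = 1, i.e. collapsed) dimensions in mm
_PELVIS_SEMI_AXES = (3.5, 5.0, 3.0)
_INFUNDIBULUM_RADIUS = 0.6
_INFUNDIBULUM_LENGTH = (9.0, 14.0)
_MINOR_RADIUS = 0.55
_MINOR_LENGTH = (3.0, 6.0)
_CUP_RADIUS = 1.1
_URETER_RADIUS = 1.0
_URETER_LENGTH = 12.0
_EDGE_MARGIN_MM = 4.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def sample_pcs_geometry(spec: PhantomSpec) -> PCSGeometry:
    """Sample a random branching PCS tree.

    Branch *directions and lengths* depend only on the seed; the
    ``dilation_factor`` scales every radius (pelvis semi-axes, capsule and
    cup radii) linearly and nothing else, so the same seed at two dilation
    factors yields geometrically aligned trees.
    """
    rng = np.random.default_rng([int(spec.seed), 0])
    d = spec.dilation_factor
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    center = extent / 2.0
    half = extent / 2.0 - _EDGE_MARGIN_MM
    if np.any(half < np.asarray(_PELVIS_SEMI_AXES) * d):
        raise PhantomError("degenerate geometry: grid too small for the pelvis")

    pelvis = Ellipsoid(tuple(center), tuple(np.asarray(_PELVIS_SEMI_AXES) * d))

    n_major = int(rng.integers(spec.n_major_calyces[0], spec.n_major_calyces[1] + 1))
    infundibula: list[Capsule] = []
    minor_branches: list[Capsule] = []
    cups: list[Sphere] = []
    tips: list[tuple[float, float, float]] = []

    # majors fan out laterally (toward +x) with azimuths spread in the y-z plane
    azimuths = np.linspace(-1.1, 1.1, n_major) + rng.uniform(-0.15, 0.15, n_major)
    for i in range(n_major):
        a = azimuths[i]
        direction = _unit(np.array([np.sin(a), np.cos(a) * np.sin(a * 1.3 + rng.uniform(-0.3, 0.3)), 0.9]))
        length = rng.uniform(*_INFUNDIBULUM_LENGTH)
        start = center + direction * 0.6 * np.asarray(_PELVIS_SEMI_AXES)
        # clamp so the farthest minor-calyx cup stays inside the grid
        reach = length + _MINOR_LENGTH[1] + 3.0
        scale = min(1.0, float(np.min((half - np.abs(start - center)) / (np.abs(direction) * reach + 1e-9))))
        length *= max(scale, 0.3)
        end = start + direction * length
        infundibula.append(Capsule(tuple(start), tuple(end), _INFUNDIBULUM_RADIUS * d))

        n_minor = int(rng.integers(spec.n_minor_per_major[0], spec.n_minor_per_major[1] + 1))
        spread = np.linspace(-0.5, 0.5, n_minor) if n_minor > 1 else np.array([0.0])
        for s in spread:
            perp = _unit(np.cross(direction, [1.0, 0.0, 0.0]))
            mdir = _unit(direction + s * perp + rng.uniform(-0.1, 0.1, 3))
            mlen = rng.uniform(*_MINOR_LENGTH) * max(scale, 0.3)
            mend = end + mdir * mlen
            mend = np.clip(mend, center - half + 2.0, center + half - 2.0)
            minor_branches.append(Capsule(tuple(end), tuple(mend), _MINOR_RADIUS * d))
            cups.append(Sphere(tuple(mend), _CUP_RADIUS * d))
            tips.append(tuple(mend))

    ureter = None
    if spec.ureter_stub:
        udir = _unit(np.array([-1.0, 0.2, -0.1]))
        u0 = center + udir * 0.5 * np.asarray(_PELVIS_SEMI_AXES)
        u1 = np.clip(u0 + udir * _URETER_LENGTH, center - half, center + half)
        ureter = Capsule(tuple(u0), tuple(u1), _URETER_RADIUS * d)

    stone = None
    if spec.stone_present:
        stone = Sphere(tuple(center), spec.stone_diameter_mm / 2.0)

    return PCSGeometry(pelvis=pelvis, infundibula=infundibula,
                       minor_branches=minor_branches, calyx_cups=cups,
                       ureter=ureter, stone=stone, tips=tips)


# --- rasterization ----------------------------------------------------------

def _grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = np.arange(spec.shape[0]) * spec.spacing[0]
    y = np.arange(spec.shape[1]) * spec.spacing[1]
    x = np.arange(spec.shape[2]) * spec.spacing[2]
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def _primitive_mask(prim, zz, yy, xx) -> np.ndarray:
    if isinstance(prim, Sphere):
        cz, cy, cx = prim.center
        return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= prim.radius ** 2
    if isinstance(prim, Ellipsoid):
        cz, cy, cx = prim.center
        az, ay, ax = prim.semi_axes
        return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    if isinstance(prim, Capsule):
        p0 = np.asarray(prim.p0)
        p1 = np.asarray(prim.p1)
        axis = p1 - p0
        L2 = float(axis @ axis)
        dz, dy, dx = zz - p0[0], yy - p0[1], xx - p0[2]
        if L2 < 1e-12:
            return dz ** 2 + dy ** 2 + dx ** 2 <= prim.radius ** 2
        t = np.clip((dz * axis[0] + dy * axis[1] + dx * axis[2]) / L2, 0.0, 1.0)
        qz = dz - t * axis[0]
        qy = dy - t * axis[1]
        qx = dx - t * axis[2]
        return qz ** 2 + qy ** 2 + qx ** 2 <= prim.radius ** 2
    raise TypeError(f"unknown primitive {type(prim)}")


def _primitive_volume(prim) -> float:
    if isinstance(prim, Sphere):
        return 4.0 / 3.0 * np.pi * prim.radius ** 3
    if isinstance(prim, Ellipsoid):
        az, ay, ax = prim.semi_axes
        return 4.0 / 3.0 * np.pi * az * ay * ax
    if isinstance(prim, Capsule):
        L = float(np.linalg.norm(np.asarray(prim.p1) - np.asarray(prim.p0)))
        return np.pi * prim.radius ** 2 * L + 4.0 / 3.0 * np.pi * prim.radius ** 3
    raise TypeError(type(prim))


def _union_volume_mm3(prims: list, seed: int, n_samples: int = 400_000) -> float:
    """Reference lumen volume: exact for a single primitive, otherwise a
    fixed-seed Monte-Carlo quadrature over the union's bounding box."""
    if not prims:
        return 0.0
    if len(prims) == 1:
        return _primitive_volume(prims[0])
    los, his = [], []
    for p in prims:
        if isinstance(p, Sphere):
            c, r = np.asarray(p.center), p.radius
            los.append(c - r); his.append(c + r)
        elif isinstance(p, Ellipsoid):
            c, a = np.asarray(p.center), np.asarray(p.semi_axes)
            los.append(c - a); his.append(c + a)
        else:
            q0, q1 = np.asarray(p.p0), np.asarray(p.p1)
            los.append(np.minimum(q0, q1) - p.radius)
            his.append(np.maximum(q0, q1) + p.radius)
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    rng = np.random.default_rng([int(seed), 3])
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = np.zeros(n_samples, dtype=bool)
    for p in prims:
        inside |= _primitive_mask(p, pts[:, 0], pts[:, 1], pts[:, 2])
    return float(inside.mean() * np.prod(hi - lo))


def rasterize_phantom(geom: PCSGeometry, spec: PhantomSpec) -> tuple[LabelVolume, GroundTruth]:
    """Label every voxel by the highest-priority primitive covering its centre
    (stone > lumen > parenchyma > fat), wrapping the lumen in a parenchymal
    shell of ``parenchyma_shell_mm``."""
    zz, yy, xx = _grid_mm(spec)
    lumen = np.zeros(spec.shape, dtype=bool)
    for prim in geom.lumen_primitives():
        lumen |= _primitive_mask(prim, zz, yy, xx)

    labels = np.zeros(spec.shape, dtype=np.int16)
    if lumen.any():
        dist = ndi.distance_transform_edt(~lumen, sampling=spec.spacing)
        labels[dist <= spec.parenchyma_shell_mm] = LABEL_PARENCHYMA
    labels[lumen] = LABEL_LUMEN
    if geom.stone is not None:
        stone = _primitive_mask(geom.stone, zz, yy, xx)
        labels[stone] = LABEL_STONE

    lv = LabelVolume(labels, spec.spacing, (0.0, 0.0, 0.0))
    vol_ref = _union_volume_mm3(geom.lumen_primitives(), spec.seed)
    return lv, GroundTruth(labels=lv, lumen_volume_mm3=vol_ref, tips=list(geom.tips))


# --- rendering --------------------------------------------------------------

def sample_stone_hu(n: int, seed: int | None = None, rng: np.random.Generator | None = None,
                    spec: PhantomSpec | None = None, clip: bool = True) -> np.ndarray:
    """Draw stone densities from the generator's Normal(720, 210) HU model."""
    spec = spec or PhantomSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.normal(spec.stone_hu_mean, spec.stone_hu_sd, size=n)
    if clip:
        draws = np.clip(draws, *spec.stone_hu_clip)
    return draws


def render_phase(labels: LabelVolume, phase: str, spec: PhantomSpec) -> CTVolume:
    """Render one CT-urography phase of a label map.

    ``native`` fills the lumen with urine density; ``excretory`` with a
    constant contrast density.  The per-voxel tissue field and the noise
    field are drawn from seed-derived substreams, so the two phases of one
    spec differ only at lumen voxels before blurring.
    """
    if phase not in ("native", "excretory"):
        raise PhantomError(f"unknown phase: {phase!r}")
    lab = labels.labels
    rng_tissue = np.random.default_rng([int(spec.seed), 1])
    u = rng_tissue.random(lab.shape)

    hu = np.empty(lab.shape, dtype=np.float64)
    for code, (lo, hi) in ((LABEL_BACKGROUND, spec.fat_hu_range),
                           (LABEL_PARENCHYMA, spec.parenchyma_hu_range),
                           (LABEL_LUMEN, spec.urine_hu_range)):
        m = lab == code
        hu[m] = lo + (hi - lo) * u[m]
    stone_mask = lab == LABEL_STONE
    if stone_mask.any():
        hu[stone_mask] = sample_stone_hu(int(stone_mask.sum()), rng=rng_tissue, spec=spec)
    if phase == "excretory":
        hu[lab == LABEL_LUMEN] = spec.contrast_lumen_hu

    if spec.blur_sigma_voxels > 0:
        hu = ndi.gaussian_filter(hu, sigma=spec.blur_sigma_voxels)
    if spec.noise_sd_hu > 0:
        rng_noise = np.random.default_rng([int(spec.seed), 2])
        hu = hu + rng_noise.normal(0.0, spec.noise_sd_hu, lab.shape)
    np.clip(hu, -1024.0, 3071.0, out=hu)
    return CTVolume(hu, labels.spacing, labels.origin)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, CTVolume, GroundTruth]:
    """Convenience: geometry → labels → (native, excretory, ground truth)."""
    geom = sample_pcs_geometry(spec)
    labels, gt = rasterize_phantom(geom, spec)
    native = render_phase(labels, "native", spec)
    excretory = render_phase(labels, "excretory", spec)
    return native, excretory, gt


# --- automated footprint placement -----------------------------------------

def auto_footprints(gt: GroundTruth, k: int, radius_fraction: float = 0.9) -> list[Footprint]:
    """Place ``k`` circle footprints at interior maxima of the lumen distance
    transform — an automated stand-in for the 2–3 clicks a user would make.

    Each footprint's radius is capped by the local distance to the lumen
    boundary, so every circle lies fully inside the lumen.  Returns fewer
    than ``k`` (with a warning) when the lumen has fewer distinct interior
    maxima.
    """
    if k < 1:
        raise PhantomError("k must be >= 1")
    lab = gt.labels.labels
    mask = (lab == LABEL_LUMEN) | (lab == LABEL_STONE)
    if not mask.any():
        raise PhantomError("nothing to annotate: lumen is empty")
    spacing = gt.labels.spacing
    edt = ndi.distance_transform_edt(mask, sampling=spacing)
    footprints: list[Footprint] = []
    for _ in range(k):
        idx = np.unravel_index(int(np.argmax(edt)), edt.shape)
        dist = float(edt[idx])
        if dist <= 0:
            break
        world = voxel_to_world(gt.labels, idx)
        radius = max(radius_fraction * dist, min(spacing[1], spacing[2]) * 0.51)
        footprints.append(Footprint(slice_index=int(idx[0]),
                                    center_mm=(float(world[1]), float(world[2])),
                                    radius_mm=float(radius)))
        # suppress a neighbourhood so the next maximum is a distinct pocket
        zz, yy, xx = _grid_mm_spacing(edt.shape, spacing)
        suppress = max(2.5 * dist, 6.0)
        ball = ((zz - idx[0] * spacing[0]) ** 2 + (yy - idx[1] * spacing[1]) ** 2
                + (xx - idx[2] * spacing[2]) ** 2) <= suppress ** 2
        edt[ball] = 0.0
    if len(footprints) < k:
        warnings.warn(f"only {len(footprints)} of {k} requested footprints placed "
                      "(lumen has fewer distinct interior maxima)", stacklevel=2)
    return footprints


def _grid_mm_spacing(shape, spacing):
    z = np.arange(shape[0]) * spacing[0]
    y = np.arange(shape[1]) * spacing[1]
    x = np.arange(shape[2]) * spacing[2]
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)
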