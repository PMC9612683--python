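import numpy as np
import pytest

from pcs3d import CTVolume, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def dilated_phantom():
    """Noise-free dilated phantom: (native, excretory, ground truth, spec)."""
    spec = PhantomSpec(seed=1, dilation_factor=1.5, noise_sd_hu=0.0)
    native, excretory, gt = generate_phantom(spec)
    return native, excretory, gt, spec


@pytest.fixture(scope="session")
def noisy_phantom():
    """Dilated phantom at the default noise level."""
    spec = PhantomSpec(seed=1, dilation_factor=1.5)
    native, excretory, gt = generate_phantom(spec)
    return native, excretory, gt, spec


def make_sphere_mask(radius_mm: float, spacing: float, margin_mm: float = 2.0):
    """Voxelized sphere mask and a matching empty CTVolume."""
    n = int(2 * (radius_mm + margin_mm) / spacing) + 1
    coords = np.arange(n) * spacing
    z, y, x = np.meshgrid(coords, coords, coords, indexing="ij")
    c = coords[n // 2]
    mask = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_mm**2
    vol = CTVolume(np.zeros((n, n, n)), (spacing, spacing, spacing))
    return mask, vol


def make_tube_mask(radius_mm=3.0, length_mm=40.0, spacing=(0.5, 0.7, 0.7)):
    """Axis-aligned (z) cylinder mask with a matching empty CTVolume."""
    nz = int((length_mm + 10) / spacing[0])
    ny = nx = int(4 * radius_mm / spacing[1]) + 9
    z = np.arange(nz)[:, None, None] * spacing[0]
    y = np.arange(ny)[None, :, None] * spacing[1]
    x = np.arange(nx)[None, None, :] * spacing[2]
    # axis through exact voxel centres: keeps the discrete cross-section odd
    cy, cx = (ny // 2) * spacing[1], (nx // 2) * spacing[2]
    z0 = 5.0
    mask = ((y - cy) ** 2 + (x - cx) ** 2 <= radius_mm**2) & (z >= z0) & (z <= z0 + length_mm)
    vol = CTVolume(np.zeros((nz, ny, nx)), spacing)
    return mask, vol
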