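from collections import deque

import numpy as np
import pytest

from pcs3d import (CTVolume, Footprint, SegmentationConfig, add_footprint,
                   auto_footprints, classical_threshold_segmentation, dice,
                   grow_region, harvest_stones, refine_footprint, seed_statistics,
                   segment_native)
from pcs3d.segmentation import FootprintLabel, SegmentationError
from pcs3d.volume_io import LABEL_LUMEN, LABEL_STONE


def flat_volume(hu_2d, spacing=(1.0, 1.0, 1.0)):
    """Single-slice CTVolume from a 2-D HU array."""
    return CTVolume(np.asarray(hu_2d, float)[None, :, :], spacing)


def label_from_indices(indices, fp=None):
    fp = fp or Footprint(0, (0.0, 0.0), 1.0)
    return FootprintLabel(footprint=fp,
                          labeled=np.asarray(indices, dtype=np.intp).reshape(-1, 3),
                          excluded_stone=np.empty((0, 3), dtype=np.intp))


def bfs_flood_fill(hu, seeds, mu, delta_low, delta_up):
    """Independent oracle: queue-based flood fill, 8-connected within each
    axial slice plus direct overlap onto z±1, accepting voxels inside the
    density band; seed voxels always start the fill."""
    hu = np.rint(hu).astype(int)
    nz, ny, nx = hu.shape
    offsets = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dy, dx) != (0, 0)] + [(1, 0, 0), (-1, 0, 0)]
    seen = set(map(tuple, seeds))
    queue = deque(seen)
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            nb = (z + dz, y + dy, x + dx)
            if not (0 <= nb[0] < nz and 0 <= nb[1] < ny and 0 <= nb[2] < nx):
                continue
            if nb in seen:
                continue
            if mu - delta_low <= hu[nb] <= mu + delta_up:
                seen.add(nb)
                queue.append(nb)
    return seen


class TestRefineFootprint:
    def test_uniform_circle_fully_labeled(self):
        vol = flat_volume(np.full((11, 11), 10.0), spacing=(1, 1, 1))
        fp = Footprint(0, (5.0, 5.0), 3.0)
        lab = refine_footprint(vol, fp)
        n_circle = ((np.add.outer((np.arange(11) - 5.0) ** 2,
                                  (np.arange(11) - 5.0) ** 2)) <= 9.0).sum()
        assert len(lab.labeled) == n_circle
        assert len(lab.excluded_stone) == 0

    def test_straddling_circle_matches_median_mad_oracle(self):
        """Circle half in lumen (~5 HU), minority in parenchyma (~40 HU):
        the smart brush keeps exactly the median±k·MAD band."""
        rng = np.random.default_rng(3)
        img = rng.uniform(3, 7, (13, 13))
        img[:, 9:] = rng.uniform(38, 42, (13, 4))
        vol = flat_volume(img)
        fp = Footprint(0, (6.0, 6.0), 5.0)
        lab = refine_footprint(vol, fp)
        # brute-force recomputation on the constructed patch
        hu = np.rint(img).astype(int)
        jj, kk = np.nonzero(np.add.outer((np.arange(13) - 6.0) ** 2,
                                         (np.arange(13) - 6.0) ** 2) <= 25.0)
        circle_hu = hu[jj, kk]
        med = np.median(circle_hu)
        mad = np.median(np.abs(circle_hu - med))
        expect = {(0, j, k) for j, k, v in zip(jj, kk, circle_hu)
                  if abs(v - med) <= 3 * mad}
        got = set(map(tuple, lab.labeled))
        assert got == expect
        assert all(hu[j, k] < 30 for _, j, k in got)  # parenchyma dropped

    def test_stone_voxel_goes_to_excluded_set(self):
        img = np.full((9, 9), 8.0)
        img[4, 4] = 720.0
        lab = refine_footprint(flat_volume(img), Footprint(0, (4.0, 4.0), 2.5))
        assert (0, 4, 4) in set(map(tuple, lab.excluded_stone))
        assert (0, 4, 4) not in set(map(tuple, lab.labeled))

    def test_circle_outside_grid_and_all_stone_errors(self):
        vol = flat_volume(np.full((9, 9), 8.0))
        with pytest.raises(SegmentationError, match="out of bounds"):
            refine_footprint(vol, Footprint(0, (100.0, 100.0), 2.0))
        stone = flat_volume(np.full((9, 9), 800.0))
        with pytest.raises(SegmentationError, match="on stone"):
            refine_footprint(stone, Footprint(0, (4.0, 4.0), 2.0))


class TestSeedStatistics:
    def test_stone_excluded_from_mean(self):
        img = np.array([[5.0, 10.0, 720.0]])
        vol = flat_volume(img)
        lab = FootprintLabel(Footprint(0, (0.0, 0.0), 1.0),
                             labeled=np.array([[0, 0, 0], [0, 0, 1]], dtype=np.intp),
                             excluded_stone=np.array([[0, 0, 2]], dtype=np.intp))
        stats = seed_statistics([lab], vol)
        assert stats.mean_hu == 7.5
        assert stats.n_stone_excluded == 1

    def test_uniform_label_zero_sd(self):
        vol = flat_volume(np.full((4, 4), 12.0))
        lab = label_from_indices([[0, j, k] for j in range(4) for k in range(4)])
        stats = seed_statistics([lab], vol)
        assert stats.mean_hu == 12.0 and stats.sd_hu == 0.0

    def test_two_labels_match_bruteforce_mean(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(-50, 50, (20, 20))
        vol = flat_volume(img)
        idx_a = [[0, j, k] for j in range(10) for k in range(10)]
        idx_b = [[0, j, k] for j in range(10, 20) for k in range(10, 20)]
        stats = seed_statistics([label_from_indices(idx_a), label_from_indices(idx_b)], vol)
        hu = np.rint(img).astype(int)
        expect = np.mean([hu[j, k] for _, j, k in idx_a + idx_b])
        assert stats.mean_hu == pytest.approx(expect)

    def test_mean_shift_equals_removing_stone_voxel(self):
        """mu computed with a stone voxel inside the circle equals the mean
        with that voxel's HU simply removed."""
        img = np.full((9, 9), 8.0)
        img[3, 3] = 11.0
        vol_clean = flat_volume(img.copy())
        img_stone = img.copy()
        img_stone[4, 4] = 720.0
        vol_stone = flat_volume(img_stone)
        fp = Footprint(0, (4.0, 4.0), 2.5)
        s_stone = seed_statistics([refine_footprint(vol_stone, fp)], vol_stone)
        lab_clean = refine_footprint(vol_clean, fp)
        keep = [r for r in map(tuple, lab_clean.labeled) if r != (0, 4, 4)]
        s_ref = seed_statistics([label_from_indices(keep)], vol_clean)
        assert s_stone.mean_hu == pytest.approx(s_ref.mean_hu)


class TestGrowRegion:
    def test_printed_row_worked_example(self):
        """Row [40, 12, 8, 5, 14, 38] seeded at {5, 8} (mu = 6.5): growth keeps
        {12, 8, 5, 14} and stops at 40/38 (> mu + 15)."""
        vol = flat_volume(np.array([[40.0, 12.0, 8.0, 5.0, 14.0, 38.0]]))
        labs = [label_from_indices([[0, 0, 2], [0, 0, 3]])]
        stats = seed_statistics(labs, vol)
        assert stats.mean_hu == 6.5
        mask = grow_region(vol, labs, stats)
        expect = np.zeros((1, 1, 6), bool)
        expect[0, 0, 1:5] = True
        np.testing.assert_array_equal(mask.mask, expect)

    def test_uniform_volume_at_mu_fills_grid(self):
        vol = CTVolume(np.full((4, 6, 6), 10.0), (1, 1, 1))
        labs = [label_from_indices([[2, 3, 3]])]
        mask = grow_region(vol, labs, seed_statistics(labs, vol))
        assert mask.mask.all()

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_flood_fill(self, trial):
        rng = np.random.default_rng(100 + trial)
        shape = tuple(rng.integers(4, 17, 3))
        vol = CTVolume(rng.integers(-30, 60, shape).astype(float), (1, 1, 1))
        seed = [list(rng.integers(0, s) for s in shape)]
        labs = [label_from_indices(seed)]
        stats = seed_statistics(labs, vol)
        cfg = SegmentationConfig()
        expect = bfs_flood_fill(vol.voxels, seed, stats.mean_hu,
                                cfg.delta_low, cfg.delta_up)
        mask = grow_region(vol, labs, stats, cfg)
        assert set(map(tuple, np.argwhere(mask.mask))) == expect

    def test_monotone_in_delta_up(self):
        rng = np.random.default_rng(5)
        vol = CTVolume(rng.integers(-10, 50, (6, 10, 10)).astype(float), (1, 1, 1))
        labs = [label_from_indices([[3, 5, 5]])]
        stats = seed_statistics(labs, vol)
        prev = None
        for dup in (5.0, 15.0, 40.0):
            m = grow_region(vol, labs, stats, SegmentationConfig(delta_up=dup)).mask
            if prev is not None:
                assert np.all(prev <= m)  # non-decreasing region
            prev = m

    def test_no_voxel_in_band_errors(self):
        vol = flat_volume(np.full((4, 4), 500.0))
        labs = [label_from_indices([[0, 1, 1]])]
        with pytest.raises(SegmentationError):
            stats = seed_statistics(labs, vol)
            # seed itself at 500 HU: mu = 500, the whole grid is in band;
            # force an out-of-band situation instead
            grow_region(vol, labs,
                        type(stats)(mean_hu=-900.0, sd_hu=0.0, n_voxels=1,
                                    n_stone_excluded=0),
                        SegmentationConfig(min_region_voxels=10))

    def test_disconnected_footprints_error(self):
        img = np.full((1, 5, 9), 40.0)
        img[0, :, :3] = 5.0
        img[0, :, 6:] = 5.0
        vol = CTVolume(img, (1, 1, 1))
        labs = [label_from_indices([[0, 2, 1]]), label_from_indices([[0, 2, 7]])]
        with pytest.raises(SegmentationError, match="disconnected"):
            grow_region(vol, labs, seed_statistics(labs, vol))


class TestFootprintWorkflow:
    def test_order_invariance(self, dilated_phantom):
        native, _, gt, _ = dilated_phantom
        fps = auto_footprints(gt, 3)
        a = segment_native(native, fps)
        b = segment_native(native, fps[::-1])
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_redundant_footprint_is_idempotent(self, dilated_phantom):
        native, _, gt, _ = dilated_phantom
        fps = auto_footprints(gt, 2)
        mask = segment_native(native, fps)
        inner = fps[0]
        redundant = Footprint(inner.slice_index, inner.center_mm,
                              max(inner.radius_mm / 2, 1.0))
        updated = add_footprint(native, mask, redundant)
        np.testing.assert_array_equal(updated.mask, mask.mask)

    def test_incremental_equals_batch(self, noisy_phantom):
        native, _, gt, _ = noisy_phantom
        fps = auto_footprints(gt, 3)
        current = segment_native(native, fps[:1])
        for fp in fps[1:]:
            current = add_footprint(native, current, fp)
        batch = segment_native(native, fps)
        np.testing.assert_array_equal(current.mask, batch.mask)

    def test_new_footprint_in_denser_pocket_grows_mask(self):
        """A second pocket at higher HU joins only after its footprint shifts
        mu upward — the mask strictly grows."""
        img = np.full((1, 7, 13), 60.0)
        img[0, 2:5, 1:5] = 5.0    # pocket A
        img[0, 2:5, 8:12] = 28.0  # pocket B, above mu_A + 15
        img[0, 3, 5:8] = 12.0     # corridor
        vol = CTVolume(img, (1, 1, 1))
        fp_a = Footprint(0, (3.0, 2.0), 1.2)
        mask_a = segment_native(vol, [fp_a])
        assert not mask_a.mask[0, 3, 9]
        mask_ab = add_footprint(vol, mask_a, Footprint(0, (3.0, 9.0), 1.2))
        assert np.all(mask_a.mask <= mask_ab.mask)
        assert mask_ab.n_voxels > mask_a.n_voxels
        assert mask_ab.mask[0, 3, 9]


class TestHarvestStones:
    def _lumen_with_stone(self):
        shape = (24, 24, 24)
        z, y, x = np.meshgrid(*[np.arange(s) * 1.0 for s in shape], indexing="ij")
        lumen = (z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 9.0**2
        stone = (z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 4.5**2
        hu = np.where(lumen, 8.0, 40.0)
        hu[stone] = 720.0
        return CTVolume(hu, (1, 1, 1)), lumen, stone

    def test_enclosed_stone_harvested_into_model(self):
        vol, lumen, stone = self._lumen_with_stone()
        fp = Footprint(12, (12.0, 12.0), 6.0)  # circle over the stone
        mask = segment_native(vol, [fp])
        assert not mask.mask[12, 12, 12]  # stone not in grown region
        out = harvest_stones(vol, mask, [fp])
        assert out.mask[12, 12, 12]
        assert out.stone_mask[12, 12, 12]
        assert np.all(out.stone_mask <= out.mask)

    def test_harvest_leaves_no_cavity_at_stone_site(self):
        from scipy import ndimage as ndi

        vol, lumen, stone = self._lumen_with_stone()
        fp = Footprint(12, (12.0, 12.0), 6.0)
        out = harvest_stones(vol, segment_native(vol, [fp]), [fp])
        filled = ndi.binary_fill_holes(out.mask)
        np.testing.assert_array_equal(out.mask, filled)

    def test_stone_outside_mask_and_circles_untouched(self):
        vol, lumen, stone = self._lumen_with_stone()
        hu = vol.voxels.copy()
        hu[2, 2, 2] = 900.0  # isolated stone far from everything
        vol2 = CTVolume(hu, (1, 1, 1))
        fp = Footprint(12, (12.0, 12.0), 6.0)
        out = harvest_stones(vol2, segment_native(vol2, [fp]), [fp])
        assert not out.mask[2, 2, 2]

    def test_seed_statistics_untouched_by_harvest(self):
        vol, *_ = self._lumen_with_stone()
        fp = Footprint(12, (12.0, 12.0), 6.0)
        mask = segment_native(vol, [fp])
        out = harvest_stones(vol, mask, [fp])
        assert out.seed_stats == mask.seed_stats
        assert out.seed_stats.mean_hu < 100  # no stone HU leaked into mu


class TestClassicalThreshold:
    def test_default_recovers_stone_only(self):
        shape = (20, 20, 20)
        z, y, x = np.meshgrid(*[np.arange(s) * 1.0 for s in shape], indexing="ij")
        stone = (z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2 <= 4.0**2
        hu = np.where(stone, 720.0, 35.0)
        mask = classical_threshold_segmentation(CTVolume(hu, (1, 1, 1)))
        np.testing.assert_array_equal(mask.mask, stone)

    def test_excretory_phase_lumen_recovered(self, dilated_phantom):
        _, excretory, gt, spec = dilated_phantom
        lumen = gt.labels.labels == LABEL_LUMEN
        seed = tuple(np.argwhere(lumen)[len(np.argwhere(lumen)) // 2])
        mask = classical_threshold_segmentation(excretory, threshold_hu=150.0,
                                                seed_point=seed)
        assert dice(mask.mask, lumen) > 0.9
        parenchyma = gt.labels.labels == 1
        assert (mask.mask & parenchyma).sum() / parenchyma.sum() < 0.01

    def test_unreachable_threshold_errors(self):
        vol = CTVolume(np.full((4, 4, 4), 100.0), (1, 1, 1))
        with pytest.raises(SegmentationError, match="empty segmentation"):
            classical_threshold_segmentation(vol, threshold_hu=4000.0)

    def test_seed_below_threshold_errors(self):
        vol = CTVolume(np.full((4, 4, 4), 100.0), (1, 1, 1))
        vol.voxels[0, 0, 0] = 500.0
        with pytest.raises(SegmentationError, match="seed not in mask"):
            classical_threshold_segmentation(vol, threshold_hu=200.0,
                                             seed_point=(2, 2, 2))
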