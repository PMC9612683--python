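"""Agreement metrics and the synthetic contrast-vs-native cohort experiment.

``run_cohort`` re-creates, on phantoms, the study design the tool is built
for: each synthetic kidney is imaged in an excretory (contrast-filled) and a
native phase; the excretory phase is reconstructed with the classical global
threshold, the native phase with the footprint-seeded algorithm; both are
meshed and smoothed identically and their surface areas compared with a
normality-gated paired test (Shapiro–Wilk, then paired t or Wilcoxon
signed-rank).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import mesh as meshmod
from . import phantom as phmod
from . import segmentation as segmod
from .volume_io import LABEL_LUMEN, LABEL_STONE, world_to_voxel


class EvaluationError(ValueError):
    pass


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen–Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise EvaluationError("shape mismatch between masks")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass
class AreaComparison:
    test_used: str               # "t_test" | "mann_whitney" | "wilcoxon" | "no_variation"
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    shapiro_p: Optional[float]
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n: int
    paired: bool = False


def compare_areas(areas_a: Sequence[float], areas_b: Sequence[float],
                  alpha: float = 0.05, paired: bool = False) -> AreaComparison:
    """Compare two surface-area samples with a normality-gated test.

    The default is the classical two-sample workflow for group comparisons
    of model surface areas: Shapiro–Wilk assesses normality, then Student's
    t-test (normal) or Mann–Whitney (otherwise) is applied.  With
    ``paired=True`` the normality gate runs on the paired differences and
    the test becomes paired-t / Wilcoxon signed-rank — far more sensitive
    when the two samples come from the same geometries, which is worth
    keeping in mind when interpreting significance on synthetic cohorts
    (see the methods note).  Significance is declared at ``alpha``.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise EvaluationError("samples must be 1-D sequences")
    if paired and a.shape != b.shape:
        raise EvaluationError("paired samples must have equal length")
    if min(len(a), len(b)) < 3:
        raise EvaluationError("need at least 3 observations per sample")
    common = dict(alpha=alpha, mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                  mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                  n=min(len(a), len(b)), paired=paired)
    if paired:
        diffs = a - b
        if np.allclose(diffs, 0.0):
            return AreaComparison(test_used="no_variation", statistic=0.0, p_value=1.0,
                                  significant=False, shapiro_p=None, **common)
        _, sw_p = sps.shapiro(diffs)
        if sw_p > 0.05:
            stat, p = sps.ttest_rel(a, b)
            used = "t_test"
        else:
            stat, p = sps.wilcoxon(a, b)
            used = "wilcoxon"
    else:
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.allclose(a[0], b[0]):
            return AreaComparison(test_used="no_variation", statistic=0.0, p_value=1.0,
                                  significant=False, shapiro_p=None, **common)
        sw_p = min(sps.shapiro(a)[1], sps.shapiro(b)[1])
        if sw_p > 0.05:
            stat, p = sps.ttest_ind(a, b)
            used = "t_test"
        else:
            stat, p = sps.mannwhitneyu(a, b)
            used = "mann_whitney"
    return AreaComparison(test_used=used, statistic=float(stat), p_value=float(p),
                          significant=bool(p < alpha), shapiro_p=float(sw_p), **common)


@dataclass
class CohortResult:
    records: pd.DataFrame        # one row per phantom
    comparison: Optional[AreaComparison]          # two-sample (study design)
    comparison_paired: Optional[AreaComparison]   # paired variant, for reference
    n_success: int
    n_total: int

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_total

    def summary(self) -> dict:
        d = {"n_total": self.n_total, "n_success": self.n_success,
             "success_rate": self.success_rate}
        ok = self.records[self.records.reconstruction_success]
        if len(ok):
            d["mean_area_contrast_mm2"] = float(ok.area_contrast_mm2.mean())
            d["sd_area_contrast_mm2"] = float(ok.area_contrast_mm2.std(ddof=1)) if len(ok) > 1 else 0.0
            d["mean_area_native_mm2"] = float(ok.area_native_mm2.mean())
            d["sd_area_native_mm2"] = float(ok.area_native_mm2.std(ddof=1)) if len(ok) > 1 else 0.0
            d["mean_dice_native"] = float(ok.dice_native_vs_gt.mean())
            rel = (ok.area_contrast_mm2 - ok.area_native_mm2).abs() / ok.area_contrast_mm2
            d["mean_relative_area_difference"] = float(rel.mean())
        if self.comparison is not None:
            d["test_used"] = self.comparison.test_used
            d["statistic"] = self.comparison.statistic
            d["p_value"] = self.comparison.p_value
            d["significant"] = self.comparison.significant
        if self.comparison_paired is not None:
            d["paired_test_used"] = self.comparison_paired.test_used
            d["paired_p_value"] = self.comparison_paired.p_value
        return d


DICE_SUCCESS_THRESHOLD = 0.5   # a native model counts as reconstructed when
                               # it overlaps ground truth at least this much


def excretory_threshold_hu(spec: phmod.PhantomSpec) -> float:
    """Default contrast-phase threshold: halfway between the brightest
    parenchyma and the opacified lumen."""
    return (spec.parenchyma_hu_range[1] + spec.contrast_lumen_hu) / 2.0


def reconstruct_phantom(spec: phmod.PhantomSpec, n_footprints: int = 3,
                        cfg: segmod.SegmentationConfig | None = None) -> dict:
    """Run the full two-phase pipeline on one phantom; returns one record."""
    cfg = cfg or segmod.SegmentationConfig()
    native, excretory, gt = phmod.generate_phantom(spec)
    gt_lumen = np.isin(gt.labels.labels, (LABEL_LUMEN, LABEL_STONE))
    record = dict(seed=spec.seed, dilation_factor=spec.dilation_factor,
                  area_contrast_mm2=np.nan, area_native_mm2=np.nan,
                  dice_native_vs_gt=0.0, reconstruction_success=False)

    fps = phmod.auto_footprints(gt, k=n_footprints)
    seed_vox = tuple(int(round(v)) for v in world_to_voxel(
        native, (fps[0].slice_index * spec.spacing[0], *fps[0].center_mm)))

    contrast_mask = segmod.classical_threshold_segmentation(
        excretory, threshold_hu=excretory_threshold_hu(spec), seed_point=seed_vox, cfg=cfg)
    m = meshmod.extract_surface(contrast_mask, excretory)
    record["area_contrast_mm2"] = meshmod.surface_area(meshmod.smooth_mesh(m))

    try:
        native_mask = segmod.segment_native(native, fps, cfg)
    except segmod.SegmentationError:
        return record
    d = dice(native_mask.mask, gt_lumen)
    record["dice_native_vs_gt"] = d
    if d < DICE_SUCCESS_THRESHOLD:
        return record
    m = meshmod.extract_surface(native_mask, native)
    record["area_native_mm2"] = meshmod.surface_area(meshmod.smooth_mesh(m))
    record["reconstruction_success"] = True
    return record


def run_cohort(template: phmod.PhantomSpec, n: int, seed: int,
               n_footprints: int = 3,
               cfg: segmod.SegmentationConfig | None = None) -> CohortResult:
    """Generate ``n`` phantoms from a spec template (per-phantom seeds derived
    from ``seed``), reconstruct both phases of each, and compare paired
    surface areas over the successful reconstructions."""
    if n < 3:
        raise EvaluationError("need at least 3 phantoms")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    records = []
    for s in sub_seeds:
        spec = dataclasses.replace(template, seed=int(s))
        records.append(reconstruct_phantom(spec, n_footprints=n_footprints, cfg=cfg))
    df = pd.DataFrame.from_records(records)
    ok = df[df.reconstruction_success]
    comparison = comparison_paired = None
    if len(ok) >= 3:
        comparison = compare_areas(ok.area_contrast_mm2.to_numpy(),
                                   ok.area_native_mm2.to_numpy(), paired=False)
        comparison_paired = compare_areas(ok.area_contrast_mm2.to_numpy(),
                                          ok.area_native_mm2.to_numpy(), paired=True)
    return CohortResult(records=df, comparison=comparison,
                        comparison_paired=comparison_paired,
                        n_success=int(df.reconstruction_success.sum()), n_total=n)
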