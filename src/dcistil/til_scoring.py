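"""CPath TIL scoring.

The continuous biomarker is the average TIL density over the stromal
patches of the periductal microenvironment, multiplied by ten; the binary
biomarker dichotomises the score at a pre-defined threshold (the cohort
median by default), with ties going to the high category.

Two density definitions are supported. The default, ``area_fraction``,
takes the per-patch TIL density as lymphocyte-nucleus area over stromal
area, aggregated as a stroma-area-weighted mean so that sliver patches do
not dominate; ``count_per_mm2`` reports lymphocytes per mm^2 of ring
stroma instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ScoreConfig
from .exceptions import (
    InsufficientDataError,
    NoDcisError,
    NotEvaluableError,
)
from .microenvironment import Patch, PatchGrid, periductal_ring, tile_patches
from .tissue_segmentation import (
    CalibratedImage,
    NucleusRecord,
    StromaMask,
    classify_lymphocytes,
    deconvolve_stains,
    rgb_to_od,
    segment_nuclei,
    segment_stroma,
)


@dataclass(frozen=True)
class TILScoreResult:
    """Per-patient TIL score.

    ``raw_density`` is the mean TIL density (an area fraction in [0, 1]
    under the default mode); ``score`` is raw_density x 10, the scale on
    which thresholds are published. Both are None when not evaluable.
    """

    patient_id: str
    raw_density: float | None
    score: float | None
    radius_um: float
    n_patches: int
    evaluable: bool
    stroma_mm2: float = 0.0
    score_mode: str = "area_fraction"


@dataclass(frozen=True)
class TILCategoryAssignment:
    patient_id: str
    threshold: float
    category: str  # "low" or "high"


@dataclass
class TileAnalysis:
    """Segmentation intermediates reusable across ring radii."""

    image: CalibratedImage
    dcis_mask: np.ndarray
    nuclei: list[NucleusRecord]
    stroma: StromaMask


@dataclass(frozen=True)
class RadiusSensitivityResult:
    spearman_rho: float
    category_agreement: float
    radius_a_um: float
    radius_b_um: float
    scores_a: list[TILScoreResult] | None = None
    scores_b: list[TILScoreResult] | None = None


def patch_til_fraction(
    patch: Patch,
    nuclei_by_id: dict[int, NucleusRecord],
    mpp: float,
) -> float:
    """Lymphocyte-nucleus area over stromal area for one patch, in [0, 1]."""
    if patch.stroma_pixel_count <= 0:
        raise NotEvaluableError("patch has no stromal pixels")
    lymph_area = sum(nuclei_by_id[i].area for i in patch.lymphocyte_ids)
    stroma_area = patch.stroma_pixel_count * mpp**2
    return float(np.clip(lymph_area / stroma_area, 0.0, 1.0))


def cpath_til_score(
    grid: PatchGrid,
    nuclei: list[NucleusRecord],
    patient_id: str,
    radius_um: float,
    config: ScoreConfig | None = None,
) -> TILScoreResult:
    """Aggregate per-patch densities into the x10 CPath TIL score.

    The aggregation is a stroma-area-weighted mean of patch densities and
    is therefore invariant to patch enumeration order. Patients with less
    than ``config.min_stroma_mm2`` of ring stroma are flagged not
    evaluable and carry no score.
    """
    cfg = config or ScoreConfig()
    stroma_mm2 = grid.total_stroma_px * (grid.mpp / 1000.0) ** 2
    if not grid.patches or stroma_mm2 < cfg.min_stroma_mm2:
        return TILScoreResult(patient_id=patient_id, raw_density=None,
                              score=None, radius_um=radius_um, n_patches=0,
                              evaluable=False, stroma_mm2=stroma_mm2,
                              score_mode=cfg.score_mode)
    nuclei_by_id = {n.id: n for n in nuclei}
    weights = np.array([p.stroma_pixel_count for p in grid.patches], float)
    if cfg.score_mode == "area_fraction":
        fractions = np.array([
            patch_til_fraction(p, nuclei_by_id, grid.mpp)
            for p in grid.patches])
        raw = float(np.average(fractions, weights=weights))
        score = 10.0 * raw
    else:  # count_per_mm2
        n_lymph = sum(len(p.lymphocyte_ids) for p in grid.patches)
        raw = float(n_lymph / stroma_mm2)
        score = raw
    return TILScoreResult(patient_id=patient_id, raw_density=raw,
                          score=score, radius_um=radius_um,
                          n_patches=len(grid.patches), evaluable=True,
                          stroma_mm2=stroma_mm2, score_mode=cfg.score_mode)


def analyze_tile(
    image: CalibratedImage,
    dcis_mask: np.ndarray,
    config: ScoreConfig | None = None,
) -> TileAnalysis:
    """Run the radius-independent segmentation stages once."""
    cfg = config or ScoreConfig()
    od = rgb_to_od(image)
    stains = deconvolve_stains(od)
    nuclei = classify_lymphocytes(
        segment_nuclei(stains, image.mpp, cfg), cfg.lymphocyte_rule)
    stroma = segment_stroma(image, dcis_mask, nuclei, cfg)
    return TileAnalysis(image=image, dcis_mask=np.asarray(dcis_mask, bool),
                        nuclei=nuclei, stroma=stroma)


def score_from_analysis(
    analysis: TileAnalysis,
    patient_id: str,
    config: ScoreConfig | None = None,
    radius_um: float | None = None,
) -> TILScoreResult:
    """Score a pre-segmented tile at the given ring radius."""
    cfg = config or ScoreConfig()
    radius = radius_um if radius_um is not None else cfg.radius_um
    try:
        ring = periductal_ring(analysis.dcis_mask, radius, analysis.image.mpp)
    except NoDcisError:
        return TILScoreResult(patient_id=patient_id, raw_density=None,
                              score=None, radius_um=radius, n_patches=0,
                              evaluable=False, score_mode=cfg.score_mode)
    grid = tile_patches(ring, analysis.stroma, analysis.nuclei,
                        cfg.patch_size_um)
    return cpath_til_score(grid, analysis.nuclei, patient_id, radius, cfg)


def score_image(
    image: CalibratedImage,
    dcis_mask: np.ndarray,
    patient_id: str,
    config: ScoreConfig | None = None,
) -> TILScoreResult:
    """Full pipeline on one tile: segmentation, ring, patches, score."""
    return score_from_analysis(analyze_tile(image, dcis_mask, config),
                               patient_id, config)


def dichotomize(
    scores: list[TILScoreResult],
    threshold: float | None = None,
) -> tuple[list[TILCategoryAssignment], float]:
    """Assign TIL-low/TIL-high categories.

    When no threshold is given, the median of the evaluable scores is used
    (midpoint convention for even n). Scores >= threshold are high; only
    evaluable patients receive a category.
    """
    evaluable = [s for s in scores if s.evaluable]
    if threshold is None:
        if len(evaluable) < 2:
            raise NotEvaluableError(
                "need >= 2 evaluable scores to compute a median threshold")
        threshold = float(np.median([s.score for s in evaluable]))
    elif not evaluable:
        raise NotEvaluableError("no evaluable scores to categorise")
    assignments = [
        TILCategoryAssignment(
            patient_id=s.patient_id, threshold=threshold,
            category="high" if s.score >= threshold else "low")
        for s in evaluable
    ]
    return assignments, threshold


def radius_sensitivity(
    analyses: list[tuple[str, TileAnalysis]],
    radius_a_um: float = 250.0,
    radius_b_um: float = 200.0,
    config: ScoreConfig | None = None,
    keep_scores: bool = True,
) -> RadiusSensitivityResult:
    """Robustness of scores and categories to the ring radius.

    Recomputes the score at both radii for every patient evaluable at both,
    reports the Spearman rank correlation of the scores and the fraction of
    patients whose category (each radius dichotomised at its own median) is
    unchanged.
    """
    cfg = config or ScoreConfig()
    scores_a, scores_b = [], []
    for patient_id, analysis in analyses:
        scores_a.append(score_from_analysis(analysis, patient_id, cfg,
                                            radius_um=radius_a_um))
        scores_b.append(score_from_analysis(analysis, patient_id, cfg,
                                            radius_um=radius_b_um))
    both = [(a, b) for a, b in zip(scores_a, scores_b)
            if a.evaluable and b.evaluable]
    if len(both) < 3:
        raise InsufficientDataError(
            "radius sensitivity needs >= 3 patients evaluable at both radii")
    va = [a.score for a, _ in both]
    vb = [b.score for _, b in both]
    rho = float(stats.spearmanr(va, vb).statistic)
    cats_a, _ = dichotomize([a for a, _ in both], cfg.threshold)
    cats_b, _ = dichotomize([b for _, b in both], cfg.threshold)
    agree = float(np.mean([ca.category == cb.category
                           for ca, cb in zip(cats_a, cats_b)]))
    return RadiusSensitivityResult(
        spearman_rho=rho, category_agreement=agree,
        radius_a_um=radius_a_um, radius_b_um=radius_b_um,
        scores_a=scores_a if keep_scores else None,
        scores_b=scores_b if keep_scores else None)
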