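"""Classical H&E image analysis: stain unmixing, nuclei, lymphocytes, stroma.

The chain is fully deterministic: optical-density conversion, least-squares
deconvolution onto the Ruifrok-Johnston H&E stain vectors, Otsu thresholding
of the hematoxylin channel with a distance-transform watershed to split
touching nuclei, a morphometric lymphocyte rule, and an HSV tissue mask for
the stroma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .config import LymphocyteRule, ScoreConfig
from .exceptions import DegenerateStainError, DimensionMismatchError

#: Ruifrok-Johnston H&E optical-density stain vectors (rows: hematoxylin,
#: eosin), normalised to unit length.
HE_STAIN_VECTORS = np.array([
    [0.65, 0.70, 0.29],
    [0.07, 0.99, 0.11],
])
HE_STAIN_VECTORS = HE_STAIN_VECTORS / np.linalg.norm(
    HE_STAIN_VECTORS, axis=1, keepdims=True)

#: Hematoxylin OD floor below which a channel is treated as blank.
_BLANK_OD = 0.05
#: Noise floor added to the Otsu threshold so that near-blank channels do
#: not segment sensor noise.
_MIN_NUCLEUS_OD = 0.10


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit RGB histology tile with its microns-per-pixel scale."""

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("pixels must be an HxWx3 RGB array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class StainChannels:
    """Per-pixel hematoxylin and eosin optical densities."""

    hematoxylin_od: np.ndarray
    eosin_od: np.ndarray


@dataclass
class NucleusRecord:
    """One segmented nucleus with its morphometrics.

    ``area`` is in um^2; ``circularity`` is 4*pi*A/P^2, near 1 for a disk
    (values slightly above 1 can arise from perimeter discretisation and are
    clipped at 1.05); ``label`` is ``"lymphocyte"`` or ``"other"``.
    """

    id: int
    centroid: tuple[float, float]  # (row, col) in pixels
    area: float
    circularity: float
    mean_hematoxylin_od: float
    label: str = "unlabelled"


@dataclass(frozen=True)
class StromaMask:
    """Binary stromal-tissue mask with its pixel scale."""

    mask: np.ndarray
    mpp: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.mpp / 1000.0) ** 2


def rgb_to_od(image: CalibratedImage | np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to per-channel optical density.

    OD = -log10((I + 1) / 256): white maps to (near) zero absorbance and OD
    decreases monotonically with intensity.
    """
    pixels = image.pixels if isinstance(image, CalibratedImage) else image
    arr = np.asarray(pixels, dtype=np.float64)
    return -np.log10((arr + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped and rounded to 8-bit RGB."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def deconvolve_stains(
    od: np.ndarray,
    stain_vectors: np.ndarray = HE_STAIN_VECTORS,
) -> StainChannels:
    """Least-squares unmixing of pixel OD onto two stain vectors.

    Each pixel's 3-vector OD is decomposed onto the (unit-norm) stain
    vectors by the pseudoinverse; negative coefficients are physically
    meaningless and clipped to zero.
    """
    vectors = np.asarray(stain_vectors, dtype=np.float64)
    if vectors.shape != (2, 3):
        raise DegenerateStainError("expected two 3-component stain vectors")
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    if np.linalg.cond(vectors @ vectors.T) > 1e6:
        raise DegenerateStainError("stain vectors are near-collinear")
    pinv = np.linalg.pinv(vectors)  # 3x2
    coeffs = np.asarray(od, dtype=np.float64) @ pinv
    coeffs = np.clip(coeffs, 0.0, None)
    return StainChannels(hematoxylin_od=coeffs[..., 0], eosin_od=coeffs[..., 1])


def segment_nuclei(
    stains: StainChannels,
    mpp: float,
    config: ScoreConfig | None = None,
) -> list[NucleusRecord]:
    """Segment nuclei from the hematoxylin channel.

    Otsu threshold (with a small OD floor against noise), morphological
    opening with a 1 um disk, then a distance-transform watershed seeded at
    local maxima at least 3 um apart to split touching nuclei. Components
    smaller than 10 um^2 are discarded. A blank hematoxylin channel yields
    an empty list, not an error.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    cfg = config or ScoreConfig()
    hema = np.asarray(stains.hematoxylin_od, dtype=np.float64)
    if hema.max() < _BLANK_OD:
        return []
    thr = max(float(threshold_otsu(hema)), _MIN_NUCLEUS_OD)
    binary = hema > thr
    open_radius = max(1, int(round(cfg.opening_radius_um / mpp)))
    binary = morphology.opening(binary, morphology.disk(open_radius))
    if not binary.any():
        return []

    dist = ndimage.distance_transform_edt(binary)
    min_sep = max(1, int(round(cfg.watershed_min_separation_um / mpp)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=binary,
                           exclude_border=False)
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=binary)

    min_area_px = cfg.min_nucleus_area_um2 / mpp**2
    records: list[NucleusRecord] = []
    next_id = 0
    for region in measure.regionprops(labels, intensity_image=hema):
        if region.area < min_area_px:
            continue
        perimeter = region.perimeter_crofton
        if perimeter <= 0:
            continue
        circ = min(4.0 * np.pi * region.area / perimeter**2, 1.05)
        records.append(NucleusRecord(
            id=next_id,
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            area=float(region.area) * mpp**2,
            circularity=float(circ),
            mean_hematoxylin_od=float(region.intensity_mean),
        ))
        next_id += 1
    return records


def classify_lymphocytes(
    nuclei: list[NucleusRecord],
    rule: LymphocyteRule | None = None,
) -> list[NucleusRecord]:
    """Label each nucleus lymphocyte/other by the morphometric rule.

    The rule is a pure function of the record's fields; all bounds are
    inclusive, so a nucleus sitting exactly on a threshold is a lymphocyte.
    Returns new records, leaving the input unmodified.
    """
    rule = rule or LymphocyteRule()
    out = []
    for n in nuclei:
        is_til = (rule.area_min_um2 <= n.area <= rule.area_max_um2
                  and n.circularity >= rule.min_circularity
                  and n.mean_hematoxylin_od >= rule.min_hematoxylin_od)
        out.append(replace(n, label="lymphocyte" if is_til else "other"))
    return out


def tissue_mask(image: CalibratedImage, config: ScoreConfig | None = None) -> np.ndarray:
    """Tissue-vs-glass mask: saturated, non-bright pixels in HSV space."""
    cfg = config or ScoreConfig()
    hsv = color.rgb2hsv(image.pixels)
    return (hsv[..., 1] >= cfg.tissue_saturation_min) & (
        hsv[..., 2] <= cfg.tissue_value_max)


def segment_stroma(
    image: CalibratedImage,
    dcis_mask: np.ndarray,
    nuclei: list[NucleusRecord],
    config: ScoreConfig | None = None,
) -> StromaMask:
    """Stromal tissue: tissue minus the annotated DCIS and its epithelium.

    Non-lymphocyte nuclei whose centroid lies inside the annotation are
    dilated by 2 um and removed, so epithelial cells spilling over the
    annotation boundary do not count as stroma.
    """
    cfg = config or ScoreConfig()
    dcis_mask = np.asarray(dcis_mask, dtype=bool)
    if dcis_mask.shape != image.shape:
        raise DimensionMismatchError(
            f"dcis_mask shape {dcis_mask.shape} != image shape {image.shape}")
    stroma = tissue_mask(image, cfg) & ~dcis_mask

    dilate_px = max(1, int(round(2.0 / image.mpp)))
    epithelium = np.zeros(image.shape, dtype=bool)
    h, w = image.shape
    for n in nuclei:
        if n.label == "lymphocyte":
            continue
        r, c = int(round(n.centroid[0])), int(round(n.centroid[1]))
        if 0 <= r < h and 0 <= c < w and dcis_mask[r, c]:
            radius_px = np.sqrt(n.area / np.pi) / image.mpp + dilate_px
            rr, cc = np.ogrid[:h, :w]
            within = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px**2
            epithelium |= within
    return StromaMask(mask=stroma & ~epithelium, mpp=image.mpp)
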