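"""Periductal microenvironment geometry.

Rasterises duct annotations, builds the periductal ring (all stroma within a
fixed radius of the DCIS boundary, 250 um by default) with a Euclidean
distance transform, and partitions the ring into a fixed stromal patch grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

from .exceptions import (
    DegeneratePatchError,
    DimensionMismatchError,
    InvalidAnnotationError,
    NoDcisError,
)
from .tissue_segmentation import NucleusRecord, StromaMask


@dataclass(frozen=True)
class AnnotationSet:
    """Duct annotation polygons, in (x=col, y=row) vertex order.

    ``units`` says whether vertex coordinates are in pixels or microns.
    """

    polygons: list
    units: str = "px"  # "px" or "um"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.units not in ("px", "um"):
            raise InvalidAnnotationError(f"unknown units {self.units!r}")
        for poly in self.polygons:
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise InvalidAnnotationError(
                    "each polygon needs >= 3 (x, y) vertices")
            if not ShapelyPolygon(arr).is_simple:
                raise InvalidAnnotationError("self-intersecting polygon")

    @classmethod
    def from_geojson(cls, source: str | Path | dict, units: str = "px",
                     source_id: str = "") -> "AnnotationSet":
        """Read duct polygons from a GeoJSON FeatureCollection."""
        if isinstance(source, (str, Path)):
            data = json.loads(Path(source).read_text())
            source_id = source_id or Path(source).stem
        else:
            data = source
        polygons = []
        for feature in data.get("features", []):
            geom = feature.get("geometry", {})
            if geom.get("type") == "Polygon":
                rings = [geom["coordinates"][0]]
            elif geom.get("type") == "MultiPolygon":
                rings = [part[0] for part in geom["coordinates"]]
            else:
                continue
            polygons.extend(np.asarray(r, dtype=float) for r in rings)
        return cls(polygons=polygons, units=units, source_id=source_id)

    def to_geojson(self, classification: str = "DCIS") -> dict:
        features = []
        for poly in self.polygons:
            coords = np.asarray(poly, dtype=float)
            if not np.array_equal(coords[0], coords[-1]):
                coords = np.vstack([coords, coords[:1]])
            features.append({
                "type": "Feature",
                "geometry": {"type": "Polygon",
                             "coordinates": [coords.tolist()]},
                "properties": {"classification": classification},
            })
        return {"type": "FeatureCollection", "features": features}


@dataclass(frozen=True)
class RingMask:
    """Periductal ring: pixels within ``radius_um`` of the DCIS boundary."""

    mask: np.ndarray
    radius_um: float
    mpp: float


@dataclass(frozen=True)
class Patch:
    """One half-open grid box [r0, r1) x [c0, c1) with its ring-stroma
    pixel count and the ids of lymphocytes whose centroid falls inside."""

    patch_id: int
    r0: int
    c0: int
    r1: int
    c1: int
    stroma_pixel_count: int
    lymphocyte_ids: tuple[int, ...] = ()


@dataclass(frozen=True)
class PatchGrid:
    patch_size_um: float
    mpp: float
    patches: list[Patch] = field(default_factory=list)

    @property
    def total_stroma_px(self) -> int:
        return int(sum(p.stroma_pixel_count for p in self.patches))


def rasterize_annotations(
    ann: AnnotationSet,
    shape: tuple[int, int],
    mpp: float,
) -> np.ndarray:
    """Rasterise annotation polygons to a binary mask.

    A pixel is set iff its centre lies strictly inside any polygon
    (even-odd rule); pixel (r, c) covers the unit square [c, c+1) x
    [r, r+1), so its centre sits at (c+0.5, r+0.5). Overlapping polygons
    combine by union.
    """
    mask = np.zeros(shape, dtype=bool)
    scale = 1.0 / mpp if ann.units == "um" else 1.0
    h, w = shape
    for poly in ann.polygons:
        xy = np.asarray(poly, dtype=float) * scale
        geom = ShapelyPolygon(xy)
        minx, miny, maxx, maxy = geom.bounds
        c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, w)
        r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, cols + 0.5, rows + 0.5)
        mask[r0:r1, c0:c1] |= inside
    return mask


def periductal_ring(
    dcis_mask: np.ndarray,
    radius_um: float,
    mpp: float,
) -> RingMask:
    """Ring of pixels outside the DCIS within ``radius_um`` of its boundary.

    Distances are Euclidean (distance transform of the mask complement);
    inclusion is half-open, 0 < d <= r, so DCIS pixels themselves are never
    part of the ring. Rings of multiple ducts merge by union.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    dcis_mask = np.asarray(dcis_mask, dtype=bool)
    if not dcis_mask.any():
        raise NoDcisError("annotation mask is empty; patient not evaluable")
    dist = ndimage.distance_transform_edt(~dcis_mask)
    ring = (~dcis_mask) & (dist <= radius_um / mpp)
    return RingMask(mask=ring, radius_um=radius_um, mpp=mpp)


def tile_patches(
    ring: RingMask,
    stroma: StromaMask,
    nuclei: list[NucleusRecord],
    patch_size_um: float,
) -> PatchGrid:
    """Partition ring-stroma into a fixed square grid anchored at the origin.

    Boxes are half-open, so every pixel (and every lymphocyte centroid)
    belongs to exactly one patch; patches with no ring-stroma pixel are
    dropped.
    """
    if ring.mask.shape != stroma.mask.shape:
        raise DimensionMismatchError("ring and stroma masks differ in shape")
    mpp = ring.mpp
    if patch_size_um < 2 * mpp:
        raise DegeneratePatchError(
            f"patch_size_um={patch_size_um} below 2*mpp={2 * mpp}")
    size_px = max(1, int(round(patch_size_um / mpp)))
    ring_stroma = ring.mask & stroma.mask
    h, w = ring_stroma.shape

    lymph_by_box: dict[tuple[int, int], list[int]] = {}
    for n in nuclei:
        if n.label != "lymphocyte":
            continue
        r, c = int(round(n.centroid[0])), int(round(n.centroid[1]))
        if not (0 <= r < h and 0 <= c < w) or not ring_stroma[r, c]:
            continue
        key = (int(n.centroid[0] // size_px), int(n.centroid[1] // size_px))
        lymph_by_box.setdefault(key, []).append(n.id)

    patches: list[Patch] = []
    pid = 0
    for br in range(0, h, size_px):
        for bc in range(0, w, size_px):
            r1, c1 = min(br + size_px, h), min(bc + size_px, w)
            count = int(ring_stroma[br:r1, bc:c1].sum())
            if count == 0:
                continue
            ids = tuple(lymph_by_box.get((br // size_px, bc // size_px), ()))
            patches.append(Patch(patch_id=pid, r0=br, c0=bc, r1=r1, c1=c1,
                                 stroma_pixel_count=count,
                                 lymphocyte_ids=ids))
            pid += 1
    return PatchGrid(patch_size_um=patch_size_um, mpp=mpp, patches=patches)
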