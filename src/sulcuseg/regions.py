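"""Connected-component labeling and the structure-selection chain.

After binarization the crop typically contains the groove plus residual
bright speckle.  The selection chain identifies every 8-connected
component, discards small ones, keeps those whose centroid lies inside
the clinician's ROI polygon, picks the largest survivor, clips it to the
rasterized ROI, and transposes the result back to the original frame.

Geometry helpers (`points_in_polygon`, `rasterize_polygon`) implement a
boundary-inclusive even-odd test so that centroids and pixels lying
exactly on the user's stroke count as selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.measure import label as _sk_label
from skimage.measure import regionprops as _sk_regionprops

from .binarize import BinaryMask
from .errors import BoundsError, EmptySelectionError, FrameError, GeometryError
from .preprocess import CropWindow


@dataclass(frozen=True)
class ROIPolygon:
    """Clinician-drawn groove outline: ordered (x, y) vertices, original frame.

    The polygon is implicitly closed (last vertex connects to the first).
    """

    vertices: tuple
    groove_label: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise GeometryError("ROI polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def to_crop_frame(self, window: CropWindow) -> "ROIPolygon":
        shifted = [(x - window.col_min, y - window.row_min) for x, y in self.vertices]
        return ROIPolygon(shifted, groove_label=self.groove_label)


@dataclass(frozen=True)
class RegionRecord:
    label: int
    area: int
    centroid: tuple  # (row, col)
    bbox: CropWindow


@dataclass
class LabeledRegions:
    """Integer label image (0 = background) plus per-region records."""

    label_image: np.ndarray
    records: list

    @property
    def nregions(self) -> int:
        return len(self.records)

    def get(self, lab: int) -> RegionRecord:
        for rec in self.records:
            if rec.label == lab:
                return rec
        raise KeyError(lab)


# ---------------------------------------------------------------------------
# polygon geometry


def points_in_polygon(points: np.ndarray, vertices: Sequence) -> np.ndarray:
    """Boundary-inclusive even-odd point-in-polygon test.

    ``points`` is (n, 2) of (x, y); ``vertices`` the closed polygon (last
    vertex implicitly joined to the first).  Points on an edge or vertex
    count as inside.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    verts = np.asarray(vertices, dtype=float)
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-segment check: zero cross product and within the bounding box
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (np.minimum(x1, x2) - 1e-9 <= px) & (px <= np.maximum(x1, x2) + 1e-9)
            & (np.minimum(y1, y2) - 1e-9 <= py) & (py <= np.maximum(y1, y2) + 1e-9)
        )
        on_edge |= (np.abs(cross) <= 1e-9 * max(1.0, abs(x2 - x1) + abs(y2 - y1))) & within
        if y1 != y2:
            # half-open rule on y avoids double-counting shared vertices
            straddle = (y1 > py) != (y2 > py)
            xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= straddle & (px < xi)
    return inside | on_edge


def rasterize_polygon(vertices: Sequence, shape: tuple[int, int]) -> np.ndarray:
    """Boundary-inclusive rasterization of a polygon onto a pixel grid.

    A pixel belongs to the mask iff its center (integer x, y) lies inside
    or on the polygon.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    return points_in_polygon(pts, vertices).reshape(h, w)


def rasterize_roi(roi: ROIPolygon, shape: tuple[int, int],
                  window: Optional[CropWindow] = None) -> BinaryMask:
    """Rasterize an original-frame ROI, optionally into a crop window."""
    poly = roi.to_crop_frame(window) if window is not None else roi
    grid = rasterize_polygon(poly.as_array(), shape)
    frame = "crop" if window is not None else "original"
    return BinaryMask(grid, frame=frame, window=window)


# ---------------------------------------------------------------------------
# labeling and per-region features


def label_components(mask: BinaryMask, connectivity: int = 2) -> LabeledRegions:
    """Label connected components (default 8-neighborhood).

    Labels 1..n are assigned in raster-scan discovery order (order of each
    component's first pixel), independent of the backend's numbering.
    """
    lab = _sk_label(mask.grid.astype(int), connectivity=connectivity)
    if lab.max() > 0:
        flat = lab.ravel()
        order = np.unique(flat[flat > 0], return_index=True)
        remap = np.zeros(lab.max() + 1, dtype=lab.dtype)
        remap[order[0][np.argsort(order[1])]] = np.arange(1, len(order[0]) + 1)
        lab = remap[lab]
    lr = LabeledRegions(label_image=lab, records=[])
    lr.records = region_features(lr)
    return lr


def region_features(lr: LabeledRegions) -> list:
    """Area, centroid and bounding window for every labeled region."""
    records = []
    for p in _sk_regionprops(lr.label_image):
        r0, c0, r1, c1 = p.bbox
        records.append(
            RegionRecord(
                label=int(p.label),
                area=int(p.area),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                bbox=CropWindow(r0, r1, c0, c1),
            )
        )
    return records


# ---------------------------------------------------------------------------
# the selection chain


def filter_by_area(lr: LabeledRegions, min_area: int = 10) -> LabeledRegions:
    """Drop regions smaller than ``min_area`` pixels; labels keep their ids."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    keep = {rec.label for rec in lr.records if rec.area >= min_area}
    lab = np.where(np.isin(lr.label_image, list(keep)), lr.label_image, 0)
    return LabeledRegions(
        label_image=lab, records=[r for r in lr.records if r.label in keep]
    )


def filter_by_centroid_in_roi(lr: LabeledRegions, roi: ROIPolygon,
                              window: CropWindow) -> LabeledRegions:
    """Keep regions whose centroid falls inside the crop-frame ROI polygon."""
    poly = roi.to_crop_frame(window).as_array()
    if lr.nregions == 0:
        return LabeledRegions(label_image=lr.label_image.copy(), records=[])
    pts = np.array([(rec.centroid[1], rec.centroid[0]) for rec in lr.records])
    inside = points_in_polygon(pts, poly)
    keep = {rec.label for rec, ok in zip(lr.records, inside) if ok}
    lab = np.where(np.isin(lr.label_image, list(keep)), lr.label_image, 0)
    return LabeledRegions(
        label_image=lab, records=[r for r in lr.records if r.label in keep]
    )


def select_largest(lr: LabeledRegions, window: Optional[CropWindow] = None) -> BinaryMask:
    """Binary mask of the single maximum-area region (ties: lowest label)."""
    if lr.nregions == 0:
        raise EmptySelectionError("no region survived the selection filters")
    best = max(lr.records, key=lambda rec: (rec.area, -rec.label))
    return BinaryMask(lr.label_image == best.label, frame="crop", window=window)


def intersect_with_roi(mask: BinaryMask, roi: ROIPolygon, window: CropWindow) -> BinaryMask:
    """Clip a crop-frame mask to the rasterized ROI (elementwise product)."""
    if mask.frame != "crop":
        raise FrameError("intersect_with_roi expects a crop-frame mask")
    roi_mask = rasterize_roi(roi, mask.grid.shape, window=window)
    return BinaryMask(mask.grid & roi_mask.grid, frame="crop", window=window)


def to_original_frame(obj, window: CropWindow, image_shape: tuple[int, int]):
    """Transpose a crop-frame mask or (x, y) vertex list to the original frame.

    Masks are re-embedded into a full-size zero grid; vertex coordinates are
    shifted by the crop offset.
    """
    if isinstance(obj, BinaryMask):
        if obj.frame != "crop":
            raise FrameError("mask is already in the original frame")
        h, w = image_shape
        if window.row_min + obj.grid.shape[0] > h or window.col_min + obj.grid.shape[1] > w:
            raise BoundsError("crop window does not fit inside the original image")
        full = np.zeros(image_shape, dtype=bool)
        full[window.row_min:window.row_min + obj.grid.shape[0],
             window.col_min:window.col_min + obj.grid.shape[1]] = obj.grid
        return BinaryMask(full, frame="original", window=None)
    verts = np.asarray(obj, dtype=float)
    shifted = verts + np.array([window.col_min, window.row_min], dtype=float)
    h, w = image_shape
    # pixel-edge contour vertices sit half a pixel beyond the outermost center
    if (shifted[:, 0] < -0.5).any() or (shifted[:, 0] > w - 0.5).any() \
            or (shifted[:, 1] < -0.5).any() or (shifted[:, 1] > h - 0.5).any():
        raise BoundsError("transposed vertex falls outside the original image")
    return shifted
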