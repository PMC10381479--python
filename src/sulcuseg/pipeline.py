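"""End-to-end per-groove segmentation: the three interchangeable methods.

Each method shares the same scaffold — crop the ROI bounding window,
stretch contrast, binarize (by local thresholding or by evolving a
MorphACWE front), then run the structure-selection chain and trace the
contour — and differs only in how the binary candidate mask is produced:

* ``threshold``          crop -> min-max rescale -> local threshold -> closing
* ``sigmoid_threshold``  sigmoid correction of the full frame first, then
                         the same chain (the correction is global so that
                         the crop statistics are not biased by the window)
* ``snake``              crop -> min-max rescale -> MorphACWE -> auto-invert

A groove for which no region survives the selection chain is reported as
``failed`` with the clinician's ROI echoed back as the contour, so the
outline remains editable.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes

from .binarize import BinaryMask, ThresholdParams, closing, local_threshold
from .contour import Contour, mask_to_contour
from .errors import EmptySelectionError, ParameterError, SchemaError, TopologyError
from .imgio import UltrasoundImage
from .preprocess import SigmoidParams, crop, rescale_minmax, sigmoid_correction
from .regions import (
    ROIPolygon,
    filter_by_area,
    filter_by_centroid_in_roi,
    intersect_with_roi,
    label_components,
    rasterize_roi,
    select_largest,
    to_original_frame,
)
from .snake import SnakeParams, auto_invert, morph_acwe

METHODS = ("threshold", "sigmoid_threshold", "snake")


@dataclass
class MethodConfig:
    """Complete configuration for one segmentation run."""

    method: str = "threshold"
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    closing_radius: int = 2
    min_area: int = 10
    connectivity: int = 2
    snake: SnakeParams = field(default_factory=SnakeParams)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "MethodConfig":
        """Build from flat dotted keys (e.g. ``threshold.block_size``)."""
        nested: dict = {}
        for key, value in mapping.items():
            parts = key.split(".")
            cur = nested
            for p in parts[:-1]:
                cur = cur.setdefault(p, {})
            cur[parts[-1]] = value
        kwargs: dict = {}
        if "method" in nested:
            kwargs["method"] = nested["method"]
        if "sigmoid" in nested:
            kwargs["sigmoid"] = SigmoidParams(**nested["sigmoid"])
        if "threshold" in nested:
            kwargs["threshold"] = ThresholdParams(**nested["threshold"])
        if "snake" in nested:
            kwargs["snake"] = SnakeParams(**nested["snake"])
        if "closing" in nested and "radius" in nested["closing"]:
            kwargs["closing_radius"] = int(nested["closing"]["radius"])
        if "regions" in nested:
            if "min_area" in nested["regions"]:
                kwargs["min_area"] = int(nested["regions"]["min_area"])
            if "connectivity" in nested["regions"]:
                kwargs["connectivity"] = int(nested["regions"]["connectivity"])
        return cls(**kwargs)


@dataclass
class SegmentationResult:
    groove_label: str
    contour: Contour
    mask: BinaryMask  # original frame
    method: str
    config_used: MethodConfig
    elapsed: float
    status: str  # "ok" | "failed"


def _candidate_mask(img: UltrasoundImage, roi: ROIPolygon, cfg: MethodConfig):
    """Produce the method-specific binary candidate mask in the crop frame."""
    if cfg.method == "sigmoid_threshold":
        corrected = sigmoid_correction(img.pixels, cfg.sigmoid)
        grid, window = crop(corrected, roi)
    else:
        grid, window = crop(img, roi)
    grid = rescale_minmax(grid)
    if cfg.method == "snake":
        init = None
        if cfg.snake.init == "roi":
            init = rasterize_roi(roi, grid.shape, window=window).grid
        mask = morph_acwe(grid, cfg.snake, init_level_set=init, window=window)
        mask = auto_invert(mask)
    else:
        mask = local_threshold(grid, cfg.threshold, window=window)
        mask = closing(mask, cfg.closing_radius)
    # enclosed pepper holes are binarization artifacts; filling them keeps
    # every candidate region simply connected, as the outline polygon requires
    filled = binary_fill_holes(mask.grid)
    return BinaryMask(filled, frame="crop", window=window), window


def segment_groove(img: UltrasoundImage, roi: ROIPolygon,
                   cfg: Optional[MethodConfig] = None) -> SegmentationResult:
    """Run one method end-to-end for a single groove ROI."""
    cfg = cfg or MethodConfig()
    t0 = time.perf_counter()
    mask, window = _candidate_mask(img, roi, cfg)

    try:
        lr = label_components(mask, connectivity=cfg.connectivity)
        lr = filter_by_area(lr, cfg.min_area)
        lr = filter_by_centroid_in_roi(lr, roi, window)
        selected = select_largest(lr, window=window)
        selected = intersect_with_roi(selected, roi, window)
        if not selected.grid.any():
            raise EmptySelectionError("selected region lies entirely outside the ROI")
        # clipping can sever a limb that was connected only outside the ROI;
        # keep the largest remaining piece so the outline stays one component
        selected = select_largest(
            label_components(selected, connectivity=cfg.connectivity), window=window
        )
        full_mask = to_original_frame(selected, window, img.pixels.shape)
        contour_obj = _outline(full_mask, roi.groove_label, cfg.method)
    except (EmptySelectionError, TopologyError):
        elapsed = time.perf_counter() - t0
        empty = BinaryMask(
            np.zeros(img.pixels.shape, dtype=bool), frame="original"
        )
        echo = Contour(roi.vertices, groove_label=roi.groove_label, method=cfg.method)
        return SegmentationResult(
            groove_label=roi.groove_label, contour=echo, mask=empty,
            method=cfg.method, config_used=cfg,
            elapsed=elapsed, status="failed",
        )

    elapsed = time.perf_counter() - t0
    return SegmentationResult(
        groove_label=roi.groove_label, contour=contour_obj, mask=full_mask,
        method=cfg.method, config_used=cfg, elapsed=elapsed, status="ok",
    )


def _outline(full_mask: BinaryMask, groove_label: str, method: str) -> Contour:
    return mask_to_contour(full_mask, groove_label=groove_label, method=method)


def segment_all(img: UltrasoundImage, rois: Sequence[ROIPolygon],
                cfg: Optional[MethodConfig] = None) -> list:
    """Segment every groove independently; failures stay isolated per ROI."""
    labels = [roi.groove_label for roi in rois]
    if len(set(labels)) != len(labels):
        raise SchemaError("groove labels must be unique")
    return [segment_groove(img, roi, cfg) for roi in rois]
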