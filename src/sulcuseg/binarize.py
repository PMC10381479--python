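"""Local adaptive thresholding and morphological closing.

B-mode speckle makes a single global threshold unreliable, so each pixel
is compared against a statistic of its own neighborhood (arithmetic or
Gaussian-weighted mean over a ``block_size`` window).  The binary mask is
then closed (dilation followed by erosion with a disk footprint) to bridge
small dark gaps inside the bright groove.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_local
from skimage.morphology import closing as _sk_closing
from skimage.morphology import disk

from .errors import FrameError, ParameterError
from .preprocess import CropWindow


@dataclass
class BinaryMask:
    """A {0,1} grid tagged with its coordinate frame.

    ``frame`` is "crop" (grid indexed relative to a CropWindow) or
    "original" (full-frame).  ``window`` records the crop offset while in
    the crop frame.
    """

    grid: np.ndarray
    frame: str = "crop"
    window: Optional[CropWindow] = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.grid = grid.astype(bool)
        if self.frame not in ("crop", "original"):
            raise FrameError(f"unknown frame {self.frame!r}")

    @property
    def foreground_fraction(self) -> float:
        return float(self.grid.mean()) if self.grid.size else 0.0

    def count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ThresholdParams:
    """Local-threshold configuration.

    block_size: odd neighborhood side in pixels.
    method: "mean" (arithmetic) or "gaussian" (Gaussian-weighted mean,
        sigma = param, defaulting to (block_size - 1) / 6).
    offset: subtracted from the local statistic before comparison; a
        negative offset therefore demands a margin above the local mean,
        which keeps zero-mean speckle fluctuations out of the mask.
    """

    block_size: int = 27
    method: str = "gaussian"
    param: Optional[float] = None
    offset: float = -0.15

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ParameterError("block_size must be an odd integer >= 3")
        if self.method not in ("mean", "gaussian"):
            raise ParameterError(f"unknown threshold method {self.method!r}")


def local_threshold(grid: np.ndarray, params: ThresholdParams = ThresholdParams(),
                    window: Optional[CropWindow] = None) -> BinaryMask:
    """Binarize: pixel -> 1 iff intensity > (local statistic - offset).

    Border neighborhoods are completed by symmetric reflection (the edge
    pixel itself is mirrored outward).  Ties map to background, so a
    uniform field yields an empty mask.
    """
    grid = np.asarray(grid, dtype=float)
    thresh = threshold_local(
        grid,
        block_size=params.block_size,
        method=params.method,
        offset=params.offset,
        param=params.param,
        mode="reflect",
    )
    return BinaryMask(grid > thresh, frame="crop", window=window)


def closing(mask: BinaryMask, footprint_radius: int = 2) -> BinaryMask:
    """Morphological closing with a disk footprint.

    Dilation (neighborhood maximum) enlarges the bright groove fragments
    enough to bridge pepper gaps; the following erosion (neighborhood
    minimum) restores the outer extent.
    """
    if footprint_radius < 1:
        raise ParameterError("closing footprint radius must be >= 1")
    closed = _sk_closing(mask.grid, disk(footprint_radius))
    return BinaryMask(closed, frame=mask.frame, window=mask.window)
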