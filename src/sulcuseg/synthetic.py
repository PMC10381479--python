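"""Seeded ultrasound-like phantoms with known ground truth.

Real cranial ultrasound shows sulci as bright curvilinear structures on
darker tissue corrupted by multiplicative speckle.  The phantom emulates
exactly those features: each groove is a thickened smooth curve through a
few random control points, composited over a dark background, blurred by
a Gaussian point-spread approximation, and multiplied by log-normal
speckle.  The pre-noise groove support is the ground-truth mask; the ROI
polygon — standing in for the clinician's outline — is the convex hull of
the truth mask dilated by a margin, optionally jittered to emulate a
sloppy manual stroke.

Grooves are laid out in separate horizontal bands so their truth masks
are pairwise disjoint by construction.  Everything is a deterministic
function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from skimage.morphology import dilation, disk

from .binarize import BinaryMask
from .errors import ParameterError
from .imgio import UltrasoundImage
from .regions import ROIPolygon


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic frame.

    Intensities are in [0, 1]; speckle_sigma is the log-scale of the
    multiplicative noise (pixel × exp(N(0, speckle_sigma²)));
    blur_sigma approximates the point-spread function in pixels;
    roi_margin is the dilation (pixels) of the truth mask used to build
    the surrounding ROI; roi_jitter adds zero-mean Gaussian offsets to the
    ROI vertices to emulate an imprecise manual outline.
    """

    height: int = 256
    width: int = 256
    n_grooves: int = 3
    min_control_points: int = 3
    max_control_points: int = 5
    thickness: int = 3
    groove_intensity: float = 0.85
    background_intensity: float = 0.15
    speckle_sigma: float = 0.25
    blur_sigma: float = 1.0
    roi_margin: int = 8
    roi_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_grooves < 1:
            raise ParameterError("n_grooves must be >= 1")
        if self.groove_intensity <= self.background_intensity:
            raise ParameterError(
                "groove intensity must exceed background intensity "
                "(the front must separate a brighter interior)"
            )
        if self.speckle_sigma < 0 or self.blur_sigma < 0:
            raise ParameterError("noise scales must be >= 0")
        if not (3 <= self.min_control_points <= self.max_control_points <= 5):
            raise ParameterError("control points per curve must be within 3..5")
        if self.thickness < 1 or self.roi_margin < 1:
            raise ParameterError("thickness and roi_margin must be >= 1")


def _groove_mask(spec: PhantomSpec, rng: np.random.Generator,
                 band: tuple[float, float]) -> np.ndarray:
    """Rasterize one thickened smooth curve confined to a horizontal band."""
    lo, hi = band
    k = int(rng.integers(spec.min_control_points, spec.max_control_points + 1))
    x_margin = max(8, spec.width // 16)
    xs = np.linspace(x_margin, spec.width - 1 - x_margin, k)
    xs = xs + rng.uniform(-0.25, 0.25, size=k) * np.diff(xs, prepend=xs[0]).mean()
    xs[0], xs[-1] = x_margin, spec.width - 1 - x_margin
    xs = np.sort(xs)
    ys = rng.uniform(lo, hi, size=k)
    curve = CubicSpline(xs, ys)

    dense_x = np.arange(xs[0], xs[-1] + 0.25, 0.25)
    dense_y = np.clip(curve(dense_x), lo, hi)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    rr = np.round(dense_y).astype(int)
    cc = np.round(dense_x).astype(int)
    mask[rr, cc] = True
    return dilation(mask, disk(spec.thickness // 2))


def _roi_from_truth(truth: np.ndarray, spec: PhantomSpec,
                    rng: np.random.Generator, label: str) -> ROIPolygon:
    dilated = dilation(truth, disk(spec.roi_margin))
    rows, cols = np.nonzero(dilated)
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    if spec.roi_jitter > 0:
        verts = verts + rng.normal(0.0, spec.roi_jitter, size=verts.shape)
    verts[:, 0] = np.clip(verts[:, 0], 0, spec.width - 1)
    verts[:, 1] = np.clip(verts[:, 1], 0, spec.height - 1)
    return ROIPolygon(verts, groove_label=label)


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build one phantom frame and its per-groove (truth mask, ROI) pairs.

    Returns ``(UltrasoundImage, [(BinaryMask, ROIPolygon), ...])``; the
    truth masks record the pre-blur, pre-noise groove support.
    """
    rng = np.random.default_rng(spec.seed)
    band_h = spec.height / spec.n_grooves
    pairs = []
    truths = []
    for i in range(spec.n_grooves):
        # confine each curve to the middle half of its band so that ROIs
        # dilated by roi_margin cannot reach a neighboring groove
        center = (i + 0.5) * band_h
        lo = center - band_h / 4
        hi = center + band_h / 4
        truth = _groove_mask(spec, rng, (lo, hi))
        truths.append(truth)
        roi = _roi_from_truth(truth, spec, rng, label=f"groove{i + 1}")
        pairs.append((BinaryMask(truth, frame="original"), roi))

    canvas = np.full((spec.height, spec.width), spec.background_intensity)
    canvas[np.any(truths, axis=0)] = spec.groove_intensity
    if spec.blur_sigma > 0:
        canvas = gaussian_filter(canvas, spec.blur_sigma)
    if spec.speckle_sigma > 0:
        canvas = canvas * np.exp(
            rng.normal(0.0, spec.speckle_sigma, size=canvas.shape)
        )
    canvas = np.clip(canvas, 0.0, 1.0)
    img = UltrasoundImage(canvas, meta={"infant_code": "phantom", "week": 0,
                                        "plane": "c3"})
    return img, pairs


@dataclass(frozen=True)
class PhantomFixture:
    spec: PhantomSpec
    image: UltrasoundImage
    pairs: tuple  # ((BinaryMask, ROIPolygon), ...)


def phantom_suite(n_images: int, base_seed: int,
                  noise_grid: Sequence[float] = (0.25,),
                  spec: PhantomSpec = PhantomSpec()) -> list:
    """Reproducible battery: seeds base_seed..base_seed+n-1 × noise grid."""
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    fixtures = []
    for sigma in noise_grid:
        for i in range(n_images):
            s = replace(spec, seed=base_seed + i, speckle_sigma=float(sigma))
            img, pairs = generate_phantom(s)
            fixtures.append(PhantomFixture(spec=s, image=img, pairs=tuple(pairs)))
    return fixtures
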