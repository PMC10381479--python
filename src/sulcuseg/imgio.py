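"""Image and annotation-table I/O.

Images are neonatal cranial ultrasound B-mode frames stored as 8-bit
BMP/JPG/PNG; in memory they are float grids in [0, 1].  The dataset
convention conforms every frame to 550 rows x 868 columns.  Annotation
tables carry the manually drawn groove polygons, one row per vertex,
with columns ``groove, vertex, x, y`` (CSV canonical, XLSX optional).

Coordinate convention used throughout the package: 0-based, ``x`` is the
column and ``y`` the row, pixel centers at integer coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize

from .errors import FormatError, ParseError, SchemaError, ShapeError

#: Height x width every frame is conformed to.
CONFORMED_SHAPE = (550, 868)

#: Coronal and sagittal acquisition plane codes.
PLANE_CODES = frozenset(
    ["c1", "c2", "c3", "c4", "c5", "c6", "s1", "s2l", "s2r", "s3l", "s3r", "s4l", "s4r"]
)

_SUPPORTED_SUFFIXES = {".bmp", ".jpg", ".jpeg", ".png"}

# ITU-R BT.601 luminance weights for RGB -> intensity.
_LUMA = np.array([0.299, 0.587, 0.114])

_FILENAME_RE = re.compile(r"^(?P<infant>[^_]+)_(?P<week>\d+)_(?P<plane>[a-z0-9]+)$")

TABLE_COLUMNS = ["groove", "vertex", "x", "y"]


@dataclass
class UltrasoundImage:
    """A single 2-D ultrasound frame with acquisition metadata."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError("pixels must be a nonempty 2-D grid")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def parse_filename_metadata(stem: str) -> dict:
    """Parse ``<infant>_<week>_<plane>`` filename stems; empty dict otherwise."""
    m = _FILENAME_RE.match(stem)
    if m is None or m.group("plane") not in PLANE_CODES:
        return {}
    return {
        "infant_code": m.group("infant"),
        "week": int(m.group("week")),
        "plane": m.group("plane"),
    }


def load_image(path) -> UltrasoundImage:
    """Load a BMP/JPG/PNG frame as a [0, 1] intensity grid.

    RGB inputs are converted to single-channel luminance (BT.601 weights).
    Metadata is parsed from the filename when it follows the
    ``<infant>_<week>_<plane>`` convention.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format: {path.suffix!r}")
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im, dtype=float)
    except UnidentifiedImageError as exc:
        raise OSError(f"unreadable image file: {path}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    pixels = np.clip(arr / 255.0, 0.0, 1.0)
    return UltrasoundImage(pixels, meta=parse_filename_metadata(path.stem))


def save_image(img: UltrasoundImage | np.ndarray, path) -> None:
    """Write an intensity grid (or {0,1} mask) as an 8-bit grayscale file."""
    arr = img.pixels if isinstance(img, UltrasoundImage) else np.asarray(img, dtype=float)
    Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)).save(Path(path))


def conform_resize(img: UltrasoundImage, shape: tuple[int, int] = CONFORMED_SHAPE) -> UltrasoundImage:
    """Resample a frame to the dataset's 550 x 868 convention (bilinear)."""
    if img.pixels.shape == shape:
        return UltrasoundImage(img.pixels.copy(), meta=dict(img.meta))
    out = resize(img.pixels, shape, order=1, mode="reflect", anti_aliasing=False,
                 preserve_range=True)
    return UltrasoundImage(np.clip(out, 0.0, 1.0), meta=dict(img.meta))


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing column(s): {missing}")
    df = df[TABLE_COLUMNS].copy()
    for col in ("vertex", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise ParseError(f"non-numeric value in column {col!r}")
        if coerced.isna().any():
            raise ParseError(f"missing value in column {col!r}")
        df[col] = coerced
    df["groove"] = df["groove"].astype(str)
    df["vertex"] = df["vertex"].astype(int)
    for groove, grp in df.groupby("groove", sort=False):
        idx = grp["vertex"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(len(idx))):
            raise SchemaError(
                f"vertex indices for groove {groove!r} are not contiguous from 0"
            )
    return df


def read_annotation_table(path) -> pd.DataFrame:
    """Read a groove-vertex table (CSV or XLSX) and validate its schema."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    return _validate_table(df)


def write_annotation_table(table: pd.DataFrame, path) -> None:
    """Write a validated groove-vertex table as CSV (or XLSX by suffix)."""
    df = _validate_table(pd.DataFrame(table))
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
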