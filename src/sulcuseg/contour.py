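"""Mask-to-polygon conversion and vertex editing.

The final deliverable per groove is an ordered, editable outline (the red
contour overlaid on the frame).  The contour is extracted by tracing the
pixel-edge boundary of the foreground region: polygon vertices sit on the
half-integer lattice between pixel centers, so re-rasterizing the polygon
(boundary-inclusive, pixel-center rule) reproduces the mask exactly.  A
solid rectangle therefore yields its four corners, a single pixel its
unit square.

At a diagonal pinch (two pixels of an 8-connected region touching only at
a corner) the traced loop passes through the shared vertex twice; the
even-odd rasterization rule handles this correctly.  Regions with
interior holes cannot be represented by one simple polygon and are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.measure import label as _sk_label

from .binarize import BinaryMask
from .errors import BoundsError, EmptySelectionError, TopologyError
from .regions import rasterize_polygon


@dataclass(frozen=True)
class Contour:
    """Ordered closed outline: (x, y) vertices, last joins first implicitly."""

    vertices: tuple
    groove_label: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise TopologyError("contour needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        return rasterize_polygon(self.as_array(), shape)


def _left(d):
    # left turn in screen coordinates (x right, y down)
    return (d[1], -d[0])


def _right(d):
    return (-d[1], d[0])


def _boundary_edges(grid: np.ndarray):
    """Directed pixel-edge boundary segments, keyed by doubled coordinates.

    Each foreground pixel contributes one edge per side facing background,
    oriented so the loop runs clockwise on screen.  Vertex keys are
    (2x, 2y) integers to keep half-integer corners hashable exactly.
    """
    h, w = grid.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = grid
    edges = {}  # start key -> list of (end key, direction)
    rr, cc = np.nonzero(grid)
    for r, c in zip(rr.tolist(), cc.tolist()):
        x2, y2 = 2 * c, 2 * r  # doubled pixel-center coordinates
        if not padded[r, c + 1]:  # background above
            edges.setdefault((x2 - 1, y2 - 1), []).append(((x2 + 1, y2 - 1), (1, 0)))
        if not padded[r + 1, c + 2]:  # background right
            edges.setdefault((x2 + 1, y2 - 1), []).append(((x2 + 1, y2 + 1), (0, 1)))
        if not padded[r + 2, c + 1]:  # background below
            edges.setdefault((x2 + 1, y2 + 1), []).append(((x2 - 1, y2 + 1), (-1, 0)))
        if not padded[r + 1, c]:  # background left
            edges.setdefault((x2 - 1, y2 + 1), []).append(((x2 - 1, y2 - 1), (0, -1)))
    return edges


def _trace_loop(edges: dict) -> list:
    """Follow boundary edges into one closed loop, preferring left turns.

    The left-turn rule keeps diagonally touching pixels on a single loop
    (8-connectivity).  Leftover edges afterwards mean the region has an
    interior hole.
    """
    start = min(edges)
    first_end, first_dir = edges[start][0]
    loop = [start]
    used = {(start, first_end)}
    vertex, direction = first_end, first_dir
    n_edges = sum(len(v) for v in edges.values())
    while vertex != start or any(
        (vertex, e) not in used for e, _ in edges.get(vertex, [])
    ):
        loop.append(vertex)
        candidates = [
            (end, d) for end, d in edges.get(vertex, []) if (vertex, end) not in used
        ]
        if not candidates:
            raise TopologyError("boundary tracing stalled (inconsistent mask)")
        for pref in (_left(direction), direction, _right(direction)):
            chosen = next(((e, d) for e, d in candidates if d == pref), None)
            if chosen is not None:
                break
        else:  # pragma: no cover - cannot happen for valid boundaries
            chosen = candidates[0]
        used.add((vertex, chosen[0]))
        vertex, direction = chosen
    if len(used) != n_edges:
        raise TopologyError("mask has interior holes; outline would not be simple")
    return loop


def _simplify_collinear(loop: list) -> list:
    n = len(loop)
    out = []
    for i in range(n):
        prev, cur, nxt = loop[i - 1], loop[i], loop[(i + 1) % n]
        d1 = (cur[0] - prev[0], cur[1] - prev[1])
        d2 = (nxt[0] - cur[0], nxt[1] - cur[1])
        if d1[0] * d2[1] != d1[1] * d2[0]:
            out.append(cur)
    return out


def mask_to_contour(mask: BinaryMask, groove_label: str = "", method: str = "") -> Contour:
    """Trace the outline polygon of a single-component mask.

    Raises EmptySelectionError for an empty mask and TopologyError when
    the foreground has several 8-connected components or interior holes.
    """
    grid = mask.grid
    if not grid.any():
        raise EmptySelectionError("cannot outline an empty mask")
    if _sk_label(grid.astype(int), connectivity=2).max() > 1:
        raise TopologyError("mask has multiple connected components")
    loop = _trace_loop(_boundary_edges(grid))
    loop = _simplify_collinear(loop)
    verts = [(kx / 2.0, ky / 2.0) for kx, ky in loop]
    return Contour(verts, groove_label=groove_label, method=method)


def edit_vertex(contour: Contour, index: int, new_xy,
                image_shape: tuple[int, int] | None = None) -> Contour:
    """Return a contour with vertex ``index`` moved to ``new_xy``."""
    if not (0 <= index < len(contour.vertices)):
        raise IndexError(f"vertex index {index} out of range")
    x, y = float(new_xy[0]), float(new_xy[1])
    if image_shape is not None:
        h, w = image_shape
        if not (-0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5):
            raise BoundsError("target vertex position outside the image")
    verts = list(contour.vertices)
    verts[index] = (x, y)
    return replace(contour, vertices=tuple(verts))


def contours_to_table(contours) -> "pd.DataFrame":
    """Serialize contours to the canonical groove/vertex/x/y table."""
    import pandas as pd

    rows = [
        {"groove": c.groove_label, "vertex": i, "x": x, "y": y}
        for c in contours
        for i, (x, y) in enumerate(c.vertices)
    ]
    return pd.DataFrame(rows, columns=["groove", "vertex", "x", "y"])


def table_to_contours(table, method: str = "") -> list:
    """Rebuild Contour objects from an annotation table (one per groove)."""
    out = []
    for groove, grp in table.groupby("groove", sort=False):
        grp = grp.sort_values("vertex")
        out.append(
            Contour(list(zip(grp["x"], grp["y"])), groove_label=str(groove), method=method)
        )
    return out
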