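"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives an operation from first principles (explicit
sliding windows, flood fill, direct pixel counting) so it shares no code
path with the package implementation it checks.
"""

from collections import deque

import numpy as np


def _reflect_pad(grid: np.ndarray, r: int) -> np.ndarray:
    # symmetric reflection: the edge pixel itself is mirrored into the pad
    return np.pad(grid, r, mode="symmetric")


def brute_local_threshold(grid: np.ndarray, block_size: int, method: str,
                          offset: float, param=None) -> np.ndarray:
    """Pixel > (windowed statistic - offset), windows by explicit loops."""
    grid = np.asarray(grid, dtype=float)
    h, w = grid.shape
    if method == "mean":
        r = block_size // 2
        padded = _reflect_pad(grid, r)
        stat = np.empty_like(grid)
        for i in range(h):
            for j in range(w):
                stat[i, j] = padded[i:i + block_size, j:j + block_size].mean()
    elif method == "gaussian":
        sigma = param if param is not None else (block_size - 1) / 6.0
        r = int(4.0 * sigma + 0.5)  # same truncation as a 4-sigma kernel
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = _reflect_pad(grid, r)
        stat = np.empty_like(grid)
        for i in range(h):
            for j in range(w):
                stat[i, j] = (padded[i:i + 2 * r + 1, j:j + 2 * r + 1] * kernel).sum()
    else:
        raise ValueError(method)
    return grid > (stat - offset)


def flood_fill_label(grid: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """BFS connected-component labeling, raster-scan discovery order."""
    grid = np.asarray(grid).astype(bool)
    h, w = grid.shape
    if connectivity == 2:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for i in range(h):
        for j in range(w):
            if grid[i, j] and labels[i, j] == 0:
                nxt += 1
                q = deque([(i, j)])
                labels[i, j] = nxt
                while q:
                    r, c = q.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and grid[rr, cc] \
                                and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            q.append((rr, cc))
    return labels


def brute_dilate(grid: np.ndarray, offsets) -> np.ndarray:
    """Neighborhood maximum; pixels outside the image count as background."""
    grid = np.asarray(grid).astype(bool)
    h, w = grid.shape
    out = np.zeros_like(grid)
    for i in range(h):
        for j in range(w):
            out[i, j] = any(
                0 <= i + dr < h and 0 <= j + dc < w and grid[i + dr, j + dc]
                for dr, dc in offsets
            )
    return out


def brute_erode(grid: np.ndarray, offsets) -> np.ndarray:
    """Neighborhood minimum; pixels outside the image count as foreground."""
    grid = np.asarray(grid).astype(bool)
    h, w = grid.shape
    out = np.zeros_like(grid)
    for i in range(h):
        for j in range(w):
            out[i, j] = all(
                grid[i + dr, j + dc]
                for dr, dc in offsets
                if 0 <= i + dr < h and 0 <= j + dc < w
            )
    return out


def disk_offsets(radius: int):
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def brute_closing(grid: np.ndarray, radius: int) -> np.ndarray:
    offs = disk_offsets(radius)
    return brute_erode(brute_dilate(grid, offs), offs)


def brute_dice(S: np.ndarray, GT: np.ndarray):
    """TP/FP/FN by explicit pixel enumeration."""
    tp = fp = fn = 0
    for a, b in zip(np.asarray(S).astype(bool).ravel(),
                    np.asarray(GT).astype(bool).ravel()):
        if a and b:
            tp += 1
        elif a:
            fp += 1
        elif b:
            fn += 1
    dsc = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return dsc, tp, fp, fn


def shapely_point_in_polygon(points, vertices) -> np.ndarray:
    """Boundary-inclusive point-in-polygon via shapely (winding-based)."""
    import shapely

    poly = shapely.Polygon(vertices)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
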