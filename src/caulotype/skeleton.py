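"""Skeleton path extraction shared by stalk segmentation and morphometrics."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_longest_path(mask: np.ndarray) -> np.ndarray:
    """Ordered pixel path (N, 2, row/col) along the geometrically longest
    skeleton branch of a binary mask.

    Thins the mask to a 1-px skeleton, then extracts the weighted diameter
    (diagonal steps cost sqrt 2) of its pixel graph; side spurs fall away
    because only the longest end-to-end path is kept. Returns an empty
    array for masks whose skeleton is empty.
    """
    skel = skeletonize(mask.astype(bool))
    pts = np.argwhere(skel)
    n = len(pts)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    if n == 1:
        return pts.astype(int)

    index = -np.ones(mask.shape, dtype=int)
    index[tuple(pts.T)] = np.arange(n)

    rows, cols, w = [], [], []
    h, wid = mask.shape
    for dr, dc in _NEIGHBOURS:
        rr = pts[:, 0] + dr
        cc = pts[:, 1] + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < wid)
        j = np.full(n, -1, dtype=int)
        j[ok] = index[rr[ok], cc[ok]]
        valid = j >= 0
        rows.append(np.flatnonzero(valid))
        cols.append(j[valid])
        w.append(np.full(valid.sum(), np.hypot(dr, dc)))
    graph = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()

    # two-sweep diameter: farthest from vertex 0, then farthest from there
    d0 = dijkstra(graph, indices=0, directed=False)
    a = int(np.nanargmax(np.where(np.isfinite(d0), d0, -1)))
    da, pred = dijkstra(graph, indices=a, directed=False, return_predecessors=True)
    b = int(np.nanargmax(np.where(np.isfinite(da), da, -1)))

    path = [b]
    while path[-1] != a and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return pts[np.array(path[::-1])]


def smooth_path(path: np.ndarray, window: int = 7) -> np.ndarray:
    """Moving-average smoothing that keeps the endpoints pinned."""
    p = np.asarray(path, dtype=float)
    if len(p) <= window:
        return p
    sm = np.column_stack([
        ndi.uniform_filter1d(p[:, 0], window, mode="nearest"),
        ndi.uniform_filter1d(p[:, 1], window, mode="nearest"),
    ])
    sm[0], sm[-1] = p[0], p[-1]
    return sm


def extend_to_boundary(
    path: np.ndarray, mask: np.ndarray, step: float = 0.25, tangent_pts: int = 5
) -> np.ndarray:
    """Extend both path ends along their local tangent until leaving the mask.

    Coordinates are in (fractional) pixel units of ``mask``. The marching
    stops at the first sample outside the mask (or the frame), appending
    the last inside-to-outside midpoint, which lands on the contour to
    within half a step.
    """
    p = np.asarray(path, dtype=float)
    if len(p) < 2:
        return p

    def march(end: np.ndarray, direction: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(direction)
        if nrm == 0:
            return np.empty((0, 2))
        d = direction / nrm
        out = []
        pos = end.copy()
        for _ in range(int(np.ceil(max(mask.shape) / step))):
            nxt = pos + d * step
            rc = np.round(nxt).astype(int)
            if not (0 <= rc[0] < mask.shape[0] and 0 <= rc[1] < mask.shape[1]):
                break
            if not mask[rc[0], rc[1]]:
                out.append((pos + nxt) / 2.0)
                break
            out.append(nxt)
            pos = nxt
        return np.asarray(out).reshape(-1, 2)

    k = min(tangent_pts, len(p) - 1)
    head = march(p[0], p[0] - p[k])
    tail = march(p[-1], p[-1] - p[-1 - k])
    return np.vstack([head[::-1], p, tail])
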