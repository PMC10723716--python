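"""Planar geometry helpers: polylines, circular arcs, capsule rasterization.

Conventions
-----------
Polylines are ``(N, 2)`` float arrays of ``(row, col)`` coordinates in µm.
A cell body is a *capsule of total extent L*: the union of disks of radius
``width(s)/2`` swept along the centerline trimmed by ``width/2`` at each
end, so the tip-to-tip (pole-to-pole) extent equals the centerline arc
length ``L``. The polyline endpoints are therefore the cell poles.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "arc_length",
    "resample_polyline",
    "circular_arc",
    "polyline_tangents",
    "rasterize_tube",
    "point_polyline_distance",
]


def arc_length(polyline: np.ndarray) -> float:
    """Total arc length of a polyline (µm)."""
    p = np.asarray(polyline, dtype=float)
    if len(p) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def cumulative_length(polyline: np.ndarray) -> np.ndarray:
    p = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(polyline: np.ndarray, spacing: float) -> np.ndarray:
    """Resample at (approximately) uniform arc-length spacing, keeping endpoints."""
    p = np.asarray(polyline, dtype=float)
    s = cumulative_length(p)
    total = s[-1]
    if total == 0:
        return p[:1].copy()
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    rows = np.interp(si, s, p[:, 0])
    cols = np.interp(si, s, p[:, 1])
    return np.column_stack([rows, cols])


def circular_arc(length: float, curvature: float, n: int = 64) -> np.ndarray:
    """Centerline of arc length ``length`` with constant curvature (1/µm).

    Returned centred at its midpoint, oriented along the +col axis,
    bending toward +row. ``curvature == 0`` gives a straight segment.
    """
    s = np.linspace(-length / 2.0, length / 2.0, n)
    if abs(curvature) < 1e-9:
        return np.column_stack([np.zeros_like(s), s])
    r = 1.0 / curvature
    theta = s / r
    col = r * np.sin(theta)
    row = r * (1.0 - np.cos(theta))
    return np.column_stack([row, col])


def transform(polyline: np.ndarray, angle: float, offset: np.ndarray) -> np.ndarray:
    """Rotate by ``angle`` (radians) then translate by ``offset`` (row, col)."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return polyline @ rot.T + np.asarray(offset, dtype=float)


def polyline_tangents(polyline: np.ndarray) -> np.ndarray:
    """Unit tangents at each vertex (central differences)."""
    p = np.asarray(polyline, dtype=float)
    t = np.gradient(p, axis=0)
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return t / norm


def trim_polyline(polyline: np.ndarray, trim: float) -> np.ndarray:
    """Drop ``trim`` µm of arc length from each end (re-interpolated)."""
    p = np.asarray(polyline, dtype=float)
    s = cumulative_length(p)
    total = s[-1]
    if total <= 2 * trim:
        mid = p[len(p) // 2]
        return np.vstack([mid, mid])
    si = np.linspace(trim, total - trim, max(len(p), 2))
    rows = np.interp(si, s, p[:, 0])
    cols = np.interp(si, s, p[:, 1])
    return np.column_stack([rows, cols])


def point_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from each point (M, 2) to a polyline, via dense sampling."""
    samples = resample_polyline(polyline, 0.01)
    d = np.linalg.norm(points[:, None, :] - samples[None, :, :], axis=2)
    return d.min(axis=1)


def rasterize_tube(
    centerline_um: np.ndarray,
    radius_um: np.ndarray | float,
    pixel_size: float,
    shape: tuple[int, int],
    soft: bool = False,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Rasterize a variable-radius tube around a centerline.

    Returns ``(patch, window)`` where ``patch`` covers the bounding window of
    the tube within ``shape``. Hard masks (``soft=False``) are boolean
    (pixel centre within radius); soft masks are anti-aliased coverage in
    [0, 1] with a one-pixel linear edge ramp.

    The centerline is densely resampled (quarter-pixel spacing) and each
    pixel takes the minimum signed distance ``|p - c(s)| - r(s)`` over
    samples, which handles curvature and width profiles exactly enough at
    this resolution.
    """
    cl = np.asarray(centerline_um, dtype=float)
    if cl.ndim != 2 or len(cl) == 0:
        raise ValueError("centerline must be a non-empty (N, 2) array")
    if np.isscalar(radius_um):
        radii = np.full(len(cl), float(radius_um))
    else:
        radii = np.asarray(radius_um, dtype=float)
        if radii.shape != (len(cl),):
            raise ValueError("radius array must match centerline vertices")

    spacing = pixel_size / 4.0
    s_old = cumulative_length(cl)
    dense = resample_polyline(cl, spacing)
    s_new = cumulative_length(dense)
    r_dense = np.interp(s_new, s_old, radii)

    rmax = float(r_dense.max())
    lo = np.floor((dense.min(axis=0) - rmax) / pixel_size).astype(int) - 1
    hi = np.ceil((dense.max(axis=0) + rmax) / pixel_size).astype(int) + 2
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape))
    if np.any(hi <= lo):
        return np.zeros((0, 0)), (slice(0, 0), slice(0, 0))

    rr = (np.arange(lo[0], hi[0]) + 0.0) * pixel_size
    cc = (np.arange(lo[1], hi[1]) + 0.0) * pixel_size
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)  # (R, C, 2)
    pts = grid.reshape(-1, 2)

    # chunk over centerline samples to bound memory on long filaments
    signed = np.full(len(pts), np.inf)
    step = max(1, int(2e6 // max(len(pts), 1)))
    for i in range(0, len(dense), step):
        d = np.linalg.norm(pts[:, None, :] - dense[None, i:i + step, :], axis=2)
        sd = d - r_dense[None, i:i + step]
        signed = np.minimum(signed, sd.min(axis=1))
    signed = signed.reshape(hi[0] - lo[0], hi[1] - lo[1])

    if soft:
        patch = np.clip(0.5 - signed / pixel_size, 0.0, 1.0)
    else:
        patch = signed <= 0
    return patch, (slice(lo[0], hi[0]), slice(lo[1], hi[1]))
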