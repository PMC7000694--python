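"""Polyline and mask geometry shared by the simulator and the ROI analysis.

Coordinates are physical (micrometres) with the origin at the centre of the
top-left pixel; pixel (row r, col c) has centre (x, y) = (c * px, r * px).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "arclengths",
    "path_length",
    "point_at_arclength",
    "project_to_polyline",
    "pixel_centers",
    "disk_mask",
    "tube_mask",
]


def _vertices(path) -> np.ndarray:
    v = np.asarray(path, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("polyline must be an (N>=2, 2) array of (x, y) vertices")
    return v


def arclengths(path) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at 0."""
    v = _vertices(path)
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def path_length(path) -> float:
    return float(arclengths(path)[-1])


def point_at_arclength(path, s: float) -> np.ndarray:
    """Point (x, y) at arc length ``s`` along the polyline (clipped to ends)."""
    v = _vertices(path)
    cum = arclengths(v)
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(cum) - 2)
    seg = cum[i + 1] - cum[i]
    f = 0.0 if seg == 0 else (s - cum[i]) / seg
    return v[i] + f * (v[i + 1] - v[i])


def project_to_polyline(points, path) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto the polyline.

    Returns (arc length of the closest point, distance to it) per input
    point.  Vectorized over points, looped over segments (paths are short).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = _vertices(path)
    cum = arclengths(v)
    best_d2 = np.full(len(pts), np.inf)
    best_s = np.zeros(len(pts))
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        ab = b - a
        L2 = float(ab @ ab)
        t = np.zeros(len(pts)) if L2 == 0 else np.clip((pts - a) @ ab / L2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.sum((pts - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_s[better] = cum[i] + t[better] * np.sqrt(L2)
    return best_s, np.sqrt(best_d2)


def pixel_centers(shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    """(rows*cols, 2) array of pixel-centre (x, y) coordinates in um."""
    rows, cols = shape
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    return np.column_stack([cc.ravel() * pixel_size_um, rr.ravel() * pixel_size_um])


def disk_mask(shape: tuple[int, int], pixel_size_um: float, center_um, radius_um: float) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within a disk."""
    pts = pixel_centers(shape, pixel_size_um)
    d2 = np.sum((pts - np.asarray(center_um, dtype=float)) ** 2, axis=1)
    return (d2 <= radius_um * radius_um).reshape(shape)


def tube_mask(shape: tuple[int, int], pixel_size_um: float, path, radius_um: float) -> np.ndarray:
    """Boolean mask of pixels within ``radius_um`` of the polyline."""
    pts = pixel_centers(shape, pixel_size_um)
    _, dist = project_to_polyline(pts, path)
    return (dist <= radius_um).reshape(shape)
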