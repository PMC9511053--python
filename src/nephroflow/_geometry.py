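"""Polyline helpers shared by the generators, tracers and morphometry.

All coordinates are physical micrometres. Rasterisation everywhere in the
package samples pixel centres: index ``i`` maps to physical ``(i + 0.5) * size``.
"""

from __future__ import annotations

import numpy as np


def cumulative_arc(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (µm) along a polyline of shape (N, D)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("polyline needs at least two points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def arc_length(points: np.ndarray) -> float:
    """Total arc length (µm) of a polyline."""
    return float(cumulative_arc(points)[-1])


def resample_polyline(
    points: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length ``spacing``.

    Returns ``(points, s)`` where ``s`` is the arc-length coordinate of each
    resampled point. The original endpoints are always retained.
    """
    points = np.asarray(points, dtype=float)
    s = cumulative_arc(points)
    total = s[-1]
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = max(int(np.floor(total / spacing)), 1)
    new_s = np.arange(n + 1) * spacing
    if total - new_s[-1] > 1e-9:
        new_s = np.concatenate([new_s, [total]])
    out = np.column_stack([np.interp(new_s, s, points[:, d]) for d in range(points.shape[1])])
    return out, new_s


def interp_along(s_from: np.ndarray, values: np.ndarray, s_to: np.ndarray) -> np.ndarray:
    """Linear interpolation of a per-point quantity onto new arc positions."""
    return np.interp(s_to, s_from, values)


def unit_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at every polyline vertex (central differences)."""
    points = np.asarray(points, dtype=float)
    t = np.gradient(points, axis=0)
    norm = np.linalg.norm(t, axis=1)
    norm[norm == 0] = 1.0
    return t / norm[:, None]


def normals_2d(points: np.ndarray) -> np.ndarray:
    """Unit normals of a 2D polyline (tangent rotated +90°)."""
    t = unit_tangents(points)
    return np.column_stack([-t[:, 1], t[:, 0]])


def polyline_self_intersections(points: np.ndarray) -> list[tuple[float, float]]:
    """Arc positions (s_a, s_b) of self-intersecting segment pairs, if any.

    Brute-force pairwise segment test; adjacent segments are skipped.
    """
    points = np.asarray(points, dtype=float)[:, :2]
    s = cumulative_arc(points)
    hits: list[tuple[float, float]] = []
    n = len(points) - 1
    for i in range(n):
        p, r = points[i], points[i + 1] - points[i]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1 and np.allclose(points[0], points[-1]):
                continue
            q, u = points[j], points[j + 1] - points[j]
            denom = r[0] * u[1] - r[1] * u[0]
            if abs(denom) < 1e-12:
                continue
            d = q - p
            ti = (d[0] * u[1] - d[1] * u[0]) / denom
            tj = (d[0] * r[1] - d[1] * r[0]) / denom
            if 0.0 <= ti <= 1.0 and 0.0 <= tj <= 1.0:
                hits.append((float(s[i] + ti * (s[i + 1] - s[i])),
                             float(s[j] + tj * (s[j + 1] - s[j]))))
    return hits
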