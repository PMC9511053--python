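"""Semi-automatic proximal-tubule tracing and geometry measurement.

The user supplies ordered seed points from the glomerulotubular junction
outward (the seed order defines the flow direction). The seed polyline is
refined against a maximum-intensity projection of the trailing (fully
filled) frames: each point is re-centred on the lumen by taking the midpoint
of the half-maximum crossings of the intensity profile perpendicular to the
local tangent, and the local radius is half the full width at half maximum
(FWHM) above local background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter1d

from ._geometry import (
    cumulative_arc,
    normals_2d,
    polyline_self_intersections,
    resample_polyline,
)
from .config import DEFAULT_CONFIG, Config
from .io import ImageSeries

log = logging.getLogger(__name__)

__all__ = ["SeedAnnotation", "TubulePath", "trace_tubule", "tubule_volume"]


@dataclass
class SeedAnnotation:
    """Ordered click points along the tubule, in pixel coordinates (x, y)."""

    points_px: np.ndarray
    image: str = ""
    made_by: str = ""
    timestamp: str | None = None

    def __post_init__(self) -> None:
        self.points_px = np.atleast_2d(np.asarray(self.points_px, dtype=float))
        if self.points_px.shape[0] < 2:
            raise ValueError("seed annotation needs at least two points")
        if self.points_px.shape[1] not in (2, 3):
            raise ValueError("seed points must be 2D (x, y) or 3D (x, y, z)")
        if self.timestamp is None:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def validate_bounds(self, shape_px: tuple[int, int]) -> None:
        ny, nx = shape_px
        x, y = self.points_px[:, 0], self.points_px[:, 1]
        if np.any(x < 0) or np.any(y < 0) or np.any(x >= nx) or np.any(y >= ny):
            raise ValueError("seed points fall outside the image bounds")

    def points_um(self, pixel_size_um: float) -> np.ndarray:
        # pixel index i maps to the pixel centre at (i + 0.5) * size
        return (self.points_px[:, :2] + 0.5) * pixel_size_um

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "image": self.image,
                    "points_px": self.points_px.tolist(),
                    "made_by": self.made_by,
                    "timestamp": self.timestamp,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SeedAnnotation":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            points_px=np.asarray(raw["points_px"], dtype=float),
            image=raw.get("image", ""),
            made_by=raw.get("made_by", ""),
            timestamp=raw.get("timestamp"),
        )


@dataclass
class TubulePath:
    """A traced centreline resampled at uniform arc spacing, with radii."""

    points_um: np.ndarray          # (N, 2)
    s_um: np.ndarray               # (N,) arc-length coordinate
    radius_um: np.ndarray          # (N,) local lumen radius
    radius_ok: np.ndarray = field(default=None)  # per-point reliability flag
    min_length_um: float = 45.0

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        self.s_um = np.asarray(self.s_um, dtype=float)
        self.radius_um = np.asarray(self.radius_um, dtype=float)
        if self.radius_ok is None:
            self.radius_ok = np.isfinite(self.radius_um) & (self.radius_um > 0)
        self.radius_ok = np.asarray(self.radius_ok, dtype=bool)
        n = len(self.points_um)
        if not (len(self.s_um) == len(self.radius_um) == len(self.radius_ok) == n):
            raise ValueError("points, s, radii and flags must have equal length")

    @property
    def length_um(self) -> float:
        return float(cumulative_arc(self.points_um)[-1])

    @property
    def mean_diameter_um(self) -> float:
        r = self.radius_um[self.radius_ok]
        return float(2.0 * np.mean(r)) if len(r) else float("nan")

    @property
    def meets_length_criterion(self) -> bool:
        return self.length_um >= self.min_length_um

    @property
    def volume_um3(self) -> float:
        return tubule_volume(self)

    @property
    def cylinder_volume_um3(self) -> float:
        """Single-cylinder volume from mean diameter × length (comparator)."""
        return float(np.pi * (self.mean_diameter_um / 2.0) ** 2 * self.length_um)

    def cumulative_volume(self, s: np.ndarray | None = None) -> np.ndarray:
        """Frusta-sum volume from the junction to each arc position."""
        r = _filled_radii(self)
        rmid = 0.5 * (r[:-1] + r[1:])
        dv = np.pi * rmid**2 * np.diff(self.s_um)
        cum = np.concatenate([[0.0], np.cumsum(dv)])
        if s is None:
            return cum
        return np.interp(s, self.s_um, cum)

    def summary(self) -> dict:
        return {
            "length_um": self.length_um,
            "mean_diameter_um": self.mean_diameter_um,
            "volume_um3": self.volume_um3,
            "cylinder_volume_um3": self.cylinder_volume_um3,
            "meets_length_criterion": self.meets_length_criterion,
            "n_points": int(len(self.points_um)),
            "n_unreliable_radii": int((~self.radius_ok).sum()),
        }

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "s_um": self.s_um,
                "x_um": self.points_um[:, 0],
                "y_um": self.points_um[:, 1],
                "radius_um": self.radius_um,
                "radius_ok": self.radius_ok,
            }
        ).to_csv(path, index=False)


def _filled_radii(path: TubulePath) -> np.ndarray:
    """Radii with unreliable points filled by interpolation from reliable ones."""
    r = path.radius_um.copy()
    ok = path.radius_ok & np.isfinite(r) & (r > 0)
    if ok.all():
        return r
    if not ok.any():
        raise ValueError("no reliable radius estimates along the path")
    r[~ok] = np.interp(path.s_um[~ok], path.s_um[ok], r[ok])
    return r


def tubule_volume(path: TubulePath) -> float:
    """Lumen volume as a sum of cylinder frusta between consecutive points.

    ``Σ π ((rᵢ + rᵢ₊₁)/2)² Δsᵢ`` over the resampled centreline. Unreliable
    radii are interpolated from their reliable neighbours; a non-positive
    reliable radius raises.
    """
    if np.any(path.radius_um[path.radius_ok] <= 0):
        raise ValueError("non-positive radius in tubule path")
    r = _filled_radii(path)
    rmid = 0.5 * (r[:-1] + r[1:])
    return float(np.sum(np.pi * rmid**2 * np.diff(path.s_um)))


# ---------------------------------------------------------------------------
# tracing


def filled_projection(series: ImageSeries, n_frames: int = 3) -> np.ndarray:
    """Maximum-intensity projection over the trailing ``n_frames`` frames.

    The trailing frames show the completely filled tubule at best contrast.
    """
    n = min(n_frames, series.n_frames)
    return series.data[-n:].max(axis=0)


def _sample_profile(img: np.ndarray, center_um, normal, offsets_um, pixel_size_um):
    pts = center_um[None, :] + offsets_um[:, None] * normal[None, :]
    # physical µm -> fractional pixel index (centre convention)
    cols = pts[:, 0] / pixel_size_um - 0.5
    rows = pts[:, 1] / pixel_size_um - 0.5
    return map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _fwhm_crossings(profile: np.ndarray, offsets: np.ndarray):
    """Half-max crossings around the profile's central peak.

    Returns (left, right, ok): offsets (µm) of the half-maximum crossings on
    either side of the peak, or ok=False when the profile never falls to
    half-max on one side (FWHM not bracketed).
    """
    n_tail = max(len(profile) // 8, 2)
    bg = float(np.median(np.concatenate([profile[:n_tail], profile[-n_tail:]])))
    center_lo = len(profile) // 4
    center_hi = len(profile) - center_lo
    k = center_lo + int(np.argmax(profile[center_lo:center_hi]))
    peak = float(profile[k])
    half = bg + 0.5 * (peak - bg)
    if peak <= bg:
        return 0.0, 0.0, False

    left = right = None
    for i in range(k, 0, -1):
        if profile[i - 1] < half <= profile[i]:
            f = (half - profile[i - 1]) / (profile[i] - profile[i - 1])
            left = offsets[i - 1] + f * (offsets[i] - offsets[i - 1])
            break
    for i in range(k, len(profile) - 1):
        if profile[i + 1] < half <= profile[i]:
            f = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = offsets[i] + f * (offsets[i + 1] - offsets[i])
            break
    if left is None or right is None:
        return 0.0, 0.0, False
    return float(left), float(right), True


def trace_tubule(
    series: ImageSeries,
    seeds: SeedAnnotation,
    config: Config | None = None,
) -> TubulePath:
    """Refine seed points into a centreline with per-point FWHM radii.

    Raises on fewer than two seeds, on out-of-bounds seeds, and on a refined
    path that self-intersects (the offending arc positions are named).
    Positions whose perpendicular profile never falls to half-maximum keep a
    NaN radius and are flagged unreliable rather than raising.
    """
    cfg = config or DEFAULT_CONFIG
    seeds.validate_bounds(series.shape_px)
    px = series.pixel_size_um

    proj = filled_projection(series, cfg.projection_frames)
    sigma_px = cfg.smooth_sigma_um / px
    img = gaussian_filter(proj.astype(float), sigma_px) if sigma_px > 0 else proj.astype(float)

    pts, s = resample_polyline(seeds.points_um(px), cfg.resample_um)
    offsets = np.arange(-cfg.profile_halfwidth_um, cfg.profile_halfwidth_um + 1e-9,
                        cfg.profile_step_um)

    for _ in range(cfg.center_iterations):
        normals = normals_2d(pts)
        shifts = np.zeros(len(pts))
        for i in range(len(pts)):
            prof = _sample_profile(img, pts[i], normals[i], offsets, px)
            left, right, ok = _fwhm_crossings(prof, offsets)
            if ok:
                shifts[i] = np.clip(0.5 * (left + right),
                                    -cfg.snap_radius_um, cfg.snap_radius_um)
        # light smoothing of the shift field stabilises the iteration
        if len(shifts) >= 5:
            kernel = np.ones(5) / 5.0
            shifts = np.convolve(shifts, kernel, mode="same")
        pts = pts + shifts[:, None] * normals
        # coordinate smoothing suppresses noise-induced micro-kinks that would
        # otherwise read as self-intersections of adjacent segments; endpoints
        # stay fixed so the traced length is not eroded
        if len(pts) >= 5:
            ends = pts[[0, -1]].copy()
            pts = uniform_filter1d(pts, size=3, axis=0, mode="nearest")
            pts[[0, -1]] = ends
        pts, s = resample_polyline(pts, cfg.resample_um)

    hits = polyline_self_intersections(pts)
    if hits:
        locs = ", ".join(f"(s={a:.1f} µm, s={b:.1f} µm)" for a, b in hits[:5])
        raise ValueError(f"refined centreline self-intersects at {locs}")

    normals = normals_2d(pts)
    radii = np.full(len(pts), np.nan)
    ok_flags = np.zeros(len(pts), dtype=bool)
    for i in range(len(pts)):
        prof = _sample_profile(img, pts[i], normals[i], offsets, px)
        left, right, ok = _fwhm_crossings(prof, offsets)
        if ok:
            radii[i] = 0.5 * (right - left)
            ok_flags[i] = radii[i] > 0

    path = TubulePath(points_um=pts, s_um=s, radius_um=radii, radius_ok=ok_flags,
                      min_length_um=cfg.min_length_um)
    if not path.meets_length_criterion:
        log.info(
            "traced tubule length %.1f µm is below the %.0f µm inclusion minimum",
            path.length_um, cfg.min_length_um,
        )
    return path


def load_roi(path) -> SeedAnnotation:
    return SeedAnnotation.from_json(Path(path))
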