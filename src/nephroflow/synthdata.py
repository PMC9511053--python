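"""Synthetic multiphoton-like image data with known ground truth.

Two generators are provided:

* :func:`generate_filling_series` — a 2D time-lapse of a fluorescent tracer
  bolus filling a proximal tubule downstream of a glomerulus. The front
  advances at ``v(s) = Q / A(s)`` where ``Q`` is the true single-nephron
  filtration rate converted to µm³/s and ``A(s) = π r(s)²`` the local lumen
  cross-section, so the ground-truth arrival time at arc length ``s`` is
  ``t0 + ∫₀ˢ A(u) du / Q``.
* :func:`generate_vessel_stack` — a 3D z-stack containing a voxelised tube
  (straight, tilted or curved) and optionally a sphere standing in for the
  glomerular capillary tuft.

Both apply a photon-counting noise model ``Poisson(signal·gain)/gain +
Gaussian(0, read_sd)`` and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial import cKDTree
from scipy.special import expit

from ._geometry import cumulative_arc, resample_polyline

__all__ = [
    "NoiseModel",
    "NephronPhantom",
    "VesselPhantom",
    "FillingTruth",
    "VesselTruth",
    "generate_filling_series",
    "generate_vessel_stack",
    "filling_ground_truth",
    "straight_nephron",
    "random_nephron",
    "straight_vessel",
    "tilted_vessel",
    "curved_vessel",
]

#: exact conversion factor, 1 nl/min = 1e6 µm³ / 60 s
NL_MIN_TO_UM3_S = 1.0e6 / 60.0

_FINE_STEP_UM = 0.25   # centreline sampling for rasterisation
_TRUTH_STEP_UM = 0.05  # finer grid for the arrival-time quadrature


@dataclass(frozen=True)
class NoiseModel:
    """Photon-counting noise: Poisson shot noise plus Gaussian read noise."""

    poisson_gain: float = 1.0
    gaussian_read_sd: float = 2.0

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = expected
        if self.poisson_gain > 0:
            out = rng.poisson(np.clip(expected, 0, None) * self.poisson_gain) / self.poisson_gain
        if self.gaussian_read_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_read_sd, size=expected.shape)
        return out.astype(np.float64)


@dataclass
class NephronPhantom:
    """Ground-truth description of one glomerulus + proximal tubule scene.

    ``centerline_um`` is the tubule centreline as an (N, 2) polyline in µm,
    ordered from the glomerulotubular junction outward (the flow direction).
    ``radius_um`` is a scalar or per-vertex lumen radius.
    """

    centerline_um: np.ndarray
    radius_um: np.ndarray | float
    true_sngfr_nl_min: float
    glomerulus_center_um: tuple[float, float] | None = None
    glomerulus_radius_um: float = 0.0
    pixel_size_um: float = 0.5
    frame_interval_s: float = 1.0 / 6.0
    n_frames: int | None = None
    bolus_start_s: float = 2.0
    rise_width_s: float = 0.15
    background_level: float = 10.0
    peak_intensity: float = 100.0
    noise_model: NoiseModel | None = field(default_factory=NoiseModel)
    seed: int = 0
    fov_shape_px: tuple[int, int] | None = None  # (ny, nx)
    fov_margin_um: float = 8.0
    min_length_um: float = 45.0
    allow_short: bool = False

    def __post_init__(self) -> None:
        self.centerline_um = np.atleast_2d(np.asarray(self.centerline_um, dtype=float))
        if self.centerline_um.shape[1] == 3:
            # single focal plane: a constant z column is tolerated and dropped
            if np.ptp(self.centerline_um[:, 2]) > 1e-9:
                raise ValueError("time-series phantoms are single-plane; z must be constant")
            self.centerline_um = self.centerline_um[:, :2]
        if self.centerline_um.shape[1] != 2 or len(self.centerline_um) < 2:
            raise ValueError("centerline_um must be an (N>=2, 2) polyline")
        r = np.asarray(self.radius_um, dtype=float)
        if r.ndim == 0:
            r = np.full(len(self.centerline_um), float(r))
        if len(r) != len(self.centerline_um):
            raise ValueError("radius profile length must match centerline")
        if np.any(r <= 0):
            raise ValueError("all radii must be positive")
        self.radius_um = r
        if self.true_sngfr_nl_min <= 0:
            raise ValueError("true_sngfr_nl_min must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        length = cumulative_arc(self.centerline_um)[-1]
        if length < self.min_length_um and not self.allow_short:
            raise ValueError(
                f"tubule arc length {length:.1f} µm is below the "
                f"{self.min_length_um:g} µm inclusion minimum "
                "(pass allow_short=True to override)"
            )

    @property
    def length_um(self) -> float:
        return float(cumulative_arc(self.centerline_um)[-1])


@dataclass
class FillingTruth:
    """Ground truth for a filling series (arrival times on a fine arc grid)."""

    s_um: np.ndarray
    arrival_s: np.ndarray
    radius_um: np.ndarray
    tubule_volume_um3: float
    flow_um3_per_s: float
    true_sngfr_nl_min: float
    bolus_start_s: float
    total_fill_time_s: float
    truncated: bool = False
    out_of_fov: bool = False

    def arrival_at(self, s: np.ndarray | float) -> np.ndarray | float:
        """Interpolated front arrival time (s) at arc position(s) ``s`` µm."""
        return np.interp(s, self.s_um, self.arrival_s)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("s_um", "arrival_s", "radius_um"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def filling_ground_truth(phantom: NephronPhantom) -> FillingTruth:
    """Analytic arrival times and tubule volume for a phantom (no rendering).

    Arrival at arc length ``s`` is ``bolus_start + ∫₀ˢ π r(u)² du / Q``
    evaluated by trapezoidal quadrature on a 0.05 µm grid.
    """
    pts, s = resample_polyline(phantom.centerline_um, _TRUTH_STEP_UM)
    s0 = cumulative_arc(phantom.centerline_um)
    r = np.interp(s, s0, phantom.radius_um)
    area = math.pi * r**2
    q = phantom.true_sngfr_nl_min * NL_MIN_TO_UM3_S
    cumvol = cumulative_trapezoid(area, s, initial=0.0)
    arrival = phantom.bolus_start_s + cumvol / q
    volume = float(cumvol[-1])
    return FillingTruth(
        s_um=s,
        arrival_s=arrival,
        radius_um=r,
        tubule_volume_um3=volume,
        flow_um3_per_s=q,
        true_sngfr_nl_min=phantom.true_sngfr_nl_min,
        bolus_start_s=phantom.bolus_start_s,
        total_fill_time_s=volume / q,
    )


def _auto_fov(phantom: NephronPhantom) -> tuple[int, int]:
    pts = phantom.centerline_um
    rmax = float(np.max(phantom.radius_um))
    lo = pts.min(axis=0) - rmax
    hi = pts.max(axis=0) + rmax
    if phantom.glomerulus_center_um is not None:
        c = np.asarray(phantom.glomerulus_center_um, dtype=float)
        lo = np.minimum(lo, c - phantom.glomerulus_radius_um)
        hi = np.maximum(hi, c + phantom.glomerulus_radius_um)
    hi = hi + phantom.fov_margin_um
    nx = int(np.ceil(hi[0] / phantom.pixel_size_um))
    ny = int(np.ceil(hi[1] / phantom.pixel_size_um))
    return ny, nx


def generate_filling_series(phantom: NephronPhantom):
    """Render the tracer bolus filling the tubule; return (series, truth).

    The intensity at a pixel behind the front rises along a logistic ramp of
    width ``rise_width_s`` centred on the ground-truth arrival time, from
    ``background_level`` to ``background_level + peak_intensity``. A front
    still travelling when the acquisition ends sets ``truth.truncated``
    rather than raising, mirroring real truncated acquisitions; geometry
    falling outside the field of view sets ``truth.out_of_fov``.
    """
    from .io import ImageSeries  # local import to avoid a cycle

    truth = filling_ground_truth(phantom)
    px = phantom.pixel_size_um
    dt = phantom.frame_interval_s
    ny, nx = phantom.fov_shape_px if phantom.fov_shape_px is not None else _auto_fov(phantom)

    n_frames = phantom.n_frames
    if n_frames is None:
        t_end = truth.arrival_s[-1] + 8.0 * phantom.rise_width_s + 2.0
        n_frames = int(np.ceil(t_end / dt)) + 1

    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])

    fine_pts, fine_s = resample_polyline(phantom.centerline_um, _FINE_STEP_UM)
    fine_r = np.interp(fine_s, truth.s_um, truth.radius_um)
    fine_arrival = np.interp(fine_s, truth.s_um, truth.arrival_s)
    tree = cKDTree(fine_pts)
    dist, idx = tree.query(grid, workers=-1)
    inside = dist <= fine_r[idx]
    arrival_px = fine_arrival[idx]

    if phantom.glomerulus_center_um is not None and phantom.glomerulus_radius_um > 0:
        c = np.asarray(phantom.glomerulus_center_um, dtype=float)
        in_glom = np.linalg.norm(grid - c, axis=1) <= phantom.glomerulus_radius_um
        arrival_px = np.where(
            in_glom, np.minimum(arrival_px, phantom.bolus_start_s), arrival_px
        )
        inside = inside | in_glom

    arrival_in = arrival_px[inside]
    times = np.arange(n_frames) * dt
    frames = np.full((n_frames, ny * nx), float(phantom.background_level))
    # logistic ramp; vectorised over (frame, inside-pixel)
    signal = phantom.peak_intensity * expit(
        (times[:, None] - arrival_in[None, :]) / phantom.rise_width_s
    )
    frames[:, inside] += signal
    frames = frames.reshape(n_frames, ny, nx)

    if phantom.noise_model is not None:
        rng = np.random.default_rng(phantom.seed)
        frames = phantom.noise_model.apply(frames, rng)

    truth.truncated = bool(truth.arrival_s[-1] > times[-1])
    lo = phantom.centerline_um.min(axis=0) - np.max(phantom.radius_um)
    hi = phantom.centerline_um.max(axis=0) + np.max(phantom.radius_um)
    truth.out_of_fov = bool(
        lo[0] < 0 or lo[1] < 0 or hi[0] > nx * px or hi[1] > ny * px
    )

    series = ImageSeries(data=frames, pixel_size_um=px, frame_interval_s=dt)
    return series, truth


# ---------------------------------------------------------------------------
# phantom factories


def straight_nephron(
    length_um: float = 80.0,
    radius_um: float = 10.0,
    sngfr_nl_min: float = 4.0,
    *,
    glomerulus_radius_um: float = 25.0,
    seed: int = 0,
    **kwargs,
) -> NephronPhantom:
    """A straight horizontal tubule leaving a glomerulus at its west edge."""
    margin = kwargs.pop("fov_margin_um", 8.0)
    rmax = max(radius_um, glomerulus_radius_um)
    y0 = margin + rmax
    x0 = margin + 2 * glomerulus_radius_um if glomerulus_radius_um > 0 else margin + radius_um
    n = max(int(length_um) + 1, 2)
    xs = np.linspace(x0, x0 + length_um, n)
    centerline = np.column_stack([xs, np.full(n, y0)])
    glom = (x0 - glomerulus_radius_um, y0) if glomerulus_radius_um > 0 else None
    return NephronPhantom(
        centerline_um=centerline,
        radius_um=radius_um,
        true_sngfr_nl_min=sngfr_nl_min,
        glomerulus_center_um=glom,
        glomerulus_radius_um=glomerulus_radius_um,
        seed=seed,
        fov_margin_um=margin,
        **kwargs,
    )


def random_nephron(
    seed: int,
    sngfr_nl_min: float | None = None,
    *,
    sngfr_range: tuple[float, float] = (0.5, 9.0),
    length_range: tuple[float, float] = (60.0, 100.0),
    radius_range: tuple[float, float] = (7.0, 12.0),
    **kwargs,
) -> NephronPhantom:
    """A randomly curved, gently tapering tubule phantom for recovery studies."""
    rng = np.random.default_rng(seed)
    if sngfr_nl_min is None:
        sngfr_nl_min = float(rng.uniform(*sngfr_range))
    length = float(rng.uniform(*length_range))
    r0 = float(rng.uniform(*radius_range))
    r1 = r0 * float(rng.uniform(0.85, 1.1))
    amp = float(rng.uniform(0.0, 8.0))
    period = float(rng.uniform(60.0, 160.0))
    glom_r = 25.0
    margin = 8.0
    x0 = margin + 2 * glom_r
    y0 = margin + glom_r + amp
    n = max(int(length) + 1, 2)
    xs = np.linspace(0.0, length, n)
    centerline = np.column_stack(
        [x0 + xs, y0 + amp * np.sin(2 * np.pi * xs / period)]
    )
    radii = np.linspace(r0, r1, n)
    return NephronPhantom(
        centerline_um=centerline,
        radius_um=radii,
        true_sngfr_nl_min=sngfr_nl_min,
        glomerulus_center_um=(x0 - glom_r, y0),
        glomerulus_radius_um=glom_r,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# 3D vessel stacks


@dataclass
class VesselPhantom:
    """A tube (and optional sphere) embedded in a noisy 3D volume.

    ``centerline_um`` is (N, 3) with columns (x, y, z); the rendered volume
    is indexed [z, y, x] with voxel sizes ``voxel_size_um`` = (dz, dy, dx).
    """

    centerline_um: np.ndarray
    diameter_um: np.ndarray | float
    voxel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    stack_depth_um: float = 120.0
    shape_px: tuple[int, int] | None = None  # (ny, nx); derived if omitted
    sphere_center_um: tuple[float, float, float] | None = None
    sphere_radius_um: float = 0.0
    foreground_level: float = 100.0
    background_level: float = 10.0
    noise_model: NoiseModel | None = None
    seed: int = 0
    fov_margin_um: float = 5.0

    def __post_init__(self) -> None:
        self.centerline_um = np.atleast_2d(np.asarray(self.centerline_um, dtype=float))
        if self.centerline_um.shape[1] != 2 and self.centerline_um.shape[1] != 3:
            raise ValueError("centerline_um must be (N, 3)")
        if self.centerline_um.shape[1] == 2:
            raise ValueError("vessel centerlines are 3D (x, y, z)")
        d = np.asarray(self.diameter_um, dtype=float)
        if d.ndim == 0:
            d = np.full(len(self.centerline_um), float(d))
        if len(d) != len(self.centerline_um):
            raise ValueError("diameter profile length must match centerline")
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        self.diameter_um = d
        dz, dy, dx = self.voxel_size_um
        n_planes = self.stack_depth_um / dz
        if abs(n_planes - round(n_planes)) > 1e-9:
            raise ValueError(
                f"stack_depth_um / z-step = {n_planes:g} is not an integer plane count"
            )
        if np.min(d) <= 2.0 * max(dy, dx):
            raise ValueError(
                "diameter must exceed twice the in-plane voxel size to be resolvable"
            )

    @property
    def n_planes(self) -> int:
        return int(round(self.stack_depth_um / self.voxel_size_um[0]))


@dataclass
class VesselTruth:
    """Analytic ground truth for a rendered vessel stack."""

    centerline_um: np.ndarray
    diameter_um: np.ndarray
    mean_diameter_um: float
    sphere_volume_um3: float | None
    mask: np.ndarray  # exact analytic voxelisation (z, y, x), bool
    tube_volume_voxels: int

    def to_dict(self) -> dict:
        return {
            "centerline_um": np.asarray(self.centerline_um).tolist(),
            "diameter_um": np.asarray(self.diameter_um).tolist(),
            "mean_diameter_um": self.mean_diameter_um,
            "sphere_volume_um3": self.sphere_volume_um3,
            "tube_volume_voxels": self.tube_volume_voxels,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def generate_vessel_stack(phantom: VesselPhantom):
    """Voxelise the tube/sphere scene; return (stack, truth).

    A voxel is foreground when its centre lies within the local tube radius
    of the centreline (true 3D distance) or inside the sphere. The tube must
    lie fully inside the stack; otherwise a ValueError lists the out-of-bounds
    extent per axis.
    """
    from .io import VesselStack  # local import to avoid a cycle

    dz, dy, dx = phantom.voxel_size_um
    nz = phantom.n_planes
    pts, s = resample_polyline(phantom.centerline_um, min(_FINE_STEP_UM, dx / 2))
    s_orig = cumulative_arc(phantom.centerline_um)
    radius = np.interp(s, s_orig, np.asarray(phantom.diameter_um) / 2.0)

    if phantom.shape_px is not None:
        ny, nx = phantom.shape_px
    else:
        hi = pts.max(axis=0) + radius.max() + phantom.fov_margin_um
        if phantom.sphere_center_um is not None:
            c = np.asarray(phantom.sphere_center_um)
            hi = np.maximum(hi, c + phantom.sphere_radius_um + phantom.fov_margin_um)
        nx = int(np.ceil(hi[0] / dx))
        ny = int(np.ceil(hi[1] / dy))

    extent = np.array([nx * dx, ny * dy, nz * dz])  # (x, y, z)
    # the tube must fit laterally; along z the centreline may touch the
    # stack faces (a vessel spanning the full depth is the normal case)
    lo = pts.min(axis=0) - np.array([radius.max(), radius.max(), 0.0])
    hi = pts.max(axis=0) + np.array([radius.max(), radius.max(), 0.0])
    problems = []
    for ax, name in enumerate("xyz"):
        if lo[ax] < -1e-9 or hi[ax] > extent[ax] + 1e-9:
            problems.append(
                f"{name}: tube spans [{lo[ax]:.2f}, {hi[ax]:.2f}] µm "
                f"but the stack covers [0, {extent[ax]:.2f}] µm"
            )
    if phantom.sphere_center_um is not None and phantom.sphere_radius_um > 0:
        c = np.asarray(phantom.sphere_center_um, dtype=float)
        for ax, name in enumerate("xyz"):
            if c[ax] - phantom.sphere_radius_um < 0 or c[ax] + phantom.sphere_radius_um > extent[ax]:
                problems.append(f"{name}: sphere extends outside the stack")
    if problems:
        raise ValueError("phantom not fully inside stack: " + "; ".join(problems))

    tree = cKDTree(pts)
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    mask = np.zeros((nz, ny, nx), dtype=bool)
    gx, gy = np.meshgrid(xs, ys)
    plane_xy = np.column_stack([gx.ravel(), gy.ravel()])
    for k in range(nz):
        zc = (k + 0.5) * dz
        coords = np.column_stack([plane_xy, np.full(len(plane_xy), zc)])
        dist, idx = tree.query(coords, workers=-1)
        mask[k] = (dist <= radius[idx]).reshape(ny, nx)

    sphere_volume = None
    if phantom.sphere_center_um is not None and phantom.sphere_radius_um > 0:
        c = np.asarray(phantom.sphere_center_um, dtype=float)
        zz = (np.arange(nz) + 0.5) * dz
        d2 = (
            (xs[None, None, :] - c[0]) ** 2
            + (ys[None, :, None] - c[1]) ** 2
            + (zz[:, None, None] - c[2]) ** 2
        )
        mask |= d2 <= phantom.sphere_radius_um**2
        sphere_volume = 4.0 / 3.0 * math.pi * phantom.sphere_radius_um**3

    data = np.where(mask, phantom.background_level + phantom.foreground_level,
                    float(phantom.background_level))
    if phantom.noise_model is not None:
        rng = np.random.default_rng(phantom.seed)
        data = phantom.noise_model.apply(data, rng)

    stack = VesselStack(data=data, voxel_size_um=(dz, dy, dx))
    truth = VesselTruth(
        centerline_um=pts,
        diameter_um=2 * radius,
        mean_diameter_um=float(np.mean(2 * radius)),
        sphere_volume_um3=sphere_volume,
        mask=mask,
        tube_volume_voxels=int(mask.sum()),
    )
    return stack, truth


def straight_vessel(
    diameter_um: float = 12.0,
    *,
    depth_um: float = 120.0,
    voxel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5),
    seed: int = 0,
    **kwargs,
) -> VesselPhantom:
    """A z-aligned cylinder spanning the full stack depth."""
    margin = kwargs.pop("fov_margin_um", 5.0)
    cx = cy = margin + diameter_um / 2.0 + 2.0
    centerline = np.array([[cx, cy, 0.0], [cx, cy, depth_um]])
    return VesselPhantom(
        centerline_um=centerline,
        diameter_um=diameter_um,
        voxel_size_um=voxel_size_um,
        stack_depth_um=depth_um,
        seed=seed,
        fov_margin_um=margin,
        **kwargs,
    )


def tilted_vessel(
    diameter_um: float = 10.0,
    *,
    tilt_deg: float = 45.0,
    depth_um: float = 40.0,
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 0.5),
    seed: int = 0,
    **kwargs,
) -> VesselPhantom:
    """A straight cylinder tilted in the x–z plane by ``tilt_deg``."""
    margin = kwargs.pop("fov_margin_um", 5.0)
    r = diameter_um / 2.0
    length = depth_um / math.cos(math.radians(tilt_deg))
    x0 = margin + r
    y0 = margin + r + 2.0
    dxs = length * math.sin(math.radians(tilt_deg))
    centerline = np.array([[x0, y0, 0.0], [x0 + dxs, y0, depth_um]])
    return VesselPhantom(
        centerline_um=centerline,
        diameter_um=diameter_um,
        voxel_size_um=voxel_size_um,
        stack_depth_um=depth_um,
        seed=seed,
        fov_margin_um=margin,
        **kwargs,
    )


def curved_vessel(
    diameter_um: float = 8.0,
    *,
    bend_radius_um: float = 30.0,
    arc_deg: float = 120.0,
    depth_um: float = 30.0,
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 0.5),
    seed: int = 0,
    **kwargs,
) -> VesselPhantom:
    """A torus segment: tube of ``diameter_um`` bent around ``bend_radius_um``."""
    margin = kwargs.pop("fov_margin_um", 5.0)
    r = diameter_um / 2.0
    zc = depth_um / 2.0
    theta = np.linspace(0, math.radians(arc_deg), 90)
    cx = margin + r + bend_radius_um
    cy = margin + r + bend_radius_um
    xs = cx - bend_radius_um * np.cos(theta)
    ys = cy - bend_radius_um * np.sin(theta)
    centerline = np.column_stack([xs, ys, np.full_like(xs, zc)])
    return VesselPhantom(
        centerline_um=centerline,
        diameter_um=diameter_um,
        voxel_size_um=voxel_size_um,
        stack_depth_um=depth_um,
        seed=seed,
        fov_margin_um=margin,
        **kwargs,
    )
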