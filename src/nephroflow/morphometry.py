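"""3D vessel diameter and glomerular tuft volume from z-stacks.

The vessel lumen (binary mask, per-plane contours, or thresholded
intensity) is skeletonised in 3D; the centreline is the longest path
through the skeleton graph, and the local diameter at each centreline point
is twice the Euclidean distance-transform value there — the maximal
inscribed sphere, computed with physical voxel spacings so anisotropic
stacks (1 µm z-step vs sub-µm in-plane) are handled correctly. This
definition is orientation-robust: per-slice equivalent circles overestimate
the diameter of vessels oblique to the imaging plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, label as cc_label, map_coordinates, uniform_filter1d
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

from ._geometry import cumulative_arc
from .config import DEFAULT_CONFIG, Config
from .io import VesselStack

__all__ = [
    "VesselMeasurement",
    "GlomerulusMeasurement",
    "reconstruct_vessel",
    "glomerular_volume",
    "mask_from_contours",
    "mask_from_stack",
]


@dataclass
class VesselMeasurement:
    """Centreline with per-point inscribed-sphere diameters."""

    centerline_um: np.ndarray      # (N, 3) columns (x, y, z)
    s_um: np.ndarray
    diameter_um: np.ndarray
    role: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def mean_diameter_um(self) -> float:
        return float(np.mean(self.diameter_um))

    @property
    def n_points(self) -> int:
        return len(self.diameter_um)

    @property
    def length_um(self) -> float:
        return float(self.s_um[-1] - self.s_um[0]) if len(self.s_um) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "mean_diameter_um": self.mean_diameter_um,
            "n_points": self.n_points,
            "length_um": self.length_um,
            "flags": sorted(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "s_um": self.s_um,
                "x_um": self.centerline_um[:, 0],
                "y_um": self.centerline_um[:, 1],
                "z_um": self.centerline_um[:, 2],
                "diameter_um": self.diameter_um,
            }
        ).to_csv(path, index=False)


@dataclass
class GlomerulusMeasurement:
    """Tuft volume by voxel counting."""

    volume_um3: float
    voxel_count: int
    voxel_volume_um3: float

    @property
    def equivalent_sphere_diameter_um(self) -> float:
        return float((6.0 * self.volume_um3 / np.pi) ** (1.0 / 3.0))

    def to_dict(self) -> dict:
        return {
            "volume_um3": self.volume_um3,
            "voxel_count": self.voxel_count,
            "voxel_volume_um3": self.voxel_volume_um3,
            "equivalent_sphere_diameter_um": self.equivalent_sphere_diameter_um,
        }


def mask_from_contours(contours: dict, shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterise per-plane polygon contours into a binary (Z, Y, X) volume.

    ``contours`` maps plane index -> list of polygons, each an (M, 2) list of
    (x, y) pixel vertices. Contours must be closed, non-self-intersecting
    polygons and present in at least 3 planes.
    """
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    planes_with = 0
    for key, polys in contours.items():
        k = int(key)
        if not 0 <= k < nz:
            raise ValueError(f"contour plane {k} outside stack (0..{nz - 1})")
        any_poly = False
        for verts in polys:
            verts = np.asarray(verts, dtype=float)
            if len(verts) < 3:
                raise ValueError(f"plane {k}: polygon needs >= 3 vertices")
            poly = Polygon(verts)
            if not poly.is_valid:
                raise ValueError(f"plane {k}: contour is self-intersecting or invalid")
            rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(ny, nx))
            mask[k, rr, cc] = True
            any_poly = True
        planes_with += any_poly
    if planes_with < 3:
        raise ValueError(f"contours present in only {planes_with} planes (need >= 3)")
    return mask


def mask_from_stack(stack: VesselStack, threshold: float | None = None) -> np.ndarray:
    """Binarise an intensity stack (Otsu threshold when none is given)."""
    data = np.asarray(stack.data, dtype=float)
    if data.dtype == bool or set(np.unique(data)) <= {0.0, 1.0}:
        return data.astype(bool)
    thr = float(threshold) if threshold is not None else float(threshold_otsu(data))
    return data > thr


_HALF_OFFSETS = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) > (0, 0, 0)]
)


def _mask_graph(mask: np.ndarray, spacing: np.ndarray):
    """26-connected voxel graph of the mask: (coords, geometric edge list)."""
    coords = np.argwhere(mask)
    n = len(coords)
    flat = np.full(mask.shape, -1, dtype=np.int64)
    flat[tuple(coords.T)] = np.arange(n)
    rows, cols, dists = [], [], []
    shape = np.array(mask.shape)
    for off in _HALF_OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        j = np.full(n, -1, dtype=np.int64)
        j[ok] = flat[tuple(nb[ok].T)]
        ok &= j >= 0
        rows.append(np.arange(n)[ok])
        cols.append(j[ok])
        dists.append(np.full(ok.sum(), float(np.linalg.norm(off * spacing))))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    dists = np.concatenate(dists)
    return coords, rows, cols, dists


def _centerline_path(mask: np.ndarray, spacing: np.ndarray, edt: np.ndarray) -> np.ndarray:
    """Voxel indices of the centreline through an elongated mask.

    The centreline is the geodesic between the two mutually farthest voxels
    (double Dijkstra sweep on geometric distances) computed with edge costs
    penalised by the inverse squared distance transform, which pins the path
    to the medial ridge. Side branches are trimmed implicitly because only
    the single longest geodesic is kept. This avoids voxel-parity artifacts
    that thinning-based 3D skeletonisation shows on symmetric masks.
    """
    coords, rows, cols, dists = _mask_graph(mask, spacing)
    n = len(coords)
    if n == 1:
        return coords
    geom = coo_matrix((dists, (rows, cols)), shape=(n, n))
    geom = (geom + geom.T).tocsr()

    seed = int(np.argmax(edt[tuple(coords.T)]))
    d0 = dijkstra(geom, indices=seed, directed=False)
    d0[~np.isfinite(d0)] = -1.0
    a = int(np.argmax(d0))
    d1 = dijkstra(geom, indices=a, directed=False)
    d1[~np.isfinite(d1)] = -1.0
    b = int(np.argmax(d1))

    r = edt[tuple(coords.T)]
    rmid = 0.5 * (r[rows] + r[cols])
    penal = dists / (rmid**2 + 1e-6)
    ridge = coo_matrix((penal, (rows, cols)), shape=(n, n))
    ridge = (ridge + ridge.T).tocsr()
    _, pred = dijkstra(ridge, indices=a, directed=False, return_predecessors=True)
    path = [b]
    while path[-1] != a:
        prev = pred[path[-1]]
        if prev < 0:
            raise ValueError("mask is not geodesically connected")
        path.append(int(prev))
    return coords[path[::-1]]


def _inscribed_radii(
    mask: np.ndarray,
    edt: np.ndarray,
    spacing: np.ndarray,
    pts_zyx: np.ndarray,
) -> np.ndarray:
    """Sub-voxel maximal-inscribed-sphere radius at each centreline point.

    For a point ``p`` on the medial axis, every foreground voxel ``v`` in the
    local cross-section satisfies ``edt(v) + |v_perp - p| ≈ R`` (the distance
    transform of a tube is a cone around its axis). The raw EDT at the
    nearest voxel under-reads by the voxel's offset from the axis; taking
    the midpoint of the smallest and largest cone reconstruction over the
    neighbourhood cancels that offset to first order.
    """
    from scipy.spatial import cKDTree

    from ._geometry import unit_tangents

    coords = np.argwhere(mask)
    v_um = (coords + 0.5) * spacing
    edt_v = edt[tuple(coords.T)]
    tree = cKDTree(v_um)
    hmax = float(spacing.max())
    tangents = unit_tangents(pts_zyx) if len(pts_zyx) > 1 else np.array([[1.0, 0, 0]])

    radii = np.empty(len(pts_zyx))
    for i, p in enumerate(pts_zyx):
        idx = np.asarray(tree.query_ball_point(p, 1.8 * hmax), dtype=int)
        if len(idx) == 0:
            radii[i] = float(map_coordinates(edt, ((p / spacing) - 0.5)[:, None],
                                             order=1, mode="nearest")[0])
            continue
        dv = v_um[idx] - p
        axial = dv @ tangents[i]
        sel = np.abs(axial) <= 0.55 * hmax
        if not sel.any():
            radii[i] = float(np.max(edt_v[idx]))
            continue
        perp = np.linalg.norm(dv[sel] - axial[sel, None] * tangents[i][None, :], axis=1)
        cand = edt_v[idx[sel]] + perp
        radii[i] = 0.5 * (float(cand.min()) + float(cand.max()))
    return radii


def reconstruct_vessel(
    stack: VesselStack,
    contours: dict | None = None,
    threshold: float | None = None,
    config: Config | None = None,
) -> VesselMeasurement:
    """Centreline and per-point maximal-inscribed-sphere diameters.

    The mask is reduced to its medial centreline (longest distance-ridge
    geodesic), resampled every ``diameter_sample_um`` of arc length, and the
    diameter at each sample is twice the (anisotropy-aware) distance
    transform with a sub-voxel cone correction. Samples
    closer to a path end than the local radius are excluded: there the
    inscribed sphere touches the artificial end cap, not the wall.

    Raises on a disconnected mask (components listed) and on a skeleton
    longer than 1.5× the mask bounding-box diagonal (noisy skeleton —
    smooth or clean the mask).
    """
    cfg = config or DEFAULT_CONFIG
    if contours is not None:
        mask = mask_from_contours(contours, stack.data.shape)
    else:
        mask = mask_from_stack(stack, threshold)
    if not mask.any():
        raise ValueError("empty vessel mask")

    labels, n_comp = cc_label(mask)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        raise ValueError(
            f"vessel mask has {n_comp} disconnected components "
            f"(voxel counts: {sorted(sizes.tolist(), reverse=True)}); "
            "supply a single connected lumen"
        )

    dz, dy, dx = stack.voxel_size_um
    spacing = np.array([dz, dy, dx])
    edt = distance_transform_edt(mask, sampling=spacing)

    path_vox = _centerline_path(mask, spacing, edt)
    path_um_zyx = (path_vox + 0.5) * spacing
    if len(path_um_zyx) > 4:
        # moving-average smoothing removes the voxel-grid zigzag of the path
        path_um_zyx = uniform_filter1d(path_um_zyx, size=5, axis=0, mode="nearest")
    s = cumulative_arc(path_um_zyx) if len(path_um_zyx) > 1 else np.array([0.0])

    bbox = np.ptp(np.argwhere(mask), axis=0) * spacing
    diag = float(np.linalg.norm(bbox))
    if len(s) > 1 and s[-1] > 1.5 * max(diag, 1e-9):
        raise ValueError(
            f"skeleton arc length {s[-1]:.1f} µm exceeds 1.5× the bounding-box "
            f"diagonal ({diag:.1f} µm); the mask is noisy — smooth it first"
        )

    # sample every diameter_sample_um of arc length
    if len(s) > 1:
        s_samp = np.arange(0.0, s[-1] + 1e-9, cfg.diameter_sample_um)
        pts_zyx = np.column_stack(
            [np.interp(s_samp, s, path_um_zyx[:, d]) for d in range(3)]
        )
    else:
        s_samp = s
        pts_zyx = path_um_zyx
    radii = _inscribed_radii(mask, edt, spacing, pts_zyx)

    # exclude end-cap-biased samples
    keep = np.ones(len(s_samp), dtype=bool)
    if len(s_samp) > 4:
        dist_to_end = np.minimum(s_samp - s_samp[0], s_samp[-1] - s_samp)
        keep = dist_to_end >= radii
        if keep.sum() < 3:  # pathologically short vessel: keep everything
            keep[:] = True

    flags = [] if keep.all() else ["end_caps_excluded"]
    pts_xyz = pts_zyx[keep][:, ::-1]
    diam = 2.0 * radii[keep]
    if np.any(diam <= 0):
        raise ValueError("non-positive diameter on the centreline; mask too thin")
    return VesselMeasurement(
        centerline_um=pts_xyz,
        s_um=s_samp[keep],
        diameter_um=diam,
        role=stack.role,
        flags=flags,
    )


def glomerular_volume(
    stack: VesselStack,
    tuft_mask: np.ndarray | None = None,
    threshold: float | None = None,
) -> GlomerulusMeasurement:
    """Tuft volume = voxel count × physical voxel volume."""
    mask = np.asarray(tuft_mask, dtype=bool) if tuft_mask is not None else mask_from_stack(stack, threshold)
    if mask.shape != stack.data.shape:
        raise ValueError("tuft mask shape does not match the stack")
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty tuft mask")
    vv = stack.voxel_volume_um3
    return GlomerulusMeasurement(
        volume_um3=count * vv, voxel_count=count, voxel_volume_um3=vv
    )
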