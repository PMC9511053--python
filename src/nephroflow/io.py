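"""Image containers, TIFF + YAML-sidecar round trips, ROI and manifest I/O.

Images travel as multi-page TIFF (one page per frame or z-plane) with the
physical metadata — pixel size, frame interval, voxel sizes — in an adjacent
YAML sidecar. Metadata is mandatory: loading fails loudly rather than
assuming defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageSeries",
    "VesselStack",
    "save_series",
    "load_series",
    "save_stack",
    "load_stack",
    "sidecar_path",
    "load_manifest",
]


@dataclass
class ImageSeries:
    """A 2D time-lapse: ``data`` has shape (T, Y, X), photons as float."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageSeries data must be (T, Y, X)")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class VesselStack:
    """A 3D volume: ``data`` has shape (Z, Y, X); voxel sizes are (dz, dy, dx) µm."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    role: str | None = None  # "afferent" | "efferent", supplied by the annotator

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VesselStack data must be (Z, Y, X)")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive values (dz, dy, dx)")
        if self.role is not None and self.role not in ("afferent", "efferent"):
            raise ValueError("role must be 'afferent' or 'efferent'")

    @property
    def depth_um(self) -> float:
        return self.data.shape[0] * self.voxel_size_um[0]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx


def sidecar_path(image_path) -> Path:
    return Path(image_path).with_suffix(".yaml")


def save_series(series: ImageSeries, path, sidecar=None) -> Path:
    """Write a time series as multi-page TIFF plus YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(series.data, dtype=np.float32),
                     photometric="minisblack")
    meta = {
        "kind": "time_series",
        "pixel_size_um": float(series.pixel_size_um),
        "frame_interval_s": float(series.frame_interval_s),
        "n_frames": int(series.n_frames),
    }
    sc = Path(sidecar) if sidecar else sidecar_path(path)
    with open(sc, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return sc


def load_series(path, sidecar=None) -> ImageSeries:
    """Load a time series; the sidecar must declare pixel size and frame interval."""
    path = Path(path)
    sc = Path(sidecar) if sidecar else sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"sidecar not found: {sc}")
    with open(sc) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in ("pixel_size_um", "frame_interval_s"):
        if key not in meta:
            raise ValueError(f"sidecar {sc} missing required field '{key}'")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if "n_frames" in meta and int(meta["n_frames"]) != data.shape[0]:
        raise ValueError(
            f"sidecar field 'n_frames' ({meta['n_frames']}) does not match "
            f"TIFF page count ({data.shape[0]})"
        )
    return ImageSeries(
        data=np.asarray(data, dtype=np.float64),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
    )


def save_stack(stack: VesselStack, path, sidecar=None) -> Path:
    """Write a z-stack as multi-page TIFF plus YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32),
                     photometric="minisblack")
    dz, dy, dx = stack.voxel_size_um
    meta = {
        "kind": "z_stack",
        "voxel_size_um": {"z": dz, "y": dy, "x": dx},
        "depth_um": float(stack.depth_um),
        "n_planes": int(stack.data.shape[0]),
    }
    if stack.role:
        meta["role"] = stack.role
    sc = Path(sidecar) if sidecar else sidecar_path(path)
    with open(sc, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return sc


def load_stack(path, sidecar=None) -> VesselStack:
    """Load a z-stack; sidecar must declare all three voxel sizes."""
    path = Path(path)
    sc = Path(sidecar) if sidecar else sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"sidecar not found: {sc}")
    with open(sc) as fh:
        meta = yaml.safe_load(fh) or {}
    if "voxel_size_um" not in meta:
        raise ValueError(f"sidecar {sc} missing required field 'voxel_size_um'")
    vs = meta["voxel_size_um"]
    for axis in ("z", "y", "x"):
        if axis not in vs:
            raise ValueError(f"sidecar {sc} field 'voxel_size_um' missing axis '{axis}'")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    stack = VesselStack(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_um=(float(vs["z"]), float(vs["y"]), float(vs["x"])),
        role=meta.get("role"),
    )
    if "depth_um" in meta:
        declared = float(meta["depth_um"])
        if abs(declared - stack.depth_um) > 1e-6:
            raise ValueError(
                f"sidecar field 'depth_um' ({declared}) does not match "
                f"plane count × z-step ({stack.depth_um})"
            )
    return stack


# ---------------------------------------------------------------------------
# session manifests


MANIFEST_COLUMNS = ["animal_id", "unit_id", "group", "session", "series", "sidecar", "roi"]
VALID_GROUPS = ("placebo", "enalapril", "empagliflozin", "enalapril_empagliflozin")
VALID_SESSIONS = ("before", "after")


@dataclass
class SessionManifest:
    """Rows of (animal, unit, group, session, file paths), schema-validated."""

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        bad_groups = set(self.table["group"]) - set(VALID_GROUPS)
        if bad_groups:
            raise ValueError(f"invalid group labels: {sorted(bad_groups)}")
        bad_sessions = set(self.table["session"]) - set(VALID_SESSIONS)
        if bad_sessions:
            raise ValueError(f"invalid session labels: {sorted(bad_sessions)}")
        dup = self.table.duplicated(subset=["unit_id", "session"])
        if dup.any():
            pairs = self.table.loc[dup, ["unit_id", "session"]].values.tolist()
            raise ValueError(f"duplicate (unit_id, session) pairs: {pairs}")

    def resolve(self, value: str) -> Path:
        p = Path(value)
        return p if p.is_absolute() else self.root / p

    def __len__(self) -> int:
        return len(self.table)


def load_manifest(path, check_files: bool = True) -> SessionManifest:
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    manifest = SessionManifest(table=table, root=path.parent)
    if check_files:
        missing = []
        for _, row in table.iterrows():
            for col in ("series", "sidecar", "roi"):
                p = manifest.resolve(row[col])
                if not p.exists():
                    missing.append(str(p))
        if missing:
            raise FileNotFoundError("manifest references missing files: " + ", ".join(missing))
    return manifest


def write_json(obj: dict, path) -> None:
    """JSON writer with numpy-safe conversion and stable key order."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
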