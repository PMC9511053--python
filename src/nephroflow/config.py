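"""Single configuration surface for every analysis stage.

All numeric defaults of the pipeline live here so that every threshold and
window is auditable and overridable from one YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class Config:
    # --- tubule tracing ---
    resample_um: float = 1.0          # centreline resampling step
    snap_radius_um: float = 5.0       # max per-iteration ridge-snap displacement
    center_iterations: int = 3        # perpendicular-recentering passes
    profile_halfwidth_um: float = 25.0  # half-length of perpendicular profiles
    profile_step_um: float = 0.25     # sampling step along profiles
    smooth_sigma_um: float = 0.5      # Gaussian smoothing of the projection
    projection_frames: int = 3        # trailing frames in the filled projection
    min_length_um: float = 45.0       # inclusion criterion for tubule length

    # --- intensity traces / front detection ---
    trace_spacing_um: float = 2.0     # arc spacing of measurement positions
    baseline_frames: int = 5          # pre-bolus frames for baseline subtraction
    plateau_frames: int = 10          # trailing frames defining the plateau
    front_fraction: float = 0.5       # plateau fraction defining front arrival
    noise_floor_sds: float = 3.0      # plateau must exceed this × baseline SD
    min_valid_fraction: float = 0.6   # required fraction of detected arrivals

    # --- morphometry ---
    diameter_sample_um: float = 1.0   # arc spacing of diameter samples
    max_nephrons_per_animal: int = 3  # batch-runner warning threshold

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


DEFAULT_CONFIG = Config()
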