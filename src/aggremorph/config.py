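"""Run configuration: every threshold, radius, calibration and seed.

Defaults follow the acquisition/analysis constants of the study this
package reimplements: detection threshold 60 a.u. (250 a.u. for
kinetics imaging) out of 65535, particles kept above 9 px, rolling-ball
radius 200 px, k = 4 clusters, 10-min kinetics sampling. The pixel
calibrations are config values (6.5-µm camera pixel behind 40x or 10x
optics), not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # segmentation
    intensity_threshold: float = 60.0
    kinetics_threshold: float = 250.0
    min_area_exclusive: int = 9
    connectivity: int = 2  # 2 = 8-connected, 1 = 4-connected
    # preprocessing
    rolling_ball_radius: int = 200
    registration_window: int = 32
    # calibration
    pixel_size_um: float = 0.1625      # 40x objective
    pixel_size_um_10x: float = 0.65    # 10x objective
    # morphology
    log_sigma_min_um: float = 0.15
    log_sigma_max_um: float = 0.5
    log_response_fraction: float = 0.3
    include_total_length: bool = False
    # classification
    kmeans_k: int = 4
    kmeans_restarts: int = 50
    # kinetics
    sampling_interval_min: float = 10.0
    # randomness: one seed fanned out per stage
    seed: int = 0
    # paths
    input_paths: list = field(default_factory=list)
    output_dir: str = "run_output"

    def __post_init__(self) -> None:
        if not (0 <= self.intensity_threshold <= 65535):
            raise ValueError(f"intensity_threshold={self.intensity_threshold} "
                             "outside [0, 65535]")
        if not (0 <= self.kinetics_threshold <= 65535):
            raise ValueError(f"kinetics_threshold={self.kinetics_threshold} "
                             "outside [0, 65535]")
        if self.min_area_exclusive < 0:
            raise ValueError("min_area_exclusive must be >= 0")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 or 2")
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        for name in ("pixel_size_um", "pixel_size_um_10x", "sampling_interval_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        import zlib
        return (self.seed * 1_000_003 + zlib.adler32(stage.encode())) % (2**31 - 1)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
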