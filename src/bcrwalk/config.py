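"""Run configuration with every analysis default in one place.

All values are overridable, either programmatically or from a flat
key-value YAML document (``RunConfig.from_file``).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # classification
    d_min: float = 10.0                      # immobility distance cutoff (m)
    half_width: float = math.pi / 8.0        # angular half-width of a quadrant
    # home range
    grid: int = 210                          # KDE grid nodes per axis
    levels: tuple = (100, 99, 95, 90, 80, 70, 60, 50, 40, 30, 20, 10)
    # dilation
    radii: tuple = tuple(range(1, 101))      # disk radii (m at 1 m/px)
    pixel_size: float = 1.0
    # transects
    sight: float = 200.0                     # still-transect line of sight (m)
    n_transects: int = 100
    sights: tuple = (50, 100, 200, 400, 500, 1000)
    speed_multipliers: tuple = (0.25, 0.5, 1.0, 2.0)
    respawn_ticks: int = 10_000
    rotation_radius: float = 500.0
    clock_divisor: int = 10
    # voids
    alpha_radius: float = 60.0
    min_void_area: float = 100.0
    p_cut: float = 0.05
    # comparison loop
    n_sim: int = 1000
    # seeds
    seed: int = 0
    placement_seed: int = 0

    def stat_kwargs(self) -> dict:
        """Per-statistic keyword arguments derived from this config."""
        return {
            "turning_angles": {"d_min": self.d_min},
            "home_range": {"grid": self.grid, "levels": tuple(self.levels)},
            "dilation": {"radii": tuple(self.radii), "pixel_size": self.pixel_size},
            "still_transects": {
                "sight": self.sight,
                "n_transects": self.n_transects,
                "placement_seed": self.placement_seed,
            },
            "mobile_transects": {
                "sights": tuple(self.sights),
                "speed_multipliers": tuple(self.speed_multipliers),
                "respawn_ticks": self.respawn_ticks,
                "rotation_radius": self.rotation_radius,
                "clock_divisor": self.clock_divisor,
            },
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("levels", "radii", "sights", "speed_multipliers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        for key in ("levels", "radii", "sights", "speed_multipliers"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
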