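"""Pipeline configuration: one JSON-serializable object with validated bounds."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

from .errors import ConfigError
from .mhb_scoring import MHBMapping


@dataclass
class PipelineConfig:
    depth_threshold: float = 6.0        # mm below the highest point searched for peaks
    ring: int = 2                       # peak neighbourhood rings
    stop_curvature: float = -0.6        # rad; region growth stops at sharper creases
    max_travel_permanent: float = 12.0  # mm; spill cap ("a tooth's width")
    max_travel_deciduous: float = 9.0
    merge_distance: float | None = None  # mm; default: half the max travel
    gap_penalty: float = 6.0
    discard_penalty: float = 9.0
    training_set_path: str | None = None  # None -> packaged synthetic default
    mhb: MHBMapping = field(default_factory=MHBMapping)
    seed: int = 0
    resolution: float = 0.4             # mm; synthetic-arch marching resolution

    def __post_init__(self):
        if self.depth_threshold <= 0 or self.depth_threshold > 30:
            raise ConfigError("depth_threshold must be in (0, 30] mm")
        if self.ring < 1 or self.ring > 5:
            raise ConfigError("ring must be in [1, 5]")
        if self.stop_curvature >= 0:
            raise ConfigError("stop_curvature must be negative")
        for v in (self.max_travel_permanent, self.max_travel_deciduous):
            if not 3.0 <= v <= 40.0:
                raise ConfigError("max_travel must be in [3, 40] mm")
        if self.merge_distance is not None and self.merge_distance <= 0:
            raise ConfigError("merge_distance must be positive")
        if self.gap_penalty < 0 or self.discard_penalty < 0:
            raise ConfigError("penalties must be non-negative")
        if not 0.15 <= self.resolution <= 0.6:
            raise ConfigError("resolution must be within [0.15, 0.6] mm")

    def max_travel(self, dentition: str) -> float:
        return (
            self.max_travel_deciduous
            if dentition == "deciduous"
            else self.max_travel_permanent
        )

    def merge_dist(self, dentition: str) -> float:
        if self.merge_distance is not None:
            return self.merge_distance
        return self.max_travel(dentition) / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if isinstance(d.get("mhb"), dict):
            m = d["mhb"]
            m = {
                **m,
                "buccal": tuple(tuple(x) for x in m.get("buccal", MHBMapping().buccal)),
                "labial": tuple(tuple(x) for x in m.get("labial", MHBMapping().labial)),
            }
            d["mhb"] = MHBMapping(**m)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
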