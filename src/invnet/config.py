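"""Run configuration with the analysis defaults.

Every numeric threshold of the analysis is exposed here with its standard
default: the 50-m assignment buffer, the 0.06-ha fishable-lake minimum,
the travel-speed filters, the 40-m permanent-stream merge threshold, the
5-km/20-km density rasterization, the lowest-20% density exclusion, and
the 20–100-km highway distance bands.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .angler import WeightFunctionParams
from .geometry import CRS_MODES, PLANAR


@dataclass
class PipelineConfig:
    crs_mode: str = PLANAR
    assignment_buffer_m: float = 50.0
    min_lake_area_ha: float = 0.06
    weight_params: WeightFunctionParams = field(default_factory=WeightFunctionParams)
    travel_filters: list[tuple[int, float]] = field(
        default_factory=lambda: [(0, 250.0), (1, 500.0), (2, 1500.0)]
    )
    merge_threshold_m: float = 40.0
    density_cell_km: float = 5.0
    density_radius_km: float = 20.0
    density_exclude_pct: float = 20.0
    band_edges_km: list[float] = field(default_factory=lambda: [20.0, 40.0, 60.0, 80.0, 100.0])
    hub_top_k: int = 5
    diameter_mode: str = "weight_cost"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.crs_mode not in CRS_MODES:
            raise ValueError(f"unknown crs_mode: {self.crs_mode!r}")
        for name in (
            "assignment_buffer_m",
            "merge_threshold_m",
            "density_cell_km",
            "density_radius_km",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_lake_area_ha < 0:
            raise ValueError("min_lake_area_ha must be >= 0")
        if not 0 <= self.density_exclude_pct < 100:
            raise ValueError("density_exclude_pct must be in [0, 100)")
        edges = list(self.band_edges_km)
        if any(b <= a for a, b in zip(edges, edges[1:])) or (edges and edges[0] <= 0):
            raise ValueError("band_edges_km must be positive and strictly increasing")
        for gap, max_km in self.travel_filters:
            if gap < 0 or max_km <= 0:
                raise ValueError("travel filters need day gap >= 0 and distance > 0")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["travel_filters"] = [list(t) for t in self.travel_filters]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "weight_params" in data and isinstance(data["weight_params"], dict):
            data["weight_params"] = WeightFunctionParams(**data["weight_params"])
        if "travel_filters" in data:
            data["travel_filters"] = [tuple(t) for t in data["travel_filters"]]
        return cls(**data)
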