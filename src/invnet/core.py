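"""Shared domain types for the lake-network pipeline.

Coordinates are either kilometres on a plane (``planar_km``, the mode used
for all synthetic landscapes) or longitude/latitude degrees
(``geographic_lonlat``).  All thresholds keep the units of their names
(``buffer_m`` is metres, ``hop_median_km`` kilometres) regardless of mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import LineString, Point, Polygon

#: Taxon groups recognised for invasion status (dreissenid mussels and
#: invasive watermilfoils).
TAXON_GROUPS = ("dreissena", "myriophyllum")

#: Stream flow-permanence classes carried by flowline segments.
FLOW_CLASSES = (
    "perennial",
    "intermittent",
    "ephemeral",
    "unclassified",
    "ditch",
    "canal",
    "karst",
    "pipeline",
    "underground",
)

#: Classes excluded from the hydrologic network (non-permanent,
#: subterranean or highly artificial conveyances).
EXCLUDED_FLOW_CLASSES = frozenset(
    {"ditch", "canal", "karst", "pipeline", "underground"}
)


@dataclass
class Lake:
    """A lake polygon and its network node.

    The midpoint starts as the polygon centroid; after cluster merging it is
    replaced by the centroid of the cluster's largest member, which is the
    point used for all edge lengths and distance measures.
    """

    lake_id: str
    polygon: Polygon
    area_ha: float
    name: str | None = None
    basin_id: str | None = None
    invaded_by: set[str] = field(default_factory=set)
    midpoint: Point | None = None

    def __post_init__(self) -> None:
        if self.midpoint is None:
            self.midpoint = self.polygon.centroid


@dataclass
class CatchLog:
    """Raw catch records plus per-reason drop tallies.

    ``records`` columns: user_id, timestamp (datetime64), exact_x, exact_y,
    approx_x, approx_y (NaN where absent).  Every retained record carries at
    least one location.
    """

    records: pd.DataFrame
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FlowSegment:
    """A directed (downstream) flowline segment between two node references.

    References are lake ids or junction ids; ``length_m`` is the channel
    length in metres, independent of any plotted geometry.
    """

    from_ref: str
    to_ref: str
    flow_class: str
    length_m: float

    def __post_init__(self) -> None:
        if self.flow_class not in FLOW_CLASSES:
            raise ValueError(f"unknown flow class: {self.flow_class!r}")
        if self.length_m < 0:
            raise ValueError("segment length must be >= 0")

    @property
    def permanent(self) -> bool:
        """Whether the segment counts as permanent stream (perennial)."""
        return self.flow_class == "perennial"


@dataclass(frozen=True)
class HighwayLine:
    highway_id: str
    polyline: LineString


@dataclass(frozen=True)
class RegionUnit:
    """An administrative unit (county analogue) used for risk aggregation."""

    region_id: str
    polygon: Polygon


@dataclass(frozen=True)
class Basin:
    """A major river basin; basins partition the study extent."""

    basin_id: str
    polygon: Polygon


#: Column order for movement tables.
MOVEMENT_COLUMNS = ["user_id", "origin", "dest", "day_gap", "length_km", "weight"]

#: Column order for directed-edge tables (both networks).
EDGE_COLUMNS = ["origin", "dest", "weight", "n_movements", "length_km"]
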