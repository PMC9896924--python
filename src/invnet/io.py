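"""Readers and writers for the package's standard text formats.

Vector layers use GeoJSON, catch logs and edge lists use CSV, networks can
also be exported as GraphML, and density rasters as ESRI ASCII grids.  All
files are plain text; edge-list round trips preserve weights to full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .core import EDGE_COLUMNS, Basin, CatchLog, FlowSegment, HighwayLine, Lake, RegionUnit
from .density import DensityRaster


# ---------------------------------------------------------------- lakes

def read_lakes(path: str | Path, area_unit: str = "ha") -> list[Lake]:
    """Read lake polygons from a GeoJSON FeatureCollection.

    Features need an ``id`` property, a polygon geometry and an ``area``
    property (``area_unit`` "ha" or "m2"; m² are converted, 10,000 m² =
    1 ha).  Invalid or missing geometry/id is a hard error naming the
    feature index.
    """
    fc = json.loads(Path(path).read_text())
    lakes = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        if props.get("id") in (None, ""):
            raise ValueError(f"feature {i}: missing lake id")
        if not feat.get("geometry"):
            raise ValueError(f"feature {i}: missing geometry")
        poly = shape(feat["geometry"])
        if not poly.is_valid:
            raise ValueError(f"feature {i} (id {props['id']}): invalid polygon geometry")
        area = float(props.get("area", poly.area))
        if area_unit == "m2":
            area = area / 10_000.0
        elif area_unit != "ha":
            raise ValueError(f"unknown area unit: {area_unit!r}")
        lakes.append(
            Lake(
                lake_id=str(props["id"]),
                polygon=poly,
                area_ha=area,
                name=props.get("name"),
                basin_id=props.get("basin_id"),
            )
        )
    ids = [lk.lake_id for lk in lakes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lake ids in input")
    return lakes


def write_lakes(lakes: list[Lake], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(lk.polygon),
            "properties": {
                "id": lk.lake_id,
                "area": lk.area_ha,
                "name": lk.name,
                "basin_id": lk.basin_id,
                "invaded_by": sorted(lk.invaded_by),
            },
        }
        for lk in lakes
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


# ---------------------------------------------------------------- catches

CATCH_COLUMNS = ["user_id", "timestamp", "exact_x", "exact_y", "approx_x", "approx_y"]


def read_catches(path: str | Path) -> CatchLog:
    """Read a catch-record CSV into a CatchLog.

    Rows with no usable location (neither exact nor approximate) and rows
    with unparseable timestamps are dropped and tallied; row order is
    preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in CATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catch CSV missing columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    has_exact = df["exact_x"].notna() & df["exact_y"].notna()
    has_approx = df["approx_x"].notna() & df["approx_y"].notna()
    no_loc = ~(has_exact | has_approx)
    keep = ~(bad_ts | no_loc)
    records = df.loc[keep, CATCH_COLUMNS].copy()
    records["timestamp"] = ts[keep]
    return CatchLog(
        records=records.reset_index(drop=True),
        drop_counts={
            "bad_timestamp": int(bad_ts.sum()),
            "no_location": int((no_loc & ~bad_ts).sum()),
        },
    )


def write_catches(log: CatchLog, path: str | Path) -> None:
    out = log.records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------- edges

def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a directed edge list CSV (full float precision, round-trip safe)."""
    edges[EDGE_COLUMNS].to_csv(path, index=False, float_format=None)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"origin": str, "dest": str})
    return df[EDGE_COLUMNS]


def write_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.origin,
            row.dest,
            weight=float(row.weight),
            n_movements=int(row.n_movements),
            length_km=float(row.length_km) if np.isfinite(row.length_km) else -1.0,
        )
    nx.write_graphml(g, path)


# ---------------------------------------------------------------- flowlines

def write_flowlines(segments: list[FlowSegment], path: str | Path) -> None:
    pd.DataFrame(
        [(s.from_ref, s.to_ref, s.flow_class, s.length_m) for s in segments],
        columns=["from_ref", "to_ref", "flow_class", "length_m"],
    ).to_csv(path, index=False)


def read_flowlines(path: str | Path) -> list[FlowSegment]:
    df = pd.read_csv(path, dtype={"from_ref": str, "to_ref": str})
    return [
        FlowSegment(r.from_ref, r.to_ref, r.flow_class, float(r.length_m))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- lines / regions

def write_lines_geojson(lines: list[HighwayLine], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(ln.polyline),
            "properties": {"id": ln.highway_id},
        }
        for ln in lines
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_lines_geojson(path: str | Path) -> list[HighwayLine]:
    fc = json.loads(Path(path).read_text())
    return [
        HighwayLine(str(f["properties"]["id"]), shape(f["geometry"]))
        for f in fc.get("features", [])
    ]


def write_regions_geojson(regions, path: str | Path, id_field: str = "id") -> None:
    feats = []
    for reg in regions:
        rid = getattr(reg, "region_id", None) or getattr(reg, "basin_id")
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(reg.polygon),
                "properties": {id_field: rid},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_regions_geojson(path: str | Path, kind: str = "county", id_field: str = "id"):
    fc = json.loads(Path(path).read_text())
    cls = RegionUnit if kind == "county" else Basin
    return [
        cls(str(f["properties"][id_field]), shape(f["geometry"]))
        for f in fc.get("features", [])
    ]


# ---------------------------------------------------------------- datasets

def save_dataset(ds, out_dir: str | Path) -> None:
    """Write every layer of a study dataset to a directory of text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_lakes(ds.lakes, out / "lakes.geojson")
    write_flowlines(ds.segments, out / "flowlines.csv")
    write_catches(ds.catch_log, out / "catches.csv")
    ds.occurrences.to_csv(out / "occurrences.csv", index=False)
    write_lines_geojson(ds.highways, out / "highways.geojson")
    write_regions_geojson(ds.counties, out / "counties.geojson")
    write_regions_geojson(ds.basins, out / "basins.geojson")


def load_dataset(in_dir: str | Path):
    """Read a dataset written by :func:`save_dataset`."""
    from .synthetic import SyntheticDataset

    d = Path(in_dir)
    occ = pd.read_csv(d / "occurrences.csv")
    if occ.empty:
        occ = pd.DataFrame(columns=["taxon_group", "x", "y"])
    return SyntheticDataset(
        lakes=read_lakes(d / "lakes.geojson"),
        segments=read_flowlines(d / "flowlines.csv"),
        catch_log=read_catches(d / "catches.csv"),
        occurrences=occ,
        highways=read_lines_geojson(d / "highways.geojson"),
        counties=read_regions_geojson(d / "counties.geojson", kind="county"),
        basins=read_regions_geojson(d / "basins.geojson", kind="basin"),
    )


# ---------------------------------------------------------------- raster

def write_ascii_grid(raster: DensityRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (rows top-down per the format)."""
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_x}\n"
        f"yllcorner {raster.origin_y}\n"
        f"cellsize {raster.cell_km}\n"
        f"NODATA_value -9999\n"
    )
    body = "\n".join(
        " ".join(repr(float(v)) for v in row) for row in raster.values[::-1]
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> DensityRaster:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for ln in lines[:6]:
        k, v = ln.split()
        hdr[k.lower()] = float(v)
    values = np.array([[float(v) for v in ln.split()] for ln in lines[6:] if ln.strip()])
    return DensityRaster(
        origin_x=hdr["xllcorner"],
        origin_y=hdr["yllcorner"],
        cell_km=hdr["cellsize"],
        values=values[::-1],
    )
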