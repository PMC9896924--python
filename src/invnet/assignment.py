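"""Assigning catch and occurrence points to lakes.

A point belongs to a lake if it falls inside the polygon or within a buffer
distance (default 50 m) of the polygon boundary.  When several lakes
qualify, the containing lake wins; remaining ties break by smallest
boundary distance and then lexicographic lake id, so assignment is
deterministic.  Only "fishable" lakes (surface area strictly above a
minimum, default 0.06 ha) participate in the network, so that filter runs
before any assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.strtree import STRtree

from .core import CatchLog, Lake


def filter_fishable(lakes: list[Lake], min_area_ha: float) -> list[Lake]:
    """Keep lakes with surface area strictly greater than ``min_area_ha``."""
    return [lk for lk in lakes if lk.area_ha > min_area_ha]


class LakeIndex:
    """Spatial index over lake polygons for repeated point assignment.

    In planar mode coordinates are km, so the metre buffer is converted;
    in geographic mode callers should pre-project (assignment on raw
    lon/lat would mix degrees with metres).
    """

    def __init__(self, lakes: list[Lake], buffer_m: float, coord_unit_per_km: float = 1.0):
        self.lakes = list(lakes)
        self.buffer = (buffer_m / 1000.0) * coord_unit_per_km
        self._geoms = np.array([lk.polygon for lk in self.lakes], dtype=object)
        self._ids = np.array([lk.lake_id for lk in self.lakes], dtype=object)
        self._tree = STRtree(list(self._geoms)) if self.lakes else None

    def assign_many(self, points: np.ndarray) -> np.ndarray:
        """Assign an array of shapely points; returns lake ids (object) with None where unassignable."""
        out = np.full(len(points), None, dtype=object)
        if self._tree is None or len(points) == 0:
            return out
        pt_idx, lk_idx = self._tree.query(points, predicate="dwithin", distance=self.buffer)
        if len(pt_idx) == 0:
            return out
        cand_pts = points[pt_idx]
        cand_geoms = self._geoms[lk_idx]
        dist_poly = shapely.distance(cand_pts, cand_geoms)  # 0 when inside
        dist_bound = shapely.distance(cand_pts, shapely.boundary(cand_geoms))
        df = pd.DataFrame(
            {
                "pt": pt_idx,
                "outside": dist_poly > 0,
                "dist_bound": dist_bound,
                "lake_id": self._ids[lk_idx],
            }
        )
        best = (
            df.sort_values(["pt", "outside", "dist_bound", "lake_id"])
            .groupby("pt", sort=False)
            .first()
        )
        out[best.index.to_numpy()] = best["lake_id"].to_numpy()
        return out

    def assign_one(self, point: Point) -> str | None:
        return self.assign_many(np.array([point], dtype=object))[0]


def assign_point(point: Point, lakes: list[Lake], buffer_m: float) -> str | None:
    """One-off point assignment (builds a throwaway index)."""
    return LakeIndex(lakes, buffer_m).assign_one(point)


def assign_catches(
    log: CatchLog, lakes: list[Lake], buffer_m: float
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign every catch record to a lake, exact location first.

    Returns an assignment table with columns ``user_id, timestamp, lake_id,
    source`` (source in {exact, approx}), in the input record order, plus
    drop tallies for unassignable records.
    """
    rec = log.records
    idx = LakeIndex(lakes, buffer_m)

    def _points(xcol: str, ycol: str) -> tuple[np.ndarray, np.ndarray]:
        have = rec[xcol].notna().to_numpy() & rec[ycol].notna().to_numpy()
        pts = shapely.points(
            rec.loc[have, xcol].to_numpy(dtype=float),
            rec.loc[have, ycol].to_numpy(dtype=float),
        )
        return have, pts

    assigned = np.full(len(rec), None, dtype=object)
    source = np.full(len(rec), None, dtype=object)

    have_exact, exact_pts = _points("exact_x", "exact_y")
    if have_exact.any():
        res = idx.assign_many(exact_pts)
        assigned[np.flatnonzero(have_exact)] = res
        source[np.flatnonzero(have_exact)[res != None]] = "exact"  # noqa: E711

    need = assigned == None  # noqa: E711
    have_approx, _ = _points("approx_x", "approx_y")
    fallback = need & have_approx
    if fallback.any():
        pts = shapely.points(
            rec.loc[fallback, "approx_x"].to_numpy(dtype=float),
            rec.loc[fallback, "approx_y"].to_numpy(dtype=float),
        )
        res = idx.assign_many(pts)
        assigned[np.flatnonzero(fallback)] = res
        source[np.flatnonzero(fallback)[res != None]] = "approx"  # noqa: E711

    keep = assigned != None  # noqa: E711
    table = pd.DataFrame(
        {
            "user_id": rec.loc[keep, "user_id"].to_numpy(),
            "timestamp": rec.loc[keep, "timestamp"].to_numpy(),
            "lake_id": assigned[keep],
            "source": source[keep],
        }
    )
    drops = {"unassignable": int((~keep).sum())}
    return table, drops


def mark_invaded(
    lakes: list[Lake], occurrences: pd.DataFrame, buffer_m: float
) -> list[Lake]:
    """Populate ``invaded_by`` from occurrence points (in place; returns lakes).

    ``occurrences`` columns: taxon_group, x, y.  Each occurrence marks at
    most one lake, chosen by the same containment/boundary rule as catch
    assignment.
    """
    idx = LakeIndex(lakes, buffer_m)
    if len(occurrences):
        pts = shapely.points(
            occurrences["x"].to_numpy(dtype=float), occurrences["y"].to_numpy(dtype=float)
        )
        ids = idx.assign_many(pts)
        by_id = {lk.lake_id: lk for lk in lakes}
        for lake_id, taxon in zip(ids, occurrences["taxon_group"]):
            if lake_id is not None:
                by_id[lake_id].invaded_by.add(taxon)
    return lakes
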