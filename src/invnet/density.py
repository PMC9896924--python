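"""Weighted line-density rasterization and the invasion superhighway.

The density raster follows the standard GIS line-density definition: for
each cell, the weighted length of edge segments falling within a search
disk around the cell center, divided by the disk area.  Defaults are a 5-km
cell and a 20-km search radius, and densities are reported as
connections/km².  The superhighway is the part of the highway network that
overlaps the raster cells remaining after excluding the lowest quantile of
(nonzero) density values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from .core import HighwayLine


@dataclass
class DensityRaster:
    """A regular grid of weighted connection density.

    ``values[r, c]`` is the density at the cell whose lower-left corner is
    ``(origin_x + c * cell_km, origin_y + r * cell_km)`` — row 0 is the
    bottom row.
    """

    origin_x: float
    origin_y: float
    cell_km: float
    values: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) arrays of all cell centers (row-major)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_km
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_km
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()


@dataclass
class Superhighway:
    """Highway pieces overlapping the retained high-density cells."""

    segments: list[LineString]
    retained_mask: np.ndarray
    parent_ids: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.segments


def _segment_disk_lengths(
    p1: np.ndarray, p2: np.ndarray, cx: np.ndarray, cy: np.ndarray, radius: float
) -> np.ndarray:
    """Length of segment p1→p2 inside disks of the given radius at (cx, cy).

    Solves |p1 + t d − c|² = r² per center and clips the parameter interval
    to [0, 1]; exact for straight segments.
    """
    d = p2 - p1
    seg_len = float(np.hypot(d[0], d[1]))
    if seg_len == 0.0:
        return np.zeros_like(cx)
    fx = p1[0] - cx
    fy = p1[1] - cy
    a = seg_len**2
    b = 2.0 * (fx * d[0] + fy * d[1])
    c = fx**2 + fy**2 - radius**2
    disc = b**2 - 4.0 * a * c
    inside = disc > 0.0
    sq = np.sqrt(np.where(inside, disc, 0.0))
    t0 = np.clip((-b - sq) / (2.0 * a), 0.0, 1.0)
    t1 = np.clip((-b + sq) / (2.0 * a), 0.0, 1.0)
    return np.where(inside, (t1 - t0) * seg_len, 0.0)


def line_density(
    edges: pd.DataFrame,
    lake_midpoints: dict[str, tuple[float, float]],
    extent: tuple[float, float, float, float],
    cell_km: float = 5.0,
    radius_km: float = 20.0,
) -> DensityRaster:
    """Weighted line density of edge segments on a regular grid.

    ``edges`` needs columns origin, dest, weight; segment geometry is the
    straight line between lake midpoints.  Each cell value is
    Σ_e weight(e) · length(e ∩ disk(center, radius)) / (π radius²).
    """
    if radius_km <= 0:
        raise ValueError("search radius must be > 0")
    x0, y0, x1, y1 = extent
    n_cols = max(1, int(np.ceil((x1 - x0) / cell_km)))
    n_rows = max(1, int(np.ceil((y1 - y0) / cell_km)))
    xs = x0 + (np.arange(n_cols) + 0.5) * cell_km
    ys = y0 + (np.arange(n_rows) + 0.5) * cell_km
    values = np.zeros((n_rows, n_cols))
    disk_area = np.pi * radius_km**2

    for origin, dest, weight in zip(edges["origin"], edges["dest"], edges["weight"]):
        p1 = np.asarray(lake_midpoints[origin], dtype=float)
        p2 = np.asarray(lake_midpoints[dest], dtype=float)
        lo_x, hi_x = sorted((p1[0], p2[0]))
        lo_y, hi_y = sorted((p1[1], p2[1]))
        ci = np.flatnonzero((xs >= lo_x - radius_km) & (xs <= hi_x + radius_km))
        ri = np.flatnonzero((ys >= lo_y - radius_km) & (ys <= hi_y + radius_km))
        if ci.size == 0 or ri.size == 0:
            continue
        gx, gy = np.meshgrid(xs[ci], ys[ri])
        lengths = _segment_disk_lengths(p1, p2, gx.ravel(), gy.ravel(), radius_km)
        values[np.ix_(ri, ci)] += weight * lengths.reshape(ri.size, ci.size) / disk_area

    return DensityRaster(origin_x=x0, origin_y=y0, cell_km=cell_km, values=values)


def threshold_density(raster: DensityRaster, exclude_pct: float = 20.0) -> np.ndarray:
    """Mask of cells retained after excluding the lowest density quantile.

    The percentile is computed over cells with value > 0 (the zero
    background is always excluded) with linear interpolation; cells whose
    value strictly exceeds it are retained.  Degenerate case: when the
    threshold equals the raster maximum (e.g. a uniform positive raster),
    cells at the threshold are retained so the mask is never emptied by
    ties at the top.
    """
    if not 0 <= exclude_pct < 100:
        raise ValueError("exclude_pct must be in [0, 100)")
    positive = raster.values > 0
    if not positive.any():
        warnings.warn("all-zero density raster: empty retained mask", stacklevel=2)
        return np.zeros_like(positive)
    if exclude_pct == 0:
        return positive
    q = float(np.percentile(raster.values[positive], exclude_pct))
    if q >= raster.values.max():
        return positive & (raster.values >= q)
    return positive & (raster.values > q)


def _mask_union(raster: DensityRaster, mask: np.ndarray):
    cells = [
        box(
            raster.origin_x + c * raster.cell_km,
            raster.origin_y + r * raster.cell_km,
            raster.origin_x + (c + 1) * raster.cell_km,
            raster.origin_y + (r + 1) * raster.cell_km,
        )
        for r, c in zip(*np.nonzero(mask))
    ]
    return unary_union(cells) if cells else None


def extract_superhighway(
    highways: list[HighwayLine], raster: DensityRaster, retained_mask: np.ndarray
) -> Superhighway:
    """Clip highway polylines to the retained high-density cells.

    Pieces are returned in order along each parent line (clipping is at
    raster-cell granularity; no sub-cell interpolation).
    """
    area = _mask_union(raster, retained_mask)
    segments: list[LineString] = []
    parent_ids: list[str] = []
    if area is not None:
        for hw in highways:
            clipped = hw.polyline.intersection(area)
            pieces = [
                g
                for g in getattr(clipped, "geoms", [clipped])
                if isinstance(g, LineString) and g.length > 0
            ]
            pieces.sort(key=lambda g: hw.polyline.project(shapely.Point(g.coords[0])))
            segments.extend(pieces)
            parent_ids.extend([hw.highway_id] * len(pieces))
    return Superhighway(segments=segments, retained_mask=retained_mask, parent_ids=parent_ids)


def band_mean_density(
    raster: DensityRaster,
    highways: list[HighwayLine],
    band_edges_km: list[float] = (20.0, 40.0, 60.0, 80.0, 100.0),
) -> pd.DataFrame:
    """Mean density in nonoverlapping distance bands around the highways.

    Band k covers cell centers whose distance to the nearest highway lies in
    (edge_{k−1}, edge_k], with the first band [0, edge_1].  Cells beyond the
    last edge are excluded.  Returns columns band_km (upper edge),
    mean_density, n_cells.
    """
    band_edges = list(band_edges_km)
    if any(b <= a for a, b in zip(band_edges, band_edges[1:])):
        raise ValueError("band edges must be strictly increasing")
    cx, cy = raster.cell_centers()
    pts = shapely.points(cx, cy)
    mls = unary_union([hw.polyline for hw in highways])
    dists = shapely.distance(pts, mls)
    vals = raster.values.ravel()
    rows = []
    lower = 0.0
    eps = 1e-9  # guard the closed upper bound against projection round-off
    for upper in band_edges:
        in_band = (dists <= upper + eps) & ((dists > lower + eps) | (lower == 0.0))
        rows.append(
            {
                "band_km": upper,
                "mean_density": float(vals[in_band].mean()) if in_band.any() else float("nan"),
                "n_cells": int(in_band.sum()),
            }
        )
        lower = upper
    return pd.DataFrame(rows)
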