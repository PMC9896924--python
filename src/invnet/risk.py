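"""Invasion-risk statistics around the superhighway.

Distances from lake midpoints to the superhighway, a Welch two-sample
t-test comparing invaded lakes against all lakes, cumulative
distance curves, high-risk (invaded → uninvaded) connections, and the
percentage of weighted incoming connections per county that are high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .core import Lake, RegionUnit
from .density import Superhighway


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_1: float
    mean_2: float

    def format(self) -> str:
        """Report-style rendering, e.g. ``t(3298.5) = 32.477, P < 0.001``."""
        p_txt = "P < 0.001" if self.p < 0.001 else f"P = {self.p:.3f}"
        return f"t({self.df:.1f}) = {self.t:.3f}, {p_txt}"


def distance_to_superhighway(lakes: list[Lake], superhighway: Superhighway) -> pd.Series:
    """Straight-line distance (km) from each lake midpoint to the superhighway."""
    if superhighway.is_empty:
        raise ValueError("superhighway is empty; no distances defined")
    target = unary_union(superhighway.segments)
    pts = shapely.points(
        np.array([lk.midpoint.x for lk in lakes]),
        np.array([lk.midpoint.y for lk in lakes]),
    )
    d = shapely.distance(pts, target)
    return pd.Series(d, index=[lk.lake_id for lk in lakes], name="distance_km")


def welch_t(sample_1, sample_2) -> TTestResult:
    """Welch two-sample t-test (unequal variances, two-sided).

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2) with Welch–Satterthwaite degrees
    of freedom; p from the t distribution.
    """
    a = np.asarray(sample_1, dtype=float)
    b = np.asarray(sample_2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0, a.mean(), b.mean())
        raise ValueError("both samples have zero variance")
    se1, se2 = v1 / len(a), v2 / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (
        se1**2 / (len(a) - 1) + se2**2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(a.mean()), float(b.mean()))


def cumulative_distance_curve(distances, grid) -> pd.DataFrame:
    """Empirical cumulative proportion of lakes within each grid distance."""
    d = np.sort(np.asarray(distances, dtype=float))
    if d.size == 0:
        raise ValueError("no distances supplied")
    g = np.asarray(grid, dtype=float)
    prop = np.searchsorted(d, g, side="right") / d.size
    return pd.DataFrame({"distance_km": g, "proportion": prop})


def high_risk_edges(
    edges: pd.DataFrame, lakes: list[Lake], taxon_set: set[str]
) -> pd.DataFrame:
    """Edges from a lake invaded by any taxon in ``taxon_set`` to a lake not so invaded."""
    inv = {lk.lake_id: bool(lk.invaded_by & taxon_set) for lk in lakes}
    o = edges["origin"].map(lambda i: inv.get(i, False)).astype(bool)
    d = edges["dest"].map(lambda i: inv.get(i, False)).astype(bool)
    return edges[o & ~d].reset_index(drop=True)


def county_risk_pct(
    edges: pd.DataFrame,
    high_risk: pd.DataFrame,
    lakes: list[Lake],
    counties: list[RegionUnit],
) -> pd.DataFrame:
    """Percentage of weighted incoming connections per county that are high-risk.

    Each edge is attributed to the county containing the destination lake's
    midpoint.  Counties with zero incoming weight are flagged no-data (their
    percentage is NaN, not 0).  Raises if county polygons overlap a lake
    midpoint ambiguously.
    """
    geoms = [c.polygon for c in counties]
    tree = STRtree(geoms)
    mid = {
        lk.lake_id: shapely.Point(lk.midpoint.x, lk.midpoint.y) for lk in lakes
    }
    county_of: dict[str, str | None] = {}
    for lake_id, pt in mid.items():
        hits = tree.query(pt, predicate="covered_by")
        if len(hits) > 1:
            raise ValueError(
                f"county polygons overlap at lake {lake_id!r}: "
                + ", ".join(counties[i].region_id for i in hits)
            )
        county_of[lake_id] = counties[hits[0]].region_id if len(hits) else None

    def _sum_by_county(df: pd.DataFrame) -> pd.Series:
        cc = df["dest"].map(county_of)
        return df.groupby(cc)["weight"].sum()

    total = _sum_by_county(edges) if len(edges) else pd.Series(dtype=float)
    risky = _sum_by_county(high_risk) if len(high_risk) else pd.Series(dtype=float)
    rows = []
    for c in counties:
        tw = float(total.get(c.region_id, 0.0))
        hw = float(risky.get(c.region_id, 0.0))
        no_data = tw == 0.0
        rows.append(
            {
                "region_id": c.region_id,
                "total_in_weight": tw,
                "high_risk_in_weight": hw,
                "pct_high_risk": float("nan") if no_data else 100.0 * hw / tw,
                "no_data": no_data,
            }
        )
    return pd.DataFrame(rows)


def movement_medians(movements: pd.DataFrame) -> tuple[float, float]:
    """Sample medians of (day gap, length km) over movements."""
    if movements.empty:
        raise ValueError("no movements")
    return (
        float(np.median(movements["day_gap"].to_numpy(dtype=float))),
        float(np.median(movements["length_km"].to_numpy(dtype=float))),
    )


def movement_risk_fraction(
    movements_or_edges: pd.DataFrame, lakes: list[Lake], taxon_set: set[str]
) -> dict[str, float]:
    """Fraction of movement that is invaded→uninvaded, by count and by weight."""
    inv = {lk.lake_id: bool(lk.invaded_by & taxon_set) for lk in lakes}
    o = movements_or_edges["origin"].map(lambda i: inv.get(i, False)).astype(bool)
    d = movements_or_edges["dest"].map(lambda i: inv.get(i, False)).astype(bool)
    risky = (o & ~d).to_numpy()
    w = movements_or_edges["weight"].to_numpy(dtype=float)
    n = len(movements_or_edges)
    return {
        "count_fraction": float(risky.sum() / n) if n else float("nan"),
        "weight_fraction": float(w[risky].sum() / w.sum()) if w.sum() > 0 else float("nan"),
    }
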