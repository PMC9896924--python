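"""The weighted, directed angler-movement network.

A movement is a consecutive pair of lake visits by one angler.  Its weight
is a log-logistic decay in the whole-day gap d between visits,

    w(d) = a / (1 + (d/b)^c)   for d < cutoff,   w = 0 for d >= cutoff,

with defaults a = 1.023, b = 5.341 days, c = 1.031 and a hard cutoff at
99 days — a survival-derived proxy for how likely invasive propagules are
to survive overland transport.  Summing movement weights per ordered lake
pair yields directed edges whose weight proxies propagule pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EDGE_COLUMNS, MOVEMENT_COLUMNS, Lake
from .geometry import PLANAR, point_distance_km


@dataclass(frozen=True)
class WeightFunctionParams:
    """Parameters of the time-decay weight curve (a, b in days, c, cutoff in days)."""

    a: float = 1.023
    b: float = 5.341
    c: float = 1.031
    cutoff: float = 99.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.cutoff) <= 0:
            raise ValueError("weight-function parameters must all be > 0")


DEFAULT_WEIGHT_PARAMS = WeightFunctionParams()


def movement_weight(d, params: WeightFunctionParams = DEFAULT_WEIGHT_PARAMS):
    """Evaluate the time-decay weight at day gap(s) ``d``.

    Accepts scalars or arrays; raises on negative gaps.  The printed
    closed form is used verbatim — w(0) = a = 1.023 slightly exceeds 1 and
    is deliberately not clipped.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("day gap must be >= 0")
    with np.errstate(divide="ignore"):
        w = params.a / (1.0 + (d_arr / params.b) ** params.c)
    w = np.where(d_arr >= params.cutoff, 0.0, w)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(w)
    return w


def extract_visits(assignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse assigned catches into per-user ordered visit lists.

    Input columns: user_id, timestamp, lake_id.  Records are sorted by user
    and time; consecutive records at the same lake on the same calendar day
    collapse to a single visit.  Returns columns user_id, date, lake_id.
    """
    df = assignments[["user_id", "timestamp", "lake_id"]].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values(["user_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    df["date"] = df["timestamp"].dt.normalize()
    same_user = df["user_id"].eq(df["user_id"].shift())
    dup = same_user & df["lake_id"].eq(df["lake_id"].shift()) & df["date"].eq(df["date"].shift())
    return df.loc[~dup, ["user_id", "date", "lake_id"]].reset_index(drop=True)


def extract_movements(
    visits: pd.DataFrame,
    lakes: list[Lake],
    params: WeightFunctionParams = DEFAULT_WEIGHT_PARAMS,
    crs_mode: str = PLANAR,
) -> pd.DataFrame:
    """Turn consecutive visit pairs into weighted movements.

    For each consecutive pair of one user's visits at different lakes, emit
    a movement with d = whole-day calendar gap, straight-line
    midpoint-to-midpoint length in km, and weight w(d).  Pairs at the same
    lake emit nothing; movements with w = 0 (d >= cutoff) are discarded so
    they can never contribute zero-weight edges.
    """
    if visits.empty:
        return pd.DataFrame(columns=MOVEMENT_COLUMNS)
    v = visits.reset_index(drop=True)
    nxt = v.shift(-1)
    same_user = v["user_id"].eq(nxt["user_id"])
    pairs = pd.DataFrame(
        {
            "user_id": v["user_id"],
            "origin": v["lake_id"],
            "dest": nxt["lake_id"],
            "day_gap": (nxt["date"] - v["date"]).dt.days,
        }
    )[same_user & v["lake_id"].ne(nxt["lake_id"])]
    if pairs.empty:
        return pd.DataFrame(columns=MOVEMENT_COLUMNS)
    mid = {lk.lake_id: (lk.midpoint.x, lk.midpoint.y) for lk in lakes}
    ox = pairs["origin"].map(lambda i: mid[i][0]).to_numpy()
    oy = pairs["origin"].map(lambda i: mid[i][1]).to_numpy()
    dx = pairs["dest"].map(lambda i: mid[i][0]).to_numpy()
    dy = pairs["dest"].map(lambda i: mid[i][1]).to_numpy()
    pairs["length_km"] = point_distance_km(ox, oy, dx, dy, crs_mode)
    pairs["weight"] = movement_weight(pairs["day_gap"].to_numpy(dtype=float), params)
    pairs = pairs[pairs["weight"] > 0.0]
    return pairs.reset_index(drop=True)[MOVEMENT_COLUMNS]


def filter_implausible(
    movements: pd.DataFrame,
    travel_filters: list[tuple[int, float]] = ((0, 250.0), (1, 500.0), (2, 1500.0)),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop movements implying implausible travel speed.

    ``travel_filters`` maps a day gap to the maximum plausible straight-line
    distance (strictly greater removes): same-day > 250 km, next-day
    > 500 km, 2-day > 1,500 km by default.  Gaps without a rule are always
    kept.  Returns (kept, removed).
    """
    bad = np.zeros(len(movements), dtype=bool)
    for gap, max_km in travel_filters:
        bad |= (movements["day_gap"].to_numpy() == gap) & (
            movements["length_km"].to_numpy() > max_km
        )
    return (
        movements[~bad].reset_index(drop=True),
        movements[bad].reset_index(drop=True),
    )


def drop_same_name(
    movements: pd.DataFrame, lakes: list[Lake]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop movements between two lakes sharing a name (likely logging errors).

    Names are compared case-folded and whitespace-trimmed; movements where
    either lake is unnamed are kept.
    """
    norm = {
        lk.lake_id: lk.name.strip().casefold()
        for lk in lakes
        if lk.name is not None and lk.name.strip()
    }
    o = movements["origin"].map(norm)
    d = movements["dest"].map(norm)
    bad = (o.notna() & d.notna() & o.eq(d)).to_numpy()
    return (
        movements[~bad].reset_index(drop=True),
        movements[bad].reset_index(drop=True),
    )


def aggregate_edges(movements: pd.DataFrame) -> pd.DataFrame:
    """Sum movement weights per ordered lake pair into directed edges.

    A→B and B→A are distinct edges; the edge length is the (common)
    movement length for the pair.
    """
    if movements.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    edges = (
        movements.groupby(["origin", "dest"], sort=True)
        .agg(weight=("weight", "sum"), n_movements=("weight", "size"), length_km=("length_km", "first"))
        .reset_index()
    )
    return edges[EDGE_COLUMNS]


def apply_merges(
    edges: pd.DataFrame,
    merge_map: dict[str, str],
    lakes: list[Lake],
    crs_mode: str = PLANAR,
) -> tuple[pd.DataFrame, int]:
    """Remap edge endpoints onto merge-cluster representatives.

    Edges whose endpoints land in the same cluster are deleted (the member
    lakes are now one node); parallel edges re-sum; lengths are recomputed
    from representative midpoints.  Returns (edges, n_deleted_movements)
    where the count tallies movements lost to intra-cluster deletion.
    """
    if edges.empty or not merge_map:
        return edges.copy(), 0
    e = edges.copy()
    e["origin"] = e["origin"].map(lambda i: merge_map.get(i, i))
    e["dest"] = e["dest"].map(lambda i: merge_map.get(i, i))
    self_loops = e["origin"].eq(e["dest"])
    n_deleted = int(e.loc[self_loops, "n_movements"].sum())
    e = e[~self_loops]
    if e.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS), n_deleted
    merged = (
        e.groupby(["origin", "dest"], sort=True)
        .agg(weight=("weight", "sum"), n_movements=("n_movements", "sum"))
        .reset_index()
    )
    mid = {lk.lake_id: (lk.midpoint.x, lk.midpoint.y) for lk in lakes}
    ox = merged["origin"].map(lambda i: mid[i][0]).to_numpy()
    oy = merged["origin"].map(lambda i: mid[i][1]).to_numpy()
    dx = merged["dest"].map(lambda i: mid[i][0]).to_numpy()
    dy = merged["dest"].map(lambda i: mid[i][1]).to_numpy()
    merged["length_km"] = point_distance_km(ox, oy, dx, dy, crs_mode)
    return merged[EDGE_COLUMNS], n_deleted
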