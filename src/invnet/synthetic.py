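"""Synthetic landscapes, hydrology, catch logs, occurrences and regions.

The generator produces data with the statistical structure the analysis
assumes, so every downstream stage runs without any proprietary or national
dataset: Thomas-cluster lake placement, a forest of strictly-downhill
flowline connections with flow-permanence classes, per-angler catch
sequences with log-logistic inter-catch intervals (median 7 days) and
distance-decayed lake choice calibrated to a 20-km median hop, invasions
clustered near highway corridors, and simple highway/county/basin layers.

Several features are planted deliberately so filters can be tested for
exactness: a configurable count of same-day long-distance movements (the
only movements violating the travel-speed rules — organic movement is
constrained inside those limits at generation time), lake pairs separated
by < 40 m of permanent stream, sub-minimum lake areas, duplicate lake
names, and catch points more than 50 m outside any lake (always a user's
final catch, so dropping them never splices two other movements together).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .core import Basin, CatchLog, FlowSegment, HighwayLine, Lake, RegionUnit

MIN_FISHABLE_HA = 0.06


@dataclass
class SynthParams:
    """Parameters of the synthetic study system (planar km coordinates)."""

    n_lakes: int = 500
    extent_km: tuple[float, float] = (400.0, 400.0)
    cluster_intensity: float = 1.5  # parent points per 10^4 km^2
    cluster_sd_km: float = 20.0
    fraction_below_min: float = 0.05  # lakes planted below the 0.06-ha cutoff
    dup_name_frac: float = 0.01

    n_users: int = 200
    catches_per_user_mean: float = 120.0
    catches_per_user_dispersion: float = 1.5
    interval_median_days: float = 7.0
    interval_shape: float = 1.6  # log-logistic shape; >1 keeps the mode interior
    hop_median_km: float = 20.0
    hop_tail: float = 2.5  # Pareto-like tail index of the lake-choice kernel
    approx_only_frac: float = 0.10
    approx_with_exact_frac: float = 0.50
    outside_frac: float = 0.01  # users whose final catch is unassignable
    planted_implausible: int = 5

    connect_frac: float = 0.6  # lakes participating in hydrology
    link_radius_km: float = 40.0
    link_prob: float = 0.8
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "perennial": 0.60,
            "intermittent": 0.25,
            "ephemeral": 0.10,
            "unclassified": 0.05,
        }
    )
    excluded_class_frac: float = 0.05
    merge_pairs: int = 3

    invasion_prevalence: float = 0.15
    invasion_clustering: float = 30.0  # km scale of decay from highways

    n_highways: int = 3
    region_grid: tuple[int, int] = (6, 6)
    n_basins: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.invasion_prevalence <= 1.0:
            raise ValueError("invasion_prevalence must be in [0, 1]")
        if self.interval_median_days <= 0 or self.hop_median_km <= 0:
            raise ValueError("medians must be > 0")
        if min(self.n_lakes, self.n_users, self.n_highways) < 0:
            raise ValueError("counts must be >= 0")


def _rng(p: SynthParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([p.seed, stream])


_MARGIN_KM = 10.0


def generate_lakescape(p: SynthParams) -> list[Lake]:
    """Thomas-cluster placed lakes with log-normal areas and jittered circular polygons."""
    rng = _rng(p, 1)
    w, h = p.extent_km
    if (w - 2 * _MARGIN_KM) <= 0 or (h - 2 * _MARGIN_KM) <= 0:
        raise ValueError("extent too small for lake placement margin")
    area_1e4 = w * h / 1e4
    n_parents = max(1, rng.poisson(p.cluster_intensity * area_1e4))
    px = rng.uniform(_MARGIN_KM, w - _MARGIN_KM, n_parents)
    py = rng.uniform(_MARGIN_KM, h - _MARGIN_KM, n_parents)

    xs = np.empty(p.n_lakes)
    ys = np.empty(p.n_lakes)
    parent = rng.integers(0, n_parents, p.n_lakes)
    remaining = np.arange(p.n_lakes)
    while remaining.size:
        cx = px[parent[remaining]] + rng.normal(0, p.cluster_sd_km, remaining.size)
        cy = py[parent[remaining]] + rng.normal(0, p.cluster_sd_km, remaining.size)
        ok = (cx > _MARGIN_KM) & (cx < w - _MARGIN_KM) & (cy > _MARGIN_KM) & (cy < h - _MARGIN_KM)
        xs[remaining[ok]] = cx[ok]
        ys[remaining[ok]] = cy[ok]
        remaining = remaining[~ok]

    small = rng.random(p.n_lakes) < p.fraction_below_min
    areas = np.exp(rng.normal(np.log(5.0), 1.2, p.n_lakes))  # ha; mostly fishable
    areas = np.clip(areas, 0.08, 500.0)
    areas[small] = rng.uniform(0.005, 0.055, small.sum())

    names = [f"Lake {i:05d}" for i in range(p.n_lakes)]
    n_dup = int(round(p.dup_name_frac * p.n_lakes))
    if n_dup and p.n_lakes > 1:
        dup_idx = rng.choice(np.arange(1, p.n_lakes), size=min(n_dup, p.n_lakes - 1), replace=False)
        for i in dup_idx:
            names[i] = names[rng.integers(0, i)]

    lakes = []
    for i in range(p.n_lakes):
        r_km = np.sqrt((areas[i] / 100.0) / np.pi)  # ha -> km^2 -> radius
        poly = Point(xs[i], ys[i]).buffer(r_km * rng.uniform(0.9, 1.1), quad_segs=8)
        lakes.append(Lake(lake_id=f"L{i:05d}", polygon=poly, area_ha=float(areas[i]), name=names[i]))
    return lakes


def generate_hydrology(lakes: list[Lake], p: SynthParams) -> list[FlowSegment]:
    """A forest of strictly-downhill flowline connections plus planted features.

    Every segment points from a higher- to a lower-elevation node, so the
    downstream relation is acyclic by construction.  Organic segments are at
    least 100 m long; the only sub-40-m permanent segments are the
    ``merge_pairs`` planted pairs.
    """
    rng = _rng(p, 2)
    n = len(lakes)
    elev = rng.permutation(n).astype(float)  # distinct ranks as elevation
    xy = np.array([(lk.midpoint.x, lk.midpoint.y) for lk in lakes])
    ids = [lk.lake_id for lk in lakes]

    participating = np.flatnonzero(rng.random(n) < p.connect_frac)
    classes = list(p.class_probs)
    class_p = np.array([p.class_probs[c] for c in classes], dtype=float)
    class_p = class_p / class_p.sum()

    segments: list[FlowSegment] = []
    n_junction = 0
    n_links = 0
    for i in participating:
        d = np.hypot(xy[participating, 0] - xy[i, 0], xy[participating, 1] - xy[i, 1])
        lower = (elev[participating] < elev[i]) & (d <= p.link_radius_km) & (d > 0)
        if not lower.any() or rng.random() > p.link_prob:
            continue
        j = participating[lower][np.argmin(d[lower])]
        length_m = max(100.0, float(np.hypot(*(xy[j] - xy[i]))) * 1000.0 * rng.uniform(1.1, 1.5))
        n_links += 1
        if rng.random() < 0.5:
            segments.append(
                FlowSegment(ids[i], ids[j], classes[rng.choice(len(classes), p=class_p)], length_m)
            )
        else:  # through a junction node
            jid = f"J{n_junction:05d}"
            n_junction += 1
            split = rng.uniform(0.3, 0.7)
            for a, b, frac in ((ids[i], jid, split), (jid, ids[j], 1 - split)):
                segments.append(
                    FlowSegment(a, b, classes[rng.choice(len(classes), p=class_p)], length_m * frac)
                )

    n_excluded = int(round(p.excluded_class_frac * max(n_links, 1)))
    excluded_classes = ["ditch", "canal", "pipeline"]
    for _ in range(n_excluded):
        i, j = rng.choice(n, size=2, replace=False)
        if elev[i] < elev[j]:
            i, j = j, i
        segments.append(
            FlowSegment(ids[i], ids[j], excluded_classes[rng.integers(0, 3)], float(rng.uniform(200, 5000)))
        )

    # Merge pairs use lakes outside the drainage forest: a merged cluster
    # with independent through-flow could make the collapsed flow relation
    # cyclic, which consistent hydrology never does.
    participating_set = set(int(k) for k in participating)
    used: set[int] = set()
    for _ in range(p.merge_pairs):
        free = [k for k in range(n) if k not in used and k not in participating_set]
        if len(free) < 2:
            break
        i = int(rng.choice(free))
        others = [k for k in free if k != i]
        d = np.hypot(xy[others, 0] - xy[i, 0], xy[others, 1] - xy[i, 1])
        j = others[int(np.argmin(d))]
        used.update((i, j))
        if elev[i] < elev[j]:
            i, j = j, i
        segments.append(FlowSegment(ids[i], ids[j], "perennial", float(rng.uniform(10.0, 35.0))))
    return segments


def _log_logistic(rng: np.random.Generator, median: float, shape: float, size: int) -> np.ndarray:
    u = rng.uniform(1e-12, 1 - 1e-12, size)
    return median * (u / (1.0 - u)) ** (1.0 / shape)


def _hop_kernel(d: np.ndarray, scale: float, tail: float) -> np.ndarray:
    return (1.0 + d / scale) ** (-tail)


def calibrate_hop_scale(
    dist: np.ndarray, target_median_km: float, tail: float, rng: np.random.Generator
) -> float:
    """Kernel scale such that the kernel-weighted median hop equals the target.

    Uses a sample of origin lakes and bisects on the scale; the weighted
    median of pairwise distances is monotone in the scale.
    """
    n = dist.shape[0]
    sample = rng.choice(n, size=min(n, 300), replace=False)

    def realized_median(scale: float) -> float:
        meds = []
        for i in sample:
            d = dist[i].copy()
            d[i] = np.inf
            w = _hop_kernel(d, scale, tail)
            w[~np.isfinite(d)] = 0.0
            if w.sum() == 0:
                continue
            order = np.argsort(d)
            cw = np.cumsum(w[order]) / w.sum()
            meds.append(d[order][np.searchsorted(cw, 0.5)])
        return float(np.median(meds))

    lo, hi = 0.05, 5000.0
    for _ in range(50):
        mid = np.sqrt(lo * hi)
        if realized_median(mid) < target_median_km:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# Travel-speed limits imposed on organic movement generation: slightly
# inside the analysis filters (250/500/1500 km at day gaps 0/1/2) so only
# planted movements can violate them, even after small assignment shifts.
_SAFE_LIMITS = {0: 245.0, 1: 490.0, 2: 1470.0}


def _point_in_lake(lake: Lake, rng: np.random.Generator) -> tuple[float, float]:
    c = lake.polygon.centroid
    r = np.sqrt(lake.polygon.area / np.pi)
    rho = r * 0.4 * np.sqrt(rng.random())
    theta = rng.uniform(0, 2 * np.pi)
    return c.x + rho * np.cos(theta), c.y + rho * np.sin(theta)


def generate_catch_log(lakes: list[Lake], p: SynthParams) -> CatchLog:
    """Per-user catch sequences with heavy-tailed gaps and distance-decayed hops.

    Anglers visit fishable lakes only (sub-minimum ponds exist to exercise
    the area filter on the lake side).  Inter-catch gaps are log-logistic
    with the configured median; the next lake is drawn with probability
    decaying in distance so that the realized hop-length median matches
    ``hop_median_km``; candidates are masked to the travel-speed limits for
    the realized day gap.
    """
    rng = _rng(p, 3)
    fishable = [lk for lk in lakes if lk.area_ha > MIN_FISHABLE_HA]
    if len(fishable) < 2:
        raise ValueError("need at least 2 fishable lakes")
    xy = np.array([(lk.midpoint.x, lk.midpoint.y) for lk in fishable])
    n = len(fishable)
    dist = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    hop_scale = calibrate_hop_scale(dist, p.hop_median_km, p.hop_tail, rng)

    nb_n = p.catches_per_user_dispersion
    nb_p = nb_n / (nb_n + p.catches_per_user_mean)
    epoch = pd.Timestamp("2018-01-01")

    outside_users = set(
        rng.choice(p.n_users, size=int(round(p.outside_frac * p.n_users)), replace=False)
    ) if p.n_users else set()

    rows: list[tuple] = []
    for u in range(p.n_users):
        n_catches = max(2, int(rng.negative_binomial(nb_n, nb_p)))
        cur = int(rng.integers(0, n))
        t = float(rng.uniform(0, 365)) + float(rng.uniform(0, 1))
        gaps = _log_logistic(rng, p.interval_median_days, p.interval_shape, n_catches - 1)
        lake_seq = [cur]
        times = [t]
        for g in gaps:
            t_next = t + g
            day_gap = int(np.floor(t_next) - np.floor(t))
            limit = _SAFE_LIMITS.get(day_gap)
            d = dist[cur].copy()
            w = _hop_kernel(d, hop_scale, p.hop_tail)
            w[cur] = 0.0
            if limit is not None:
                w[d > limit] = 0.0
            if w.sum() == 0:
                w = _hop_kernel(d, hop_scale, p.hop_tail)
                w[cur] = 0.0
            cur = int(rng.choice(n, p=w / w.sum()))
            t = t_next
            lake_seq.append(cur)
            times.append(t)
        for k, (li, ti) in enumerate(zip(lake_seq, times)):
            lake = fishable[li]
            ex, ey = _point_in_lake(lake, rng)
            ax, ay = lake.midpoint.x, lake.midpoint.y
            r = rng.random()
            if u in outside_users and k == len(lake_seq) - 1:
                ex, ey = _outside_point(lakes, p, rng)
                ax = ay = np.nan
            elif r < p.approx_only_frac:
                ex = ey = np.nan
            elif r > p.approx_only_frac + p.approx_with_exact_frac:
                ax = ay = np.nan
            rows.append((f"u{u:05d}", epoch + pd.to_timedelta(ti, unit="D"), ex, ey, ax, ay))

    rows.extend(_planted_implausible_rows(fishable, p, rng, epoch))
    records = pd.DataFrame(
        rows, columns=["user_id", "timestamp", "exact_x", "exact_y", "approx_x", "approx_y"]
    )
    return CatchLog(records=records, drop_counts={})


def _outside_point(lakes: list[Lake], p: SynthParams, rng: np.random.Generator) -> tuple[float, float]:
    """A point more than 50 m from every lake polygon (assignment must fail)."""
    w, h = p.extent_km
    geoms = np.array([lk.polygon for lk in lakes], dtype=object)
    tree = shapely.STRtree(list(geoms))
    for _ in range(1000):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        if len(tree.query(Point(x, y), predicate="dwithin", distance=0.06)) == 0:
            return x, y
    raise RuntimeError("could not place a point clear of all lakes")


def _planted_implausible_rows(fishable, p, rng, epoch) -> list[tuple]:
    """Same-day >260-km lake pairs: the only travel-filter violations."""
    rows = []
    by_name: dict[str, int] = {}
    for lk in fishable:
        by_name[lk.name] = by_name.get(lk.name, 0) + 1
    unique_named = [lk for lk in fishable if by_name[lk.name] == 1]
    for k in range(p.planted_implausible):
        for _ in range(5000):
            a, b = rng.choice(len(unique_named), size=2, replace=False)
            la, lb = unique_named[a], unique_named[b]
            if la.midpoint.distance(lb.midpoint) > 260.0:
                break
        else:
            raise RuntimeError("extent too small to plant implausible movements")
        day = epoch + pd.Timedelta(days=400 + k)
        for lk, hour in ((la, 8), (lb, 10)):
            rows.append(
                (
                    f"uimp{k:03d}",
                    day + pd.Timedelta(hours=hour),
                    lk.midpoint.x,
                    lk.midpoint.y,
                    np.nan,
                    np.nan,
                )
            )
    return rows


def generate_highways_and_regions(
    p: SynthParams,
) -> tuple[list[HighwayLine], list[RegionUnit], list[Basin]]:
    """Highway corridors crossing the extent, a county grid, and basin strips."""
    rng = _rng(p, 4)
    w, h = p.extent_km
    highways = []
    for i in range(p.n_highways):
        horizontal = i % 2 == 0
        span, cross = (w, h) if horizontal else (h, w)
        c0, c1 = rng.uniform(0.15 * cross, 0.85 * cross, 2)
        fracs = np.linspace(0.0, 1.0, 5)
        cs = c0 + (c1 - c0) * fracs
        cs[1:-1] += rng.normal(0, cross / 25.0, 3)
        pts = [(f * span, c) if horizontal else (c, f * span) for f, c in zip(fracs, cs)]
        highways.append(HighwayLine(highway_id=f"H{i:02d}", polyline=LineString(pts)))

    rows, cols = p.region_grid
    counties = [
        RegionUnit(
            region_id=f"C{r:02d}{c:02d}",
            polygon=box(c * w / cols, r * h / rows, (c + 1) * w / cols, (r + 1) * h / rows),
        )
        for r in range(rows)
        for c in range(cols)
    ]

    n_basins = int(np.clip(p.n_basins, 2, 4))
    cuts = np.sort(rng.uniform(0.2 * w, 0.8 * w, n_basins - 1))
    bounds = np.concatenate(([0.0], cuts, [w]))
    basins = [
        Basin(basin_id=f"B{i:02d}", polygon=box(bounds[i], 0.0, bounds[i + 1], h))
        for i in range(n_basins)
    ]
    return highways, counties, basins


def generate_occurrences(
    lakes: list[Lake], highways: list[HighwayLine], p: SynthParams
) -> pd.DataFrame:
    """Occurrence points for the two taxon groups, clustered near highways.

    Lakes are selected without replacement with probability decaying
    exponentially in distance to the nearest highway (scale
    ``invasion_clustering``); the selected fraction of fishable lakes equals
    the configured prevalence.  Returns columns taxon_group, x, y.
    """
    rng = _rng(p, 5)
    fishable = [lk for lk in lakes if lk.area_ha > MIN_FISHABLE_HA]
    n_inv = int(round(p.invasion_prevalence * len(fishable)))
    if n_inv == 0 or not highways:
        return pd.DataFrame(columns=["taxon_group", "x", "y"])
    hw_union = unary_union([hw.polyline for hw in highways])
    pts = shapely.points(
        np.array([lk.midpoint.x for lk in fishable]),
        np.array([lk.midpoint.y for lk in fishable]),
    )
    d = shapely.distance(pts, hw_union)
    w = np.exp(-d / p.invasion_clustering)
    chosen = rng.choice(len(fishable), size=n_inv, replace=False, p=w / w.sum())
    rows = []
    for i in chosen:
        lake = fishable[i]
        r = rng.random()
        taxa = ["dreissena"] if r < 0.4 else ["myriophyllum"] if r < 0.8 else ["dreissena", "myriophyllum"]
        for taxon in taxa:
            for _ in range(rng.integers(1, 3)):
                x, y = _point_in_lake(lake, rng)
                rows.append((taxon, x, y))
    return pd.DataFrame(rows, columns=["taxon_group", "x", "y"])


@dataclass
class SyntheticDataset:
    lakes: list[Lake]
    segments: list[FlowSegment]
    catch_log: CatchLog
    occurrences: pd.DataFrame
    highways: list[HighwayLine]
    counties: list[RegionUnit]
    basins: list[Basin]


def generate_all(p: SynthParams) -> SyntheticDataset:
    """Generate every layer of one synthetic study system."""
    lakes = generate_lakescape(p)
    segments = generate_hydrology(lakes, p)
    catch_log = generate_catch_log(lakes, p)
    highways, counties, basins = generate_highways_and_regions(p)
    occurrences = generate_occurrences(lakes, highways, p)
    return SyntheticDataset(lakes, segments, catch_log, occurrences, highways, counties, basins)
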