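"""End-to-end pipeline: catches → networks → superhighway → risk tables.

Each stage logs its record counts to the module logger, and every dropped
record is tallied, so input = kept + dropped at every stage.  A fixed
configuration and seed yield byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from . import angler, assignment, density, hydrology, metrics, risk
from .config import PipelineConfig
from .core import TAXON_GROUPS, Basin, CatchLog, Lake, RegionUnit
from .synthetic import SyntheticDataset, SynthParams, generate_all

logger = logging.getLogger("invnet")


@dataclass
class ResultBundle:
    """Everything one pipeline run produces."""

    lakes: list[Lake]
    merge_map: dict[str, str]
    angler_edges: pd.DataFrame
    hydro_edges: pd.DataFrame
    movements: pd.DataFrame
    angler_summary: metrics.NetworkSummary
    hydro_summary: metrics.NetworkSummary
    comparison: metrics.ComparisonCounts
    basin_matrix: pd.DataFrame
    raster: density.DensityRaster
    retained_mask: np.ndarray
    superhighway: density.Superhighway
    band_table: pd.DataFrame
    distances: pd.Series | None
    ttests: dict[str, risk.TTestResult]
    curves: dict[str, pd.DataFrame]
    high_risk: pd.DataFrame
    county_table: pd.DataFrame
    risk_fraction: dict[str, float]
    hub_table: pd.DataFrame
    movement_medians: tuple[float, float] | None
    stage_counts: dict[str, int] = field(default_factory=dict)


def _region_of_midpoints(lakes: list[Lake], regions) -> dict[str, str]:
    """Map each lake to the region covering its midpoint (ties: lowest id)."""
    if not regions:
        return {}
    ids = sorted(range(len(regions)), key=lambda i: _rid(regions[i]))
    geoms = [regions[i].polygon for i in ids]
    tree = STRtree(geoms)
    out = {}
    pts = shapely.points(
        np.array([lk.midpoint.x for lk in lakes]),
        np.array([lk.midpoint.y for lk in lakes]),
    )
    li, ri = tree.query(pts, predicate="covered_by")
    for lake_pos, region_pos in sorted(zip(li, ri), key=lambda t: (t[0], t[1])):
        lake_id = lakes[lake_pos].lake_id
        out.setdefault(lake_id, _rid(regions[ids[region_pos]]))
    return out


def _rid(region) -> str:
    return getattr(region, "region_id", None) or getattr(region, "basin_id")


def run_pipeline(config: PipelineConfig, data: SyntheticDataset) -> ResultBundle:
    """Run the full analysis on one dataset (see module docstring)."""
    counts: dict[str, int] = {}

    def stage(name: str, **vals: int) -> None:
        for k, v in vals.items():
            counts[f"{name}.{k}"] = int(v)
        logger.info("%s: %s", name, ", ".join(f"{k}={v}" for k, v in vals.items()))

    # --- fishable lakes -------------------------------------------------
    fishable = assignment.filter_fishable(data.lakes, config.min_lake_area_ha)
    stage("fishable_filter", input=len(data.lakes), kept=len(fishable),
          dropped=len(data.lakes) - len(fishable))

    # --- catch assignment ----------------------------------------------
    assigned, drops = assignment.assign_catches(
        data.catch_log, fishable, config.assignment_buffer_m
    )
    stage("assignment", input=len(data.catch_log), kept=len(assigned),
          dropped=drops["unassignable"])

    # --- movements ------------------------------------------------------
    visits = angler.extract_visits(assigned)
    movements = angler.extract_movements(visits, fishable, config.weight_params, config.crs_mode)
    kept, removed = angler.filter_implausible(movements, config.travel_filters)
    stage("travel_filter", input=len(movements), kept=len(kept), removed=len(removed))
    kept, removed_names = angler.drop_same_name(kept, fishable)
    stage("same_name_filter", kept=len(kept), removed=len(removed_names))
    movements = kept

    # --- hydrologic merge clusters and both edge sets -------------------
    merge_map = hydrology.find_merge_clusters(fishable, data.segments, config.merge_threshold_m)
    edges = angler.aggregate_edges(movements)
    edges, n_merged_away = angler.apply_merges(edges, merge_map, fishable, config.crs_mode)
    stage("angler_edges", edges=len(edges), movements_deleted_by_merge=n_merged_away)
    hydro_edges = hydrology.build_downstream_edges(fishable, data.segments, merge_map)
    stage("hydro_edges", edges=len(hydro_edges))

    # merged node universe: cluster members collapse onto representatives
    universe = [lk for lk in fishable if merge_map.get(lk.lake_id, lk.lake_id) == lk.lake_id]

    # --- invasion status (members transfer status to representatives) ---
    assignment.mark_invaded(fishable, data.occurrences, config.assignment_buffer_m)
    by_id = {lk.lake_id: lk for lk in universe}
    for lk in fishable:
        rep = merge_map.get(lk.lake_id, lk.lake_id)
        if rep != lk.lake_id and lk.invaded_by:
            by_id[rep].invaded_by |= lk.invaded_by
    stage("invaded_lakes", n=sum(1 for lk in universe if lk.invaded_by))

    # --- network statistics and comparison ------------------------------
    node_ids = [lk.lake_id for lk in universe]
    angler_summary = metrics.summarize(node_ids, edges, config.diameter_mode)
    hydro_nodes = sorted(set(hydro_edges["origin"]) | set(hydro_edges["dest"]))
    hydro_summary = metrics.summarize(hydro_nodes, hydro_edges, config.diameter_mode)
    comparison = metrics.compare_networks(edges, hydro_edges)

    basin_of = _region_of_midpoints(universe, data.basins)
    basin_matrix = (
        metrics.basin_flow_matrix(edges, basin_of)
        if len(edges) and basin_of
        else pd.DataFrame()
    )

    # --- density raster and superhighway --------------------------------
    xs = [lk.midpoint.x for lk in universe]
    ys = [lk.midpoint.y for lk in universe]
    for hw in data.highways:
        bx = hw.polyline.bounds
        xs.extend([bx[0], bx[2]])
        ys.extend([bx[1], bx[3]])
    extent = (
        float(np.floor(min(xs))), float(np.floor(min(ys))),
        float(np.ceil(max(xs))), float(np.ceil(max(ys))),
    )
    midpoints = {lk.lake_id: (lk.midpoint.x, lk.midpoint.y) for lk in universe}
    raster = density.line_density(
        edges, midpoints, extent, config.density_cell_km, config.density_radius_km
    )
    retained = density.threshold_density(raster, config.density_exclude_pct)
    superhighway = density.extract_superhighway(data.highways, raster, retained)
    band_table = (
        density.band_mean_density(raster, data.highways, config.band_edges_km)
        if data.highways
        else pd.DataFrame(columns=["band_km", "mean_density", "n_cells"])
    )
    stage("density", retained_cells=int(retained.sum()),
          superhighway_segments=len(superhighway.segments))

    # --- distances and t-tests ------------------------------------------
    distances = None
    ttests: dict[str, risk.TTestResult] = {}
    curves: dict[str, pd.DataFrame] = {}
    if not superhighway.is_empty and universe:
        distances = risk.distance_to_superhighway(universe, superhighway)
        grid = np.linspace(0.0, float(distances.max()), 101)
        curves["all"] = risk.cumulative_distance_curve(distances.to_numpy(), grid)
        for taxon in TAXON_GROUPS + ("any",):
            taxa = set(TAXON_GROUPS) if taxon == "any" else {taxon}
            inv_ids = [lk.lake_id for lk in universe if lk.invaded_by & taxa]
            if len(inv_ids) >= 2:
                sample = distances.loc[inv_ids].to_numpy()
                ttests[taxon] = risk.welch_t(sample, distances.to_numpy())
                curves[taxon] = risk.cumulative_distance_curve(sample, grid)

    # --- high-risk connections and county risk --------------------------
    taxon_all = set(TAXON_GROUPS)
    high_risk = risk.high_risk_edges(edges, universe, taxon_all)
    county_table = (
        risk.county_risk_pct(edges, high_risk, universe, data.counties)
        if data.counties
        else pd.DataFrame()
    )
    risk_fraction = (
        risk.movement_risk_fraction(movements, universe, taxon_all)
        if len(movements)
        else {"count_fraction": float("nan"), "weight_fraction": float("nan")}
    )
    stage("risk", high_risk_edges=len(high_risk))

    # --- hubs ------------------------------------------------------------
    county_of = _region_of_midpoints(universe, data.counties)
    hub_table = metrics.identify_hubs(edges, universe, county_of, config.hub_top_k)

    med = risk.movement_medians(movements) if len(movements) else None

    return ResultBundle(
        lakes=universe,
        merge_map=merge_map,
        angler_edges=edges,
        hydro_edges=hydro_edges,
        movements=movements,
        angler_summary=angler_summary,
        hydro_summary=hydro_summary,
        comparison=comparison,
        basin_matrix=basin_matrix,
        raster=raster,
        retained_mask=retained,
        superhighway=superhighway,
        band_table=band_table,
        distances=distances,
        ttests=ttests,
        curves=curves,
        high_risk=high_risk,
        county_table=county_table,
        risk_fraction=risk_fraction,
        hub_table=hub_table,
        movement_medians=med,
        stage_counts=counts,
    )


def run_synthetic(config: PipelineConfig, params: SynthParams | None = None) -> ResultBundle:
    """Generate a synthetic dataset (seeded from the config) and run the pipeline."""
    if params is None:
        params = SynthParams(seed=config.seed)
    return run_pipeline(config, generate_all(params))


def write_outputs(bundle: ResultBundle, out_dir: str | Path) -> None:
    """Write the bundle's tables, edge lists, raster and geometries to a directory."""
    from . import io as io_mod
    import json
    from dataclasses import asdict
    from shapely.geometry import mapping

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_edge_list(bundle.angler_edges, out / "angler_edges.csv")
    io_mod.write_edge_list(bundle.hydro_edges, out / "hydro_edges.csv")
    io_mod.write_graphml(bundle.angler_edges, out / "angler_network.graphml")
    pd.DataFrame(
        sorted(bundle.merge_map.items()), columns=["member_id", "representative_id"]
    ).to_csv(out / "merge_map.csv", index=False)
    summaries = {
        "angler": asdict(bundle.angler_summary),
        "hydro": asdict(bundle.hydro_summary),
        "comparison": asdict(bundle.comparison),
        "risk_fraction": bundle.risk_fraction,
        "movement_medians": bundle.movement_medians,
        "ttests": {k: asdict(v) for k, v in bundle.ttests.items()},
        "stage_counts": bundle.stage_counts,
    }
    (out / "summary.json").write_text(json.dumps(summaries, indent=2))
    if len(bundle.basin_matrix):
        bundle.basin_matrix.to_csv(out / "basin_flow_matrix.csv")
    bundle.band_table.to_csv(out / "band_density.csv", index=False)
    bundle.county_table.to_csv(out / "county_risk.csv", index=False)
    bundle.hub_table.to_csv(out / "hubs.csv", index=False)
    io_mod.write_ascii_grid(bundle.raster, out / "density.asc")
    sh_feats = [
        {"type": "Feature", "geometry": mapping(seg), "properties": {"parent": pid}}
        for seg, pid in zip(bundle.superhighway.segments, bundle.superhighway.parent_ids)
    ]
    (out / "superhighway.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": sh_feats})
    )
    if bundle.distances is not None:
        bundle.distances.rename_axis("lake_id").reset_index().to_csv(
            out / "distance_to_superhighway.csv", index=False
        )
        for name, curve in bundle.curves.items():
            curve.to_csv(out / f"curve_{name}.csv", index=False)
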