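"""Global and node-level network statistics, comparison, and hubs.

Conventions follow common usage for movement networks: components are weak
(direction ignored for membership), density is directed
(m / n(n-1)), reciprocity is the fraction of directed edges whose reverse
also exists, and the diameter is the longest shortest path within the
largest component — either in hops or with edge weight as traversal cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path

HOPS = "hops"
WEIGHT_COST = "weight_cost"


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    largest_component_frac: float
    diameter: float
    density: float
    reciprocity: float
    pct_isolates: float


@dataclass(frozen=True)
class ComparisonCounts:
    """How angler edges relate to hydrologic edges on the same node set."""

    reinforced: int
    reciprocal_upstream: int
    novel: int


def _edge_pairs(edges: pd.DataFrame) -> set[tuple[str, str]]:
    return set(zip(edges["origin"], edges["dest"]))


def components(edges: pd.DataFrame, nodes: list[str] | None = None) -> list[set[str]]:
    """Weakly connected components covering all supplied nodes."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(_edge_pairs(edges))
    return [set(c) for c in nx.connected_components(g)]


def _csgraph(edges: pd.DataFrame, node_list: list[str], weighted: bool):
    pos = {n: i for i, n in enumerate(node_list)}
    rows = [pos[o] for o in edges["origin"]]
    cols = [pos[d] for d in edges["dest"]]
    vals = edges["weight"].to_numpy(dtype=float) if weighted else np.ones(len(edges))
    n = len(node_list)
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def diameter(edges: pd.DataFrame, mode: str = WEIGHT_COST, directed: bool = False) -> float:
    """Longest shortest path over the largest (weak) component.

    ``hops`` counts edges; ``weight_cost`` uses edge weight as traversal
    cost.  By default edges are traversable in either direction; the
    directed variant restricts paths to edge direction and takes the
    maximum over ordered reachable pairs.
    """
    if edges.empty:
        raise ValueError("diameter undefined for an empty graph")
    comp = max(components(edges), key=lambda c: (len(c), sorted(c)))
    sub = edges[edges["origin"].isin(comp) & edges["dest"].isin(comp)]
    node_list = sorted(comp)
    mat = _csgraph(sub, node_list, weighted=(mode == WEIGHT_COST))
    if mode not in (HOPS, WEIGHT_COST):
        raise ValueError(f"unknown diameter mode: {mode!r}")
    dist = shortest_path(
        mat, method="D", directed=directed, unweighted=(mode == HOPS)
    )
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) if finite.size else 0.0


def density(n_nodes: int, n_edges: int) -> float:
    """Directed graph density m / (n (n-1))."""
    if n_nodes < 2:
        raise ValueError("density requires at least 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1))


def reciprocity(edges: pd.DataFrame) -> float:
    """Fraction of directed edges whose reverse edge also exists (0 for empty)."""
    pairs = _edge_pairs(edges)
    if not pairs:
        return 0.0
    return sum((d, o) in pairs for o, d in pairs) / len(pairs)


def summarize(nodes: list[str], edges: pd.DataFrame, mode: str = WEIGHT_COST) -> NetworkSummary:
    """Global statistics for one network over an explicit node universe."""
    comps = components(edges, nodes)
    n_nodes = len(nodes)
    largest = max((len(c) for c in comps), default=0)
    touched = set(edges["origin"]) | set(edges["dest"])
    isolates = sum(1 for n in nodes if n not in touched)
    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=len(edges),
        n_components=len(comps),
        largest_component_frac=largest / n_nodes if n_nodes else 0.0,
        diameter=diameter(edges, mode) if len(edges) else 0.0,
        density=density(n_nodes, len(edges)) if n_nodes >= 2 else 0.0,
        reciprocity=reciprocity(edges),
        pct_isolates=100.0 * isolates / n_nodes if n_nodes else 0.0,
    )


def compare_networks(angler_edges: pd.DataFrame, hydro_edges: pd.DataFrame) -> ComparisonCounts:
    """Classify angler edges against the hydrologic edge set.

    reinforced: angler edge duplicating a downstream hydro edge;
    reciprocal_upstream: angler edge running opposite a hydro edge (upstream
    flow created by anglers); novel: angler edge between lakes with no hydro
    connection in either direction.
    """
    hydro = _edge_pairs(hydro_edges)
    angler = _edge_pairs(angler_edges)
    reinforced = sum(e in hydro for e in angler)
    reciprocal = sum((d, o) in hydro for o, d in angler)
    novel = sum(e not in hydro and (e[1], e[0]) not in hydro for e in angler)
    return ComparisonCounts(reinforced, reciprocal, novel)


def basin_flow_matrix(
    edges: pd.DataFrame, lake_to_basin: dict[str, str]
) -> pd.DataFrame:
    """Summed edge weight from origin basin (rows) to destination basin (cols).

    The diagonal holds within-basin flow; the matrix total equals total edge
    weight.  Raises on any edge endpoint without a basin.
    """
    basins = sorted(set(lake_to_basin.values()))
    ob = edges["origin"].map(lake_to_basin)
    db = edges["dest"].map(lake_to_basin)
    for col, side in ((ob, "origin"), (db, "dest")):
        if col.isna().any():
            missing = edges.loc[col.isna(), side].iloc[0]
            raise KeyError(f"lake {missing!r} has no basin assignment")
    grouped = edges.groupby([ob.rename("ob"), db.rename("db")])["weight"].sum()
    mat = pd.DataFrame(0.0, index=basins, columns=basins)
    for (i, j), w in grouped.items():
        mat.loc[i, j] = w
    return mat


def node_strengths(edges: pd.DataFrame) -> pd.DataFrame:
    """Weighted in/out strength per node (columns in_strength, out_strength)."""
    out_s = edges.groupby("origin")["weight"].sum()
    in_s = edges.groupby("dest")["weight"].sum()
    df = pd.DataFrame({"out_strength": out_s, "in_strength": in_s}).fillna(0.0)
    df.index.name = "lake_id"
    return df


def identify_hubs(
    edges: pd.DataFrame,
    lakes,
    region_of: dict[str, str],
    top_k: int = 5,
) -> pd.DataFrame:
    """Per-region superspreader and vulnerable hub lakes.

    Superspreaders are the top_k invaded lakes by weighted out-strength
    (sources of propagules); vulnerable hubs are the top_k uninvaded lakes
    by weighted in-strength (likely next recipients).  Ties break by total
    strength then lake id.
    """
    strengths = node_strengths(edges)
    invaded = {lk.lake_id: bool(lk.invaded_by) for lk in lakes}
    rows = []
    for lake_id in strengths.index:
        rows.append(
            {
                "lake_id": lake_id,
                "region_id": region_of.get(lake_id),
                "in_strength": strengths.at[lake_id, "in_strength"],
                "out_strength": strengths.at[lake_id, "out_strength"],
                "invaded": invaded.get(lake_id, False),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["lake_id", "region_id", "in_strength", "out_strength", "invaded", "role"]
        )
    df["total"] = df["in_strength"] + df["out_strength"]
    out = []
    for region, grp in df.groupby("region_id", dropna=False):
        spread = grp[grp["invaded"]].sort_values(
            ["out_strength", "total", "lake_id"], ascending=[False, False, True]
        ).head(top_k)
        vuln = grp[~grp["invaded"]].sort_values(
            ["in_strength", "total", "lake_id"], ascending=[False, False, True]
        ).head(top_k)
        out.append(spread.assign(role="superspreader"))
        out.append(vuln.assign(role="vulnerable"))
    result = pd.concat(out, ignore_index=True).drop(columns="total")
    return result[["lake_id", "region_id", "in_strength", "out_strength", "invaded", "role"]]
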