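"""The weighted, directed downstream hydrologic lake network.

Flowline segments connect lakes and junctions strictly downstream.  Lakes
separated by less than a threshold (default 40 m) of permanent (perennial)
stream merge into one node, represented by the largest-area member.  Edges
connect first-order downstream lake pairs — pairs linked by a flow path
through junctions only, with no intermediate lake — and carry a
flow-permanence weight: the proportion of the year the limiting segment is
expected to flow (1.00 perennial/unclassified, 0.75 intermittent, 0.10
ephemeral).  Ditches, small canals, karst, pipelines and underground
conduits carry no edge.
"""

from __future__ import annotations

import heapq
from collections import defaultdict

import networkx as nx
import pandas as pd

from .core import EDGE_COLUMNS, EXCLUDED_FLOW_CLASSES, FLOW_CLASSES, FlowSegment, Lake

#: Flow-permanence edge weights per USGS-style classification.
FLOW_WEIGHTS = {
    "perennial": 1.00,
    "unclassified": 1.00,
    "intermittent": 0.75,
    "ephemeral": 0.10,
}


def flow_weight(flow_class: str) -> float | None:
    """Weight for a flow class, or None for excluded conveyance classes."""
    if flow_class in FLOW_WEIGHTS:
        return FLOW_WEIGHTS[flow_class]
    if flow_class in EXCLUDED_FLOW_CLASSES:
        return None
    raise ValueError(f"unknown flow class: {flow_class!r}")


def find_merge_clusters(
    lakes: list[Lake], segments: list[FlowSegment], threshold_m: float
) -> dict[str, str]:
    """Cluster lakes separated by < ``threshold_m`` of permanent stream.

    Builds an undirected graph over lakes with an edge wherever a chain of
    perennial segments, passing only through junctions, totals less than
    the threshold; connected components of that graph are clusters.  The
    returned map sends every member to its cluster representative (the
    largest-area member); the representative's centroid becomes the cluster
    midpoint.  The map is idempotent (representatives map to themselves)
    and omits unmerged lakes.
    """
    lake_ids = {lk.lake_id for lk in lakes}
    adj: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for seg in segments:
        if seg.permanent:
            adj[seg.from_ref].append((seg.to_ref, seg.length_m))
            adj[seg.to_ref].append((seg.from_ref, seg.length_m))

    cluster_graph = nx.Graph()
    cluster_graph.add_nodes_from(lake_ids)
    for src in lake_ids:
        # Dijkstra bounded by the threshold; paths may not pass through
        # another lake (those pairs merge transitively instead).
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, node = heapq.heappop(heap)
            if d > dist.get(node, float("inf")):
                continue
            if node != src and node in lake_ids:
                continue  # stop at lakes; do not traverse through them
            for nbr, w in adj[node]:
                nd = d + w
                if nd < threshold_m and nd < dist.get(nbr, float("inf")):
                    dist[nbr] = nd
                    heapq.heappush(heap, (nd, nbr))
        for node, d in dist.items():
            if node != src and node in lake_ids and d < threshold_m:
                cluster_graph.add_edge(src, node)

    area = {lk.lake_id: lk.area_ha for lk in lakes}
    merge_map: dict[str, str] = {}
    for comp in nx.connected_components(cluster_graph):
        if len(comp) < 2:
            continue
        rep = max(comp, key=lambda i: (area.get(i, 0.0), i))
        for member in comp:
            merge_map[member] = rep
    return merge_map


def build_downstream_edges(
    lakes: list[Lake], segments: list[FlowSegment], merge_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """First-order downstream lake-to-lake edges with permanence weights.

    Excluded conveyance classes are dropped; lake endpoints are remapped
    through ``merge_map``.  From every lake, downstream flow is traced
    through junctions until the first lake reached; the edge weight is the
    minimum segment weight along the path (the least-permanent link limits
    passage).  Braided channels producing several paths to the same lake
    collapse to one edge with the best (maximum) of those bottleneck
    weights.  Raises if the downstream relation is cyclic.
    """
    merge_map = merge_map or {}
    lake_ids = {merge_map.get(lk.lake_id, lk.lake_id) for lk in lakes}

    def _ref(r: str) -> str:
        return merge_map.get(r, r)

    dig = nx.MultiDiGraph()
    for seg in segments:
        w = flow_weight(seg.flow_class)
        if w is None:
            continue
        u, v = _ref(seg.from_ref), _ref(seg.to_ref)
        if u == v:
            continue  # intra-cluster channel, already one node
        dig.add_edge(u, v, weight=w)
    if not nx.is_directed_acyclic_graph(dig):
        raise ValueError("downstream flow topology contains a cycle")

    rows = []
    for src in sorted(lake_ids & set(dig.nodes)):
        # Bottleneck (widest-path) search maximising the minimum segment
        # weight, stopping at the first lake on each branch.
        best: dict[str, float] = {src: float("inf")}
        heap = [(-float("inf"), src)]
        while heap:
            negb, node = heapq.heappop(heap)
            b = -negb
            if b < best.get(node, -float("inf")):
                continue
            if node != src and node in lake_ids:
                continue  # first-order: do not flow through a lake
            for _, nbr, data in dig.out_edges(node, data=True):
                nb = min(b, data["weight"])
                if nb > best.get(nbr, -float("inf")):
                    best[nbr] = nb
                    heapq.heappush(heap, (-nb, nbr))
        for node, b in best.items():
            if node != src and node in lake_ids:
                rows.append((src, node, b, 1, float("nan")))

    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return edges.sort_values(["origin", "dest"]).reset_index(drop=True)
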