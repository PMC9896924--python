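"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained (no networkx, no
scipy graph routines) so it can cross-check the package implementations.
"""

from __future__ import annotations

import math

import numpy as np


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_oracle(nodes, edge_pairs):
    """Weak components via union-find."""
    uf = UnionFind(nodes)
    for a, b in edge_pairs:
        uf.union(a, b)
    comps: dict = {}
    for n in nodes:
        comps.setdefault(uf.find(n), set()).add(n)
    return sorted(comps.values(), key=lambda s: sorted(s))


def floyd_warshall_oracle(nodes, weighted_edges, directed: bool, unit: bool):
    """All-pairs shortest paths via the textbook triple loop."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0.0
    for a, b, w in weighted_edges:
        c = 1.0 if unit else w
        i, j = idx[a], idx[b]
        dist[i][j] = min(dist[i][j], c)
        if not directed:
            dist[j][i] = min(dist[j][i], c)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = dist[i][k] + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def diameter_oracle(nodes, weighted_edges, directed: bool, unit: bool) -> float:
    """Longest finite shortest path over the largest weak component."""
    comps = components_oracle(nodes, [(a, b) for a, b, _ in weighted_edges])
    comp = max(comps, key=lambda c: (len(c), sorted(c)))
    sub_nodes = sorted(comp)
    sub_edges = [(a, b, w) for a, b, w in weighted_edges if a in comp and b in comp]
    dist = floyd_warshall_oracle(sub_nodes, sub_edges, directed, unit)
    best = 0.0
    for row in dist:
        for d in row:
            if math.isfinite(d) and d > best:
                best = d
    return best


def first_order_downstream_oracle(lake_ids, segments_by_weight):
    """Exhaustive path enumeration for first-order downstream lake pairs.

    ``segments_by_weight``: list of (u, v, weight) directed links over lakes
    and junctions (excluded classes already dropped, merges applied).
    Returns {(origin_lake, dest_lake): best bottleneck weight} over all
    junction-only paths.
    """
    out_edges: dict = {}
    for u, v, w in segments_by_weight:
        out_edges.setdefault(u, []).append((v, w))
    lake_set = set(lake_ids)
    results: dict = {}

    def walk(origin, node, bottleneck, visited):
        for nbr, w in out_edges.get(node, []):
            nb = min(bottleneck, w)
            if nbr in lake_set:
                if nbr != origin:
                    key = (origin, nbr)
                    results[key] = max(results.get(key, -math.inf), nb)
                continue  # stop at any lake
            if nbr not in visited:  # junction: keep walking
                walk(origin, nbr, nb, visited | {nbr})

    for lake in lake_ids:
        walk(lake, lake, math.inf, {lake})
    return results


def line_density_mc_oracle(edges, midpoints, centers, radius, rng, n_samples=200_000):
    """Monte-Carlo line density: sample points along each edge, count the
    fraction inside each cell's search disk."""
    vals = np.zeros(len(centers))
    disk_area = math.pi * radius**2
    for origin, dest, weight in edges:
        p1 = np.asarray(midpoints[origin], dtype=float)
        p2 = np.asarray(midpoints[dest], dtype=float)
        t = rng.random(n_samples)
        pts = p1[None, :] + t[:, None] * (p2 - p1)[None, :]
        seg_len = float(np.hypot(*(p2 - p1)))
        for k, (cx, cy) in enumerate(centers):
            frac = np.mean((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= radius**2)
            vals[k] += weight * frac * seg_len / disk_area
    return vals


def point_to_lakes_bruteforce(point, lakes, buffer_km):
    """Assignment by exhaustive distance to every lake (containment first,
    then nearest boundary within the buffer; ties by boundary distance then id)."""
    best = None
    for lk in lakes:
        contains = lk.polygon.covers(point)
        d_bound = point.distance(lk.polygon.boundary)
        if not contains and d_bound > buffer_km:
            continue
        key = (not contains, d_bound, lk.lake_id)
        if best is None or key < best[0]:
            best = (key, lk.lake_id)
    return best[1] if best else None
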