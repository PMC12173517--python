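"""Brute-force oracles, independent of the package internals.

Every oracle works on an explicit point graph built with networkx: each
site/barrier placement is inserted as a graph node splitting its edge, so
distances, routes, flow direction and fragment components can be read off
with generic graph algorithms.
"""
from __future__ import annotations

import networkx as nx
import numpy as np


def split_graph(net, placements):
    """Undirected weighted graph of network nodes plus placement nodes."""
    by_edge = {}
    for p in placements:
        by_edge.setdefault(p.edge, []).append(p)
    g = nx.Graph()
    for eid, row in net.edges.iterrows():
        chain = [(0.0, row["up_node"])]
        for p in sorted(by_edge.get(eid, []), key=lambda p: (p.offset_m, str(p.id))):
            chain.append((p.offset_m, p.id))
        chain.append((float(row["length_m"]), row["down_node"]))
        for (o1, n1), (o2, n2) in zip(chain[:-1], chain[1:]):
            if n1 == n2:
                continue
            g.add_edge(n1, n2, weight=o2 - o1)
    for p in placements:  # placements exactly at a node endpoint
        if not g.has_node(p.id):
            row = net.edges.loc[p.edge]
            anchor = row["up_node"] if p.offset_m == 0 else row["down_node"]
            g.add_edge(p.id, anchor, weight=0.0)
    return g


def directed_split_graph(net, placements):
    """Downstream-directed version of the split graph."""
    by_edge = {}
    for p in placements:
        by_edge.setdefault(p.edge, []).append(p)
    g = nx.DiGraph()
    for eid, row in net.edges.iterrows():
        chain = [(0.0, row["up_node"])]
        for p in sorted(by_edge.get(eid, []), key=lambda p: (p.offset_m, str(p.id))):
            chain.append((p.offset_m, p.id))
        chain.append((float(row["length_m"]), row["down_node"]))
        for (o1, n1), (o2, n2) in zip(chain[:-1], chain[1:]):
            if n1 != n2:
                g.add_edge(n1, n2)
    for p in placements:
        if not g.has_node(p.id):
            row = net.edges.loc[p.edge]
            if p.offset_m == 0:
                g.add_edge(row["up_node"], p.id)
                g.add_edge(p.id, row["up_node"])
            else:
                g.add_edge(row["down_node"], p.id)
                g.add_edge(p.id, row["down_node"])
    return g


def oracle_distance(net, a, b):
    g = split_graph(net, [a, b])
    return nx.shortest_path_length(g, a.id, b.id, weight="weight")


def oracle_flow_connected(net, a, b):
    g = directed_split_graph(net, [a, b])
    return nx.has_path(g, a.id, b.id) or nx.has_path(g, b.id, a.id)


def oracle_route_barriers(net, a, b, barriers):
    g = split_graph(net, [a, b, *barriers])
    path = nx.shortest_path(g, a.id, b.id, weight="weight")
    barrier_ids = {p.id for p in barriers}
    return sum(1 for node in path[1:-1] if node in barrier_ids)


def oracle_fragments(net, sites, barriers):
    """Frozenset-of-frozensets fragment partition: cut the point network at
    every barrier and take connected components of what remains."""
    g = split_graph(net, [*sites, *barriers])
    g.remove_nodes_from([p.id for p in barriers])
    site_ids = {p.id for p in sites}
    parts = []
    for comp in nx.connected_components(g):
        members = frozenset(comp & site_ids)
        if members:
            parts.append(members)
    return frozenset(parts)


def dense_neg2_reml(X, y, Z_blocks, sigma2s, sigma2_resid):
    """-2 restricted log-likelihood at explicit variance components,
    evaluated with dense n x n linear algebra (no profiling, no Woodbury)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    V = sigma2_resid * np.eye(n)
    for Z, s2 in zip(Z_blocks, sigma2s):
        Zd = Z.toarray() if hasattr(Z, "toarray") else np.asarray(Z, dtype=float)
        V += s2 * (Zd @ Zd.T)
    sign, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = r @ Vi @ r
    sign2, logdetXtViX = np.linalg.slogdet(XtViX)
    return logdetV + logdetXtViX + quad + (n - p) * np.log(2 * np.pi)
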