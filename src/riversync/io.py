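"""Readers for river-network, site, barrier and density inputs.

Real-mode inputs are a GeoJSON FeatureCollection of LineStrings (the
river polylines, planar metre coordinates), CSV site and barrier tables
with coordinates, and a long-format density CSV. Synthetic and toy
networks can instead come from a plain edge-list CSV. Sites and barriers
are snapped to the nearest point on the network by perpendicular
projection (ties broken by lowest edge id).
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, shape

from .network import NetworkError, Placement, RiverNetwork, build_network

__all__ = [
    "read_edge_table",
    "read_geojson_network",
    "read_sites",
    "read_barriers",
    "read_density",
    "snap_to_network",
]


def read_edge_table(path) -> RiverNetwork:
    """Network from an edge-list CSV (edge_id, up_node, down_node, length_m)."""
    return build_network(pd.read_csv(path, comment="#"))


def read_geojson_network(path, outlet_xy: tuple[float, float]) -> RiverNetwork:
    """Network from a GeoJSON FeatureCollection of LineStrings.

    Every LineString becomes one edge; nodes are shared endpoints
    (coordinates rounded to the millimetre to merge). Edge orientation is
    inferred by walking away from the node nearest ``outlet_xy``. The
    per-edge geometry is kept for snapping.
    """
    with open(path) as fh:
        gj = json.load(fh)
    lines = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise NetworkError(f"expected LineString features, got {geom.geom_type}")
        lines.append(geom)

    def key(pt):
        return (round(pt[0], 3), round(pt[1], 3))

    # undirected adjacency on endpoint nodes
    adj: dict = {}
    ends = []
    for i, ln in enumerate(lines):
        a, b = key(ln.coords[0]), key(ln.coords[-1])
        ends.append((a, b))
        adj.setdefault(a, []).append((i, b))
        adj.setdefault(b, []).append((i, a))

    nodes = list(adj)
    d2 = [(x - outlet_xy[0]) ** 2 + (y - outlet_xy[1]) ** 2 for x, y in nodes]
    outlet = nodes[int(np.argmin(d2))]

    # orient every edge downstream toward the outlet (BFS from the outlet)
    rows = []
    geoms = {}
    seen_nodes = {outlet}
    seen_edges = set()
    frontier = [outlet]
    while frontier:
        down = frontier.pop()
        for i, other in adj[down]:
            if i in seen_edges:
                continue
            seen_edges.add(i)
            if other in seen_nodes:
                raise NetworkError("cycle detected in GeoJSON network")
            seen_nodes.add(other)
            frontier.append(other)
            a, b = ends[i]
            up = other
            # store polyline oriented upstream -> downstream
            ln = lines[i]
            if key(ln.coords[0]) == up:
                oriented = ln
            else:
                oriented = LineString(ln.coords[::-1])
            eid = f"e{i}"
            geoms[eid] = oriented
            rows.append({"edge_id": eid, "up_node": f"n{nodes.index(up)}",
                         "down_node": f"n{nodes.index(down)}",
                         "length_m": float(ln.length)})
    if len(seen_edges) != len(lines):
        raise NetworkError("multiple components in GeoJSON network")
    coords = {f"n{j}": nodes[j] for j in range(len(nodes))
              if nodes[j] in seen_nodes}
    net = build_network(pd.DataFrame(rows), node_coords=coords)
    net.edge_geoms = geoms  # used by snap_to_network
    return net


def snap_to_network(points: pd.DataFrame, net: RiverNetwork) -> list[Placement]:
    """Snap (id, x, y) rows to the nearest network point.

    Uses per-edge polyline geometry when available (GeoJSON networks),
    otherwise straight segments between node coordinates. Ties are broken
    by the lowest edge id.
    """
    geoms = getattr(net, "edge_geoms", None)
    if geoms is None:
        geoms = {}
        for eid, row in net.edges.iterrows():
            geoms[eid] = LineString([net.nodes[row["up_node"]],
                                     net.nodes[row["down_node"]]])
    edge_ids = sorted(geoms, key=str)
    out = []
    for row in points.itertuples(index=False):
        pt = Point(row.x, row.y)
        best = None
        for eid in edge_ids:
            d = geoms[eid].distance(pt)
            if best is None or d < best[0] - 1e-12:
                best = (d, eid)
        eid = best[1]
        frac = geoms[eid].project(pt, normalized=True)
        length = float(net.edges.loc[eid, "length_m"])
        out.append(Placement(id=row.id, edge=eid,
                             offset_m=float(np.clip(frac * length, 0.0, length)),
                             x=float(row.x), y=float(row.y)))
    return out


def read_sites(path) -> pd.DataFrame:
    """Site table CSV: site_id, x, y, catchment."""
    df = pd.read_csv(path, comment="#")
    return df.rename(columns={"site_id": "id"})[["id", "x", "y", "catchment"]]


def read_barriers(path, drop_removed: bool = True) -> pd.DataFrame:
    """Barrier table CSV: barrier_id, x, y, removed. Removed barriers are
    filtered out before any spatial work (they no longer fragment)."""
    df = pd.read_csv(path, comment="#").rename(columns={"barrier_id": "id"})
    if drop_removed and "removed" in df.columns:
        df = df.loc[~df["removed"].astype(bool)]
    return df[["id", "x", "y"]].reset_index(drop=True)


def read_density(path) -> pd.DataFrame:
    """Long-format density CSV: site, year, (species,) density."""
    df = pd.read_csv(path, comment="#")
    need = {"site", "year", "density"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"density table missing columns {sorted(missing)}")
    return df
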