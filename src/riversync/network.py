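"""Dendritic river network geometry.

A river network is represented as a rooted tree: edges are stored
upstream -> downstream and every path leads to a single outlet node.
On top of that substrate this module computes the pairwise quantities
the synchrony analysis needs — watercourse distance, Euclidean distance,
flow-connectedness, barrier crossings — and clusters sampling sites into
barrier-free fragments.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NetworkError",
    "Placement",
    "RiverNetwork",
    "FragmentMap",
    "build_network",
    "watercourse_distance",
    "flow_connectedness",
    "route_barriers",
    "assign_fragments",
    "pair_geometry_table",
]


class NetworkError(ValueError):
    """Raised when an edge table does not describe a valid dendritic tree."""


@dataclass(frozen=True)
class Placement:
    """A point object (site or barrier) located on a network edge.

    ``offset_m`` is measured from the edge's *upstream* node.
    """

    id: str
    edge: str
    offset_m: float
    x: float | None = None
    y: float | None = None


@dataclass
class RiverNetwork:
    """Directed tree of river reaches draining to a unique outlet.

    Attributes
    ----------
    nodes : dict
        node id -> (x, y) coordinates in metres (may be NaN for abstract
        edge-list networks without an embedding).
    edges : pandas.DataFrame
        columns ``edge_id, up_node, down_node, length_m`` (index = edge_id).
    outlet : hashable
        The unique node with no downstream edge.
    """

    nodes: dict
    edges: pd.DataFrame
    outlet: object
    # derived, filled in __post_init__
    _parent: dict = field(default_factory=dict, repr=False)
    _out_edge: dict = field(default_factory=dict, repr=False)
    _d_out: dict = field(default_factory=dict, repr=False)
    _depth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        e = self.edges
        self._out_edge = {u: eid for eid, u in zip(e.index, e["up_node"])}
        self._parent = dict(zip(e["up_node"], e["down_node"]))
        # plain-dict edge attributes: the pairwise routines are hot loops
        self._edge_up = dict(zip(e.index, e["up_node"]))
        self._edge_down = dict(zip(e.index, e["down_node"]))
        self._edge_len = dict(zip(e.index, e["length_m"].astype(float)))
        # distance-to-outlet and depth by walking down from every node
        d_out: dict = {self.outlet: 0.0}
        depth: dict = {self.outlet: 0}
        length = dict(zip(e["up_node"], e["length_m"]))

        def _resolve(node):
            stack = []
            while node not in d_out:
                stack.append(node)
                node = self._parent[node]
            for n in reversed(stack):
                par = self._parent[n]
                d_out[n] = d_out[par] + length[n]
                depth[n] = depth[par] + 1

        for node in self.nodes:
            _resolve(node)
        self._d_out = d_out
        self._depth = depth

    # -- elementary queries -------------------------------------------------
    def edge_row(self, edge_id) -> pd.Series:
        return self.edges.loc[edge_id]

    def d_out_node(self, node) -> float:
        return self._d_out[node]

    def d_out_point(self, p: Placement) -> float:
        return (self._edge_len[p.edge] - p.offset_m) + self._d_out[self._edge_down[p.edge]]

    def is_route_node(self, node, start_node) -> bool:
        """True iff ``node`` lies on the downstream route from ``start_node``
        (inclusive) to the outlet."""
        target_depth = self._depth[node]
        cur = start_node
        while self._depth[cur] > target_depth:
            cur = self._parent[cur]
        return cur == node

    def lca(self, a, b):
        """Lowest common node of the two downstream routes."""
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self._parent[a]
            da -= 1
        while db > da:
            b = self._parent[b]
            db -= 1
        while a != b:
            a = self._parent[a]
            b = self._parent[b]
        return a

    def validate_placement(self, p: Placement) -> None:
        if p.edge not in self._edge_len:
            raise NetworkError(f"placement {p.id!r} references unknown edge {p.edge!r}")
        length = self._edge_len[p.edge]
        if not (0.0 <= p.offset_m <= length):
            raise NetworkError(
                f"placement {p.id!r} offset {p.offset_m} outside [0, {length}]"
            )


def build_network(edge_table: pd.DataFrame, node_coords: Mapping | None = None) -> RiverNetwork:
    """Validate an upstream->downstream edge list and return a RiverNetwork.

    Parameters
    ----------
    edge_table : DataFrame with columns ``edge_id, up_node, down_node, length_m``.
    node_coords : optional mapping node id -> (x, y); defaults to NaN coords.

    Raises
    ------
    NetworkError
        On cycles, multiple components, multiple outlets, braided channels
        (a node with two downstream edges) or nonpositive edge lengths.
    """
    e = edge_table.copy()
    required = {"edge_id", "up_node", "down_node", "length_m"}
    missing = required - set(e.columns)
    if missing:
        raise NetworkError(f"edge table missing columns: {sorted(missing)}")
    if e["edge_id"].duplicated().any():
        raise NetworkError("duplicate edge ids")
    if (e["length_m"] <= 0).any():
        bad = e.loc[e["length_m"] <= 0, "edge_id"].tolist()
        raise NetworkError(f"nonpositive edge length on edges {bad}")

    node_ids = pd.unique(pd.concat([e["up_node"], e["down_node"]]))
    out_counts = e["up_node"].value_counts()
    if (out_counts > 1).any():
        bad = out_counts[out_counts > 1].index.tolist()
        raise NetworkError(f"braided channel: nodes {bad} have multiple downstream edges")
    outlets = [n for n in node_ids if n not in set(e["up_node"])]
    if len(outlets) > 1:
        raise NetworkError(f"multiple outlets: {outlets}")
    if len(outlets) == 0:
        raise NetworkError("cycle detected: no outlet node")
    outlet = outlets[0]
    if len(e) != len(node_ids) - 1:
        raise NetworkError(
            f"not a tree: {len(e)} edges for {len(node_ids)} nodes "
            "(cycle or multiple components)"
        )
    # connectivity: every node must reach the outlet through parent pointers
    parent = dict(zip(e["up_node"], e["down_node"]))
    for start in node_ids:
        seen = set()
        cur = start
        while cur != outlet:
            if cur in seen:
                raise NetworkError(f"cycle detected at node {cur!r}")
            seen.add(cur)
            if cur not in parent:
                raise NetworkError("multiple components: node "
                                   f"{cur!r} does not drain to the outlet")
            cur = parent[cur]

    if node_coords is None:
        nodes = {n: (np.nan, np.nan) for n in node_ids}
    else:
        nodes = {n: tuple(node_coords[n]) for n in node_ids}
    edges = e.set_index("edge_id")[["up_node", "down_node", "length_m"]]
    edges["length_m"] = edges["length_m"].astype(float)
    return RiverNetwork(nodes=nodes, edges=edges, outlet=outlet)


# ---------------------------------------------------------------------------
# pairwise geometry
# ---------------------------------------------------------------------------

def _downstream_of(net: RiverNetwork, a: Placement, b: Placement) -> bool:
    """True iff b lies on a's downstream route (different edges assumed)."""
    # a's route passes edge b iff it passes b's upstream node (whose unique
    # outgoing edge is b's edge)
    return net.is_route_node(net._edge_up[b.edge], net._edge_down[a.edge])


def watercourse_distance(a: Placement, b: Placement, net: RiverNetwork) -> float:
    """Length in metres of the unique tree path between two placements."""
    net.validate_placement(a)
    net.validate_placement(b)
    if a.edge == b.edge:
        return abs(a.offset_m - b.offset_m)
    if _downstream_of(net, a, b):
        return net.d_out_point(a) - net.d_out_point(b)
    if _downstream_of(net, b, a):
        return net.d_out_point(b) - net.d_out_point(a)
    meet = net.lca(net._edge_down[a.edge], net._edge_down[b.edge])
    return net.d_out_point(a) + net.d_out_point(b) - 2.0 * net.d_out_node(meet)


def flow_connectedness(a: Placement, b: Placement, net: RiverNetwork) -> bool:
    """True iff one site lies on the other's downstream route to the outlet.

    Flow-unconnected pairs sit on different branches: their connecting path
    descends through a confluence and climbs another tributary.
    """
    if a.edge == b.edge:
        return True
    return _downstream_of(net, a, b) or _downstream_of(net, b, a)


def _route_intervals(a: Placement, b: Placement, net: RiverNetwork) -> list[tuple]:
    """The path between two placements as (edge_id, lo_offset, hi_offset)."""
    if a.edge == b.edge:
        lo, hi = sorted((a.offset_m, b.offset_m))
        return [(a.edge, lo, hi)]

    def _down_segments(p: Placement, stop_node) -> list[tuple]:
        """Intervals from p downstream to stop_node."""
        segs = [(p.edge, p.offset_m, net._edge_len[p.edge])]
        node = net._edge_down[p.edge]
        while node != stop_node:
            eid = net._out_edge[node]
            segs.append((eid, 0.0, net._edge_len[eid]))
            node = net._edge_down[eid]
        return segs

    if _downstream_of(net, a, b):
        return _down_segments(a, net._edge_up[b.edge]) + [(b.edge, 0.0, b.offset_m)]
    if _downstream_of(net, b, a):
        return _down_segments(b, net._edge_up[a.edge]) + [(a.edge, 0.0, a.offset_m)]
    meet = net.lca(net._edge_down[a.edge], net._edge_down[b.edge])
    return _down_segments(a, meet) + _down_segments(b, meet)


def route_barriers(
    a: Placement,
    b: Placement,
    barriers: Sequence[Placement],
    net: RiverNetwork,
    count_barrier_at_site: bool = False,
) -> int:
    """Number of barriers lying on the open route between two placements.

    A barrier coincident with either placement itself does not separate
    that site from its own side unless ``count_barrier_at_site`` is set.
    """
    intervals = _route_intervals(a, b, net)
    by_edge: dict = {}
    for eid, lo, hi in intervals:
        by_edge.setdefault(eid, []).append((lo, hi))
    n = 0
    for bar in barriers:
        spans = by_edge.get(bar.edge)
        if spans is None:
            continue
        if not count_barrier_at_site:
            if any(
                bar.edge == p.edge and abs(bar.offset_m - p.offset_m) < 1e-9
                for p in (a, b)
            ):
                continue
        if any(lo <= bar.offset_m <= hi for lo, hi in spans):
            n += 1
    return n


@dataclass
class FragmentMap:
    """Site -> fragment assignment; a fragment never spans catchments."""

    site_to_fragment: dict
    fragment_catchment: dict

    def fragment_of(self, site_id) -> str:
        return self.site_to_fragment[site_id]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"site": list(self.site_to_fragment), "fragment": list(self.site_to_fragment.values())}
        )
        df["catchment"] = df["fragment"].map(self.fragment_catchment)
        return df.sort_values("site").reset_index(drop=True)


def assign_fragments(
    sites: Sequence[Placement],
    barriers: Sequence[Placement],
    net: RiverNetwork,
    catchment: str = "C0",
    count_barrier_at_site: bool = False,
) -> FragmentMap:
    """Cluster sites into fragments: two sites share a fragment iff their
    watercourse route crosses no barrier.

    Fragment ids are deterministic: the smallest member site id.
    """
    sites = sorted(sites, key=lambda p: str(p.id))
    n = len(sites)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if route_barriers(sites[i], sites[j], barriers, net,
                              count_barrier_at_site=count_barrier_at_site) == 0:
                parent[find(i)] = find(j)

    groups: dict = {}
    for i, s in enumerate(sites):
        groups.setdefault(find(i), []).append(s.id)
    site_to_fragment: dict = {}
    fragment_catchment: dict = {}
    for members in groups.values():
        frag = min(members, key=str)
        fragment_catchment[frag] = catchment
        for m in members:
            site_to_fragment[m] = frag
    return FragmentMap(site_to_fragment, fragment_catchment)


def pair_geometry_table(
    sites: Sequence[Placement],
    barriers: Sequence[Placement],
    net: RiverNetwork,
    catchment: str = "C0",
    count_barrier_at_site: bool = False,
) -> pd.DataFrame:
    """All unordered within-catchment site pairs with their geometry.

    Columns: ``site_a, site_b, d_w_m, d_e_m, flow_connected, barrier_crossed,
    n_barriers, catchment, fragment_a, fragment_b``.
    """
    for p in sites:
        net.validate_placement(p)
    fmap = assign_fragments(sites, barriers, net, catchment=catchment,
                            count_barrier_at_site=count_barrier_at_site)
    sites = sorted(sites, key=lambda p: str(p.id))
    rows = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            d_w = watercourse_distance(a, b, net)
            if a.x is not None and b.x is not None and np.isfinite([a.x, a.y, b.x, b.y]).all():
                d_e = float(np.hypot(a.x - b.x, a.y - b.y))
            else:
                d_e = np.nan
            nb = route_barriers(a, b, barriers, net,
                                count_barrier_at_site=count_barrier_at_site)
            rows.append(
                {
                    "site_a": a.id,
                    "site_b": b.id,
                    "d_w_m": d_w,
                    "d_e_m": d_e,
                    "flow_connected": flow_connectedness(a, b, net),
                    "barrier_crossed": nb > 0,
                    "n_barriers": nb,
                    "catchment": catchment,
                    "fragment_a": fmap.fragment_of(a.id),
                    "fragment_b": fmap.fragment_of(b.id),
                }
            )
    return pd.DataFrame(rows)
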