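import numpy as np
import pandas as pd
import pytest

from riversync import (
    NetworkError,
    Placement,
    assign_fragments,
    build_network,
    flow_connectedness,
    pair_geometry_table,
    route_barriers,
    watercourse_distance,
)

from _oracles import (
    oracle_distance,
    oracle_flow_connected,
    oracle_fragments,
    oracle_route_barriers,
)
from conftest import random_catchment, random_placements


class TestBuildNetwork:
    def test_single_edge(self, single_edge):
        assert single_edge.outlet == "B"
        assert len(single_edge.edges) == 1

    def test_y_tree(self, y_tree):
        assert y_tree.outlet == "out"
        assert len(y_tree.nodes) == 4
        assert len(y_tree.edges) == 3

    def test_cycle_rejected(self):
        edges = pd.DataFrame(
            {"edge_id": ["e0", "e1", "e2"],
             "up_node": ["A", "B", "C"],
             "down_node": ["B", "C", "A"],
             "length_m": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(NetworkError):
            build_network(edges)

    def test_multiple_outlets_rejected(self):
        edges = pd.DataFrame(
            {"edge_id": ["e0", "e1"], "up_node": ["A", "C"],
             "down_node": ["B", "D"], "length_m": [1.0, 1.0]}
        )
        with pytest.raises(NetworkError, match="outlet|tree"):
            build_network(edges)

    def test_braided_rejected(self):
        # node A with two downstream edges = braided channel
        edges = pd.DataFrame(
            {"edge_id": ["e0", "e1", "e2"],
             "up_node": ["A", "A", "B"],
             "down_node": ["B", "C", "C"],
             "length_m": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(NetworkError, match="braided"):
            build_network(edges)

    def test_nonpositive_length_rejected(self):
        edges = pd.DataFrame(
            {"edge_id": ["e0"], "up_node": ["A"], "down_node": ["B"],
             "length_m": [0.0]}
        )
        with pytest.raises(NetworkError, match="length"):
            build_network(edges)


class TestWatercourseDistance:
    def test_identity(self, y_tree):
        p = Placement("s", "stem", 120.0)
        assert watercourse_distance(p, p, y_tree) == 0.0

    def test_y_tree_across_confluence(self, y_tree):
        a = Placement("a", "b1", 50.0)   # 50 m left to the confluence
        b = Placement("b", "b2", 120.0)  # 80 m left to the confluence
        assert watercourse_distance(a, b, y_tree) == pytest.approx(130.0)

    def test_symmetry_and_triangle_equality(self, y_tree):
        a = Placement("a", "b1", 10.0)
        m = Placement("m", "stem", 50.0)   # on the a->c route
        c = Placement("c", "stem", 250.0)
        d_ac = watercourse_distance(a, c, y_tree)
        assert d_ac == pytest.approx(watercourse_distance(c, a, y_tree))
        assert d_ac == pytest.approx(
            watercourse_distance(a, m, y_tree) + watercourse_distance(m, c, y_tree)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_trees(self, seed):
        net, _, _ = random_catchment(seed)
        rng = np.random.default_rng(100 + seed)
        pts = random_placements(net, 10, rng)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = watercourse_distance(pts[i], pts[j], net)
                assert d == pytest.approx(oracle_distance(net, pts[i], pts[j]))


class TestFlowConnectedness:
    def test_downstream_point_is_connected(self, y_tree):
        a = Placement("a", "b1", 20.0)
        b = Placement("b", "stem", 250.0)  # on a's route to the outlet
        assert flow_connectedness(a, b, y_tree)

    def test_two_headwater_branches_unconnected(self, y_tree):
        a = Placement("a", "b1", 50.0)
        b = Placement("b", "b2", 50.0)
        assert not flow_connectedness(a, b, y_tree)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_ancestor_oracle(self, seed):
        net, _, _ = random_catchment(seed)
        rng = np.random.default_rng(200 + seed)
        pts = random_placements(net, 10, rng)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert flow_connectedness(pts[i], pts[j], net) == \
                    oracle_flow_connected(net, pts[i], pts[j])


class TestRouteBarriers:
    def test_no_barriers(self, y_tree):
        a = Placement("a", "b1", 10.0)
        b = Placement("b", "stem", 100.0)
        assert route_barriers(a, b, [], y_tree) == 0

    def test_stem_barrier(self, y_tree):
        bar = Placement("dam", "stem", 150.0)
        a = Placement("a", "b1", 10.0)
        b_below = Placement("b", "stem", 200.0)
        b_other_branch = Placement("c", "b2", 10.0)
        assert route_barriers(a, b_below, [bar], y_tree) == 1
        assert route_barriers(a, b_other_branch, [bar], y_tree) == 0

    def test_barrier_at_site_not_between(self, y_tree):
        a = Placement("a", "stem", 150.0)
        b = Placement("b", "stem", 250.0)
        bar = Placement("dam", "stem", 150.0)  # coincident with site a
        assert route_barriers(a, b, [bar], y_tree) == 0
        assert route_barriers(a, b, [bar], y_tree, count_barrier_at_site=True) == 1

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_interval_oracle(self, seed):
        net, _, barriers = random_catchment(seed, n_barriers=3)
        rng = np.random.default_rng(300 + seed)
        pts = random_placements(net, 8, rng)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                got = route_barriers(pts[i], pts[j], barriers, net)
                want = oracle_route_barriers(net, pts[i], pts[j], barriers)
                assert got == want


class TestAssignFragments:
    def test_no_barriers_single_fragment(self, y_tree):
        sites = [Placement("a", "b1", 10.0), Placement("b", "b2", 10.0),
                 Placement("c", "stem", 100.0)]
        fmap = assign_fragments(sites, [], y_tree)
        assert len(set(fmap.site_to_fragment.values())) == 1

    def test_stem_barrier_splits(self, y_tree):
        sites = [Placement("a", "b1", 10.0), Placement("b", "b2", 10.0),
                 Placement("c", "stem", 250.0)]
        bar = [Placement("dam", "stem", 150.0)]
        fmap = assign_fragments(sites, bar, y_tree)
        assert fmap.fragment_of("a") == fmap.fragment_of("b")
        assert fmap.fragment_of("c") != fmap.fragment_of("a")

    def test_order_invariance_and_deterministic_labels(self, y_tree):
        sites = [Placement("a", "b1", 10.0), Placement("b", "b2", 10.0),
                 Placement("c", "stem", 250.0)]
        bar = [Placement("dam", "stem", 150.0)]
        f1 = assign_fragments(sites, bar, y_tree)
        f2 = assign_fragments(sites[::-1], bar, y_tree)
        assert f1.site_to_fragment == f2.site_to_fragment
        # label = smallest member site id
        assert f1.fragment_of("a") == "a"
        assert f1.fragment_of("c") == "c"

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_network_cutting_oracle(self, seed):
        net, sites, barriers = random_catchment(seed, n_sites=8, n_barriers=3)
        fmap = assign_fragments(sites, barriers, net)
        got = {}
        for s, f in fmap.site_to_fragment.items():
            got.setdefault(f, set()).add(s)
        got = frozenset(frozenset(v) for v in got.values())
        assert got == oracle_fragments(net, sites, barriers)


class TestPairGeometryTable:
    def test_pair_count_and_shortcut(self, y_tree):
        rng = np.random.default_rng(0)
        sites = []
        for i, (eid, off) in enumerate([("b1", 50.0), ("b2", 100.0),
                                        ("stem", 50.0), ("stem", 280.0)]):
            row = y_tree.edges.loc[eid]
            ux, uy = y_tree.nodes[row["up_node"]]
            dx, dy = y_tree.nodes[row["down_node"]]
            t = off / row["length_m"]
            sites.append(Placement(f"s{i}", eid, off,
                                   x=ux + t * (dx - ux), y=uy + t * (dy - uy)))
        tab = pair_geometry_table(sites, [], y_tree)
        assert len(tab) == len(sites) * (len(sites) - 1) // 2
        assert (tab["d_e_m"] <= tab["d_w_m"] + 1e-9).all()

    def test_straight_river_euclidean_equals_watercourse(self, single_edge):
        sites = [Placement("a", "e0", 10.0, x=0.0, y=90.0),
                 Placement("b", "e0", 60.0, x=0.0, y=40.0)]
        tab = pair_geometry_table(sites, [], single_edge)
        assert tab.loc[0, "d_e_m"] == pytest.approx(tab.loc[0, "d_w_m"])

    @pytest.mark.parametrize("seed", [10, 11])
    def test_barrier_crossed_iff_fragments_differ(self, seed):
        net, sites, barriers = random_catchment(seed, n_sites=10, n_barriers=3)
        tab = pair_geometry_table(sites, barriers, net)
        assert (tab["barrier_crossed"] ==
                (tab["fragment_a"] != tab["fragment_b"])).all()
        assert (tab["barrier_crossed"] == (tab["n_barriers"] > 0)).all()
        assert (tab["d_e_m"] <= tab["d_w_m"] + 1e-9).all()

    def test_fragment_count_one_plus_separating_barriers(self, y_tree):
        # every barrier separates sites and every cut piece holds a site
        sites = [Placement("a", "b1", 10.0), Placement("b", "b2", 10.0),
                 Placement("c", "stem", 100.0), Placement("d", "stem", 290.0)]
        bars = [Placement("dam1", "stem", 50.0), Placement("dam2", "stem", 200.0)]
        fmap = assign_fragments(sites, bars, y_tree)
        assert len(set(fmap.site_to_fragment.values())) == 1 + len(bars)
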