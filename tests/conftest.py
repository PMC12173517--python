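import numpy as np
import pandas as pd
import pytest

from riversync import Placement, SimConfig, build_network, generate_riverscape


@pytest.fixture
def y_tree():
    """Two headwater branches (100 m, 200 m) joining at a confluence, stem
    300 m to the outlet."""
    edges = pd.DataFrame(
        {
            "edge_id": ["b1", "b2", "stem"],
            "up_node": ["h1", "h2", "conf"],
            "down_node": ["conf", "conf", "out"],
            "length_m": [100.0, 200.0, 300.0],
        }
    )
    coords = {"h1": (-50.0, 300.0), "h2": (50.0, 300.0),
              "conf": (0.0, 300.0), "out": (0.0, 0.0)}
    return build_network(edges, node_coords=coords)


@pytest.fixture
def single_edge():
    edges = pd.DataFrame(
        {"edge_id": ["e0"], "up_node": ["A"], "down_node": ["B"],
         "length_m": [100.0]}
    )
    return build_network(edges, node_coords={"A": (0.0, 100.0), "B": (0.0, 0.0)})


def random_catchment(seed, n_edges=20, n_sites=6, n_barriers=2):
    """One random catchment riverscape (network, sites, barriers)."""
    cfg = SimConfig(n_catchments=1, n_edges=n_edges, n_sites=n_sites,
                    n_barriers=n_barriers, seed=seed)
    scape = generate_riverscape(cfg).catchments["C0"]
    return scape.network, scape.sites, scape.barriers


def random_placements(net, n, rng, prefix="p"):
    """Uniform random placements on a network, for oracle comparisons."""
    edges = net.edges
    w = edges["length_m"].to_numpy()
    chosen = rng.choice(edges.index.to_numpy(), size=n, p=w / w.sum())
    out = []
    for i, eid in enumerate(chosen):
        off = float(rng.uniform(0, edges.loc[eid, "length_m"]))
        out.append(Placement(id=f"{prefix}{i}", edge=eid, offset_m=off))
    return out
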