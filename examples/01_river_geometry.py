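"""Build a small dendritic river network, place sites and a dam, and
compute the pairwise geometry the synchrony analysis runs on."""
import pandas as pd

from riversync import Placement, build_network, pair_geometry_table

# a Y-shaped river: two headwaters join a 300 m stem that drains to the outlet
edges = pd.DataFrame(
    {
        "edge_id": ["branch1", "branch2", "stem"],
        "up_node": ["h1", "h2", "conf"],
        "down_node": ["conf", "conf", "out"],
        "length_m": [100.0, 200.0, 300.0],
    }
)
coords = {"h1": (-70.0, 370.0), "h2": (140.0, 440.0),
          "conf": (0.0, 300.0), "out": (0.0, 0.0)}
net = build_network(edges, node_coords=coords)

sites = [
    Placement("up1", "branch1", 50.0, x=-35.0, y=335.0),
    Placement("up2", "branch2", 120.0, x=56.0, y=356.0),
    Placement("down", "stem", 250.0, x=0.0, y=50.0),
]
dam = [Placement("dam", "stem", 150.0)]

table = pair_geometry_table(sites, dam, net, catchment="Y")
print(table[["site_a", "site_b", "d_w_m", "flow_connected",
             "barrier_crossed", "fragment_a", "fragment_b"]])
# d_w_m is the along-river distance; the two headwater sites are
# flow-unconnected (their route descends through the confluence), share a
# fragment, and both are cut off from the downstream site by the stem dam.
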