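"""Simulate a riverscape with barrier-decoupled dynamics and compute
filtered pairwise Spearman synchrony."""
from riversync import (
    SimConfig,
    simulate_panel,
    synchrony_table,
    truncate_between_fragment_pairs,
)

cfg = SimConfig(n_catchments=2, n_edges=20, n_sites=25, n_barriers=4,
                barrier_multiplier=0.4, seed=1)
_, pairs, density = simulate_panel(cfg)

records, exclusions = synchrony_table(density, pairs, min_years=6)
records = truncate_between_fragment_pairs(records)

print(f"retained pairs: {len(records)}, excluded: {len(exclusions)}")
print(exclusions["reason"].value_counts().to_string())
within = records.loc[~records["barrier_crossed"], "rho"].mean()
between = records.loc[records["barrier_crossed"], "rho"].mean()
print(f"mean synchrony within fragments : {within:.3f}")
print(f"mean synchrony across barriers  : {between:.3f}")
# Within-fragment pairs are more synchronous: the generator multiplies the
# pair correlation by 0.4 whenever the route crosses a dam, and the
# distance truncation keeps the two groups on comparable distance ranges.
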