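"""Classify site pairs into fluvial synchrogram categories D1-D4 and test
whether adding barrier information improves model parsimony (AIC)."""
from riversync import (
    SimConfig,
    classify_pairs,
    compare_barrier_models,
    prepare_records,
    simulate_panel,
    synchrony_table,
)

cfg = SimConfig(barrier_multiplier=0.4, seed=5)
_, pairs, density = simulate_panel(cfg)
records, _ = synchrony_table(density, pairs)
records = prepare_records(records)

classified = classify_pairs(records)
print(classified["category"].value_counts().sort_index().to_string())

res = compare_barrier_models(classified)
print(f"AIC category-only model : {res.aic_without:.1f}")
print(f"AIC with barrier terms  : {res.aic_with:.1f}")
print(f"delta AIC = {res.delta_aic:.1f}, LRT p = {res.lrt_p:.2e}")
print(res.category_summary.round(3).to_string(index=False))
# D1 pairs (short Euclidean distance, d_E ~ d_W: same branch, nearby) show
# the largest synchrony gap between same-fragment and barrier-separated
# pairs, so the barrier-aware model wins decisively when beta < 1.
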