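# riversync

Spatial synchrony of river fish populations in fragmented dendritic
networks: how dams decouple population dynamics, and whether asynchrony
among subpopulations stabilises fragment metapopulations.

## The problem

Populations at different sites in a river co-fluctuate ("spatial
synchrony") through dispersal and shared environment. Rivers are trees:
two nearby sites can be *flow-unconnected* (different branches), and dams
cut the network into *fragments*. riversync asks, for long-term
electrofishing density panels:

1. Does synchrony between site pairs decay with watercourse distance
   (d_W), drop across fragment borders, and differ between flow-connected
   and flow-unconnected pairs?
2. Within a fragment, does subpopulation asynchrony buy metapopulation
   stability (a portfolio effect), and how does fragment synchrony relate
   to persistence, productivity, variability and trajectory?
3. Does adding barrier information improve the "fluvial synchrogram"
   framework (pair classes D1–D4 from d_E and d_E/d_W)?

The core statistical objects:

- Pair synchrony: Spearman ρ over ≥6 (sensitivity: ≥10) matching years.
- Mixed model: ρ ~ √d_W × flow-connected × barrier-crossed with a
  catchment random intercept and a **multimembership** site random effect
  (each pair loads on both member sites) — estimated by profiled REML.
- Portfolio effect: PE = CV_uniform / CV_observed, with CV_uniform
  extrapolated from Taylor's power law (variance = c · meanᶻ); PE > 1
  means the metapopulation is steadier than one uniform population.

All stages run on synthetic riverscapes whose pairwise correlation is
s0·exp(−d_W/ρ)·β^[barrier]·γ^[flow-unconnected] with zero-inflated
log-normal observation — so the full chain is testable without data
downloads. See `docs/methods.md` for the models and assumptions.

## Worked example

```python
from riversync import (SimConfig, simulate_panel, synchrony_table,
                       truncate_between_fragment_pairs, prepare_records,
                       build_design, threeway_terms, fit_lmm, wald_tests)

cfg = SimConfig(barrier_multiplier=0.4, seed=42)   # trout-like world
_, pairs, density = simulate_panel(cfg)
records, _ = synchrony_table(density, pairs)
records = prepare_records(truncate_between_fragment_pairs(records))
X, rand = build_design(records, threeway_terms())
fit = fit_lmm(X, records["rho"].to_numpy(), rand)
print(wald_tests(fit).round(4))
```

prints (abridged):

```
                 term  estimate  std_error  t_value  p_value
          (intercept)    0.1895     0.0275   6.8874   0.0000
           sqrt_dw_km   -0.0383     0.0070  -5.5065   0.0000
       flow_connected    0.1306     0.0345   3.7890   0.0002
      barrier_crossed   -0.1152     0.0489  -2.3569   0.0184
sqrt_dw_km:barrier_crossed  0.0220   0.0119   1.8433   0.0653
```

Synchrony falls with √distance (−0.038 per √km), flow-connected pairs are
more synchronous (+0.13), pairs separated by a dam are less synchronous
(−0.12), and the positive distance × barrier term shows the deficit
shrinking with distance — separated and unseparated pairs converge far
apart. Variance components attribute pair-level noise to catchments,
individual sites (multimembership) and residual.

The `examples/` scripts walk each capability: network geometry and
fragments (01), filtered pair synchrony (02), the mixed model (03), Taylor
fit and portfolio effect (04), synchrogram categories and the barrier AIC
test (05), and the end-to-end pipeline with CSV reports and manifest (06).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the empirical type-I error of the three-way
multimembership mixed model: 500 null panels (identity correlation, no
trends) are simulated on riverscapes of 4 catchments × 40 sites over 30
years (per-site sampling probability 0.5), pairwise synchrony is computed
and the full model fitted per panel, and the script reports the percentage
of p-values below α = 0.05 pooled over the non-intercept terms. The JSON
maps each target id to `{"value": ..., "n": ...}`.
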