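"""Run the complete analysis end-to-end on a synthetic riverscape with a
trout-like (barrier-sensitive) and a pike-like (barrier-insensitive)
species, writing CSV reports plus a run manifest."""
from riversync import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(
    out_dir="scratch/pipeline_demo",
    seed=11,
    sim=SimConfig(n_catchments=3, n_edges=20, n_sites=30, n_barriers=4,
                  n_years=30, sampling_prob=0.6),
)
res = run_pipeline(cfg)

for species, r in res["species"].items():
    fit = r["flow_connected"]
    i = fit.terms.index("barrier_crossed")
    print(f"{species}: barrier effect {fit.beta[i]:+.3f} "
          f"(p = {fit.pvalues[i]:.3g}); "
          f"synchrony records n = {len(r['records'])}")
    if r["synchrogram"] is not None:
        print(f"  synchrogram delta AIC = {r['synchrogram'].delta_aic:+.1f} "
              "(negative favours the barrier-aware model)")
print("outputs:", *(p.name for p in res["outputs"]), sep="\n  ")
# The trout-like species (barrier multiplier 0.4) shows a negative barrier
# effect and an AIC gain from barrier terms; the pike-like species
# (multiplier 1.0) shows neither — the species contrast of the analysis.
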