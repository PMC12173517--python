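"""End-to-end analysis pipeline.

``run_pipeline`` sequences the whole analysis — riverscape (simulated or
ingested), pairwise geometry, filtered synchrony, mixed models, fragment
summaries, portfolio and performance associations, synchrogram
comparison — into a deterministic directory of CSV outputs plus a
machine-readable manifest. ``sensitivity_run`` repeats it with the
6- vs 10-matching-year filters and tabulates sign/significance agreement.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .lmm import (
    LMMConvergenceError,
    build_design,
    distance_barrier_terms,
    fit_lmm,
    main_effect_terms,
    prepare_records,
    r2_nakagawa,
    threeway_terms,
)
from .network import pair_geometry_table
from .performance import performance_associations, performance_table
from .portfolio import pe_synchrony_association, portfolio_table
from .simulate import SimConfig, generate_riverscape, simulate_panel
from .synchrogram import classify_pairs, compare_barrier_models
from .synchrony import (
    fragment_mean_synchrony,
    synchrony_table,
    truncate_between_fragment_pairs,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "sensitivity_run"]

logger = logging.getLogger(__name__)

DEFAULT_SPECIES = {
    "trout_like": {"decay_range_m": 10_000.0, "barrier_multiplier": 0.4,
                   "flow_unconnected_multiplier": 0.5},
    "pike_like": {"decay_range_m": 1e9, "barrier_multiplier": 1.0,
                  "flow_unconnected_multiplier": 1.0, "s0": 0.4},
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``species`` maps a species name to SimConfig field overrides
    (synthetic mode) — defaults to a trout-like and a pike-like
    archetype. In real mode, per-catchment network files plus site,
    barrier and density tables are read instead.
    """

    out_dir: str = "riversync_out"
    seed: int = 0
    mode: str = "synthetic"
    min_years: int = 6
    min_subpops: int = 4
    min_occasions: int = 10
    mm_weight: float = 1.0
    sim: SimConfig = field(default_factory=SimConfig)
    species: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    # real mode inputs
    catchments: list = field(default_factory=list)  # [{id, network, outlet_xy}]
    sites_path: str | None = None
    barriers_path: str | None = None
    density_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, seed: int, written: list) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
    written.append(path)


def _fit_summary_rows(model_name: str, fit, records_n: int) -> list[dict]:
    r2m, r2c = r2_nakagawa(fit)
    rows = []
    for term, est, se, t, p in zip(fit.terms, fit.beta, fit.se, fit.tvalues,
                                   fit.pvalues):
        rows.append(
            {"model": model_name, "term": term,
             "transformation": "(sqrt)" if "sqrt_dw" in term else "",
             "estimate": est, "std_error": se, "t_value": t, "p_value": p,
             "n": records_n, "r2_marginal": r2m, "r2_conditional": r2c,
             "singular": fit.singular,
             **{f"var_{k}": v for k, v in fit.varcomp.items()},
             "var_residual": fit.sigma2_resid}
        )
    return rows


def _load_real_riverscape(cfg: RunConfig):
    sites_df = rio.read_sites(cfg.sites_path)
    barriers_df = rio.read_barriers(cfg.barriers_path)
    pair_tables = []
    fragment_of: dict = {}
    for entry in cfg.catchments:
        cid = entry["id"]
        net = rio.read_geojson_network(entry["network"], tuple(entry["outlet_xy"]))
        c_sites = sites_df.loc[sites_df["catchment"] == cid]
        sites = rio.snap_to_network(c_sites, net)
        barriers = rio.snap_to_network(barriers_df, net)
        # keep only barriers actually near this catchment's network
        geoms = getattr(net, "edge_geoms")
        from shapely.geometry import Point
        barriers = [
            b for b, (_, row) in zip(barriers, barriers_df.iterrows())
            if min(g.distance(Point(row.x, row.y)) for g in geoms.values()) < 1e3
        ]
        pt = pair_geometry_table(sites, barriers, net, catchment=cid)
        pair_tables.append(pt)
        for row in pt.itertuples(index=False):
            fragment_of[row.site_a] = row.fragment_a
            fragment_of[row.site_b] = row.fragment_b
    return pd.concat(pair_tables, ignore_index=True), fragment_of


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a result bundle (in-memory tables,
    output paths, manifest). Outputs are deterministic given (data,
    config, seed); any stage failure removes partial outputs and raises
    :class:`StageError` naming the stage."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"config": cfg}
    stage = "setup"
    try:
        # ---- geometry -----------------------------------------------------
        stage = "geometry"
        if cfg.mode == "synthetic":
            riverscape = generate_riverscape(
                dataclasses.replace(cfg.sim, seed=cfg.seed)
            )
            pair_table = riverscape.pair_table()
            fragment_of = {}
            for scape in riverscape.catchments.values():
                for row in scape.pair_table.itertuples(index=False):
                    fragment_of[row.site_a] = row.fragment_a
                    fragment_of[row.site_b] = row.fragment_b
        else:
            riverscape = None
            pair_table, fragment_of = _load_real_riverscape(cfg)
        logger.info("geometry: %d site pairs", len(pair_table))
        _write_csv(pair_table, out / "pair_geometry.csv", cfg.seed, written)
        fmap = pd.DataFrame(sorted(fragment_of.items()),
                            columns=["site", "fragment"])
        _write_csv(fmap, out / "fragment_map.csv", cfg.seed, written)
        results["pair_table"] = pair_table

        # ---- per-species panels -------------------------------------------
        stage = "density"
        panels: dict[str, pd.DataFrame] = {}
        if cfg.mode == "synthetic":
            ss = np.random.SeedSequence(cfg.seed)
            for name, child in zip(sorted(cfg.species), ss.spawn(len(cfg.species))):
                sp_cfg = dataclasses.replace(cfg.sim, **cfg.species[name])
                sp_seed = int(child.generate_state(1)[0] % (2**31))
                _, _, density = simulate_panel(sp_cfg, riverscape=riverscape,
                                               seed=sp_seed)
                panels[name] = density
        else:
            density = rio.read_density(cfg.density_path)
            if "species" in density.columns:
                for name, grp in density.groupby("species"):
                    panels[name] = grp.drop(columns="species")
            else:
                panels["all"] = density

        results["species"] = {}
        for name, density in panels.items():
            results["species"][name] = _analyse_species(
                name, density, pair_table, fragment_of, cfg, out, written
            )

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "mode": cfg.mode,
            "min_years": cfg.min_years,
            "species": sorted(panels),
            "n_pairs_geometry": int(len(pair_table)),
            "outputs": [p.name for p in written],
            "package": "riversync 0.1.0",
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(out / "manifest.json")
        results["manifest"] = manifest
        results["outputs"] = list(written)
        return results
    except StageError:
        raise
    except Exception as err:  # remove partial outputs, name the stage
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise StageError(stage, err) from err


def _analyse_species(name, density, pair_table, fragment_of, cfg, out, written):
    seed = cfg.seed
    res: dict = {}
    stage = f"synchrony[{name}]"
    try:
        records, exclusions = synchrony_table(density, pair_table,
                                              min_years=cfg.min_years)
        logger.info("%s: %d synchrony records (%d excluded)",
                    name, len(records), len(exclusions))
        if records.empty:
            logger.warning("%s: empty species panel, skipped", name)
            res["skipped"] = "no synchrony records"
            return res
        records = truncate_between_fragment_pairs(records)
        logger.info("%s: %d records after distance truncation", name, len(records))
        records = prepare_records(records)
        _write_csv(records, out / f"synchrony_{name}.csv", seed, written)
        _write_csv(exclusions, out / f"synchrony_exclusions_{name}.csv", seed, written)
        res["records"] = records

        stage = f"lmm[{name}]"
        rows = []
        X, rand = build_design(records, threeway_terms(), mm_weight=cfg.mm_weight)
        fit3 = fit_lmm(X, records["rho"].to_numpy(), rand)
        rows += _fit_summary_rows("threeway", fit3, len(records))
        res["threeway"] = fit3
        for flag, label in ((True, "flow_connected"), (False, "flow_unconnected")):
            sub = records.loc[records["flow_connected"] == flag]
            if sub.empty or sub["barrier_crossed"].nunique() < 2:
                continue
            Xs, rs = build_design(sub, distance_barrier_terms(),
                                  mm_weight=cfg.mm_weight)
            fit = fit_lmm(Xs, sub["rho"].to_numpy(), rs)
            rows += _fit_summary_rows(label, fit, len(sub))
            res[label] = fit
            inter = [t for t in fit.terms if ":" in t]
            if flag and inter and fit.pvalues[fit.terms.index(inter[0])] > 0.05:
                Xm, rm = build_design(sub, main_effect_terms(),
                                      mm_weight=cfg.mm_weight)
                fitm = fit_lmm(Xm, sub["rho"].to_numpy(), rm)
                rows += _fit_summary_rows("flow_connected_main_effects", fitm,
                                          len(sub))
                res["flow_connected_main_effects"] = fitm
        lmm_df = pd.DataFrame(rows)
        _write_csv(lmm_df, out / f"lmm_{name}.csv", seed, written)
        res["lmm_table"] = lmm_df

        stage = f"fragments[{name}]"
        frag_sync = fragment_mean_synchrony(records)
        _write_csv(frag_sync, out / f"fragment_synchrony_{name}.csv", seed, written)
        res["fragment_synchrony"] = frag_sync

        stage = f"portfolio[{name}]"
        pe_df = portfolio_table(density, fragment_of,
                                min_subpops=cfg.min_subpops,
                                min_occasions=cfg.min_occasions)
        pe_df = pe_df.merge(
            frag_sync[["fragment", "catchment"]], on="fragment", how="left"
        )
        _write_csv(pe_df, out / f"portfolio_{name}.csv", seed, written)
        res["portfolio"] = pe_df
        try:
            res["pe_association"] = pe_synchrony_association(pe_df, frag_sync)
        except (ValueError, LMMConvergenceError) as err:
            logger.warning("%s: PE association skipped (%s)", name, err)
            res["pe_association"] = None

        stage = f"performance[{name}]"
        perf = performance_table(density, fragment_of)
        assoc = performance_associations(perf, frag_sync, pe_table=pe_df)
        _write_csv(perf, out / f"performance_{name}.csv", seed, written)
        _write_csv(assoc, out / f"performance_associations_{name}.csv", seed, written)
        res["performance"] = perf
        res["performance_associations"] = assoc

        stage = f"synchrogram[{name}]"
        classified = classify_pairs(records)
        res["classified"] = classified
        try:
            cmpres = compare_barrier_models(classified, mm_weight=cfg.mm_weight)
            comp_df = pd.DataFrame(
                [{"aic_without_barriers": cmpres.aic_without,
                  "aic_with_barriers": cmpres.aic_with,
                  "delta_aic": cmpres.delta_aic, "lrt_stat": cmpres.lrt_stat,
                  "lrt_df": cmpres.lrt_df, "lrt_p": cmpres.lrt_p,
                  "dropped_cells": ";".join(cmpres.dropped_cells)}]
            )
            res["synchrogram"] = cmpres
        except ValueError as err:
            logger.warning("%s: synchrogram comparison skipped (%s)", name, err)
            comp_df = pd.DataFrame()
            res["synchrogram"] = None
        _write_csv(comp_df, out / f"synchrogram_{name}.csv", seed, written)
        if res["synchrogram"] is not None:
            _write_csv(cmpres.category_summary,
                       out / f"synchrogram_categories_{name}.csv", seed, written)
        return res
    except Exception as err:
        raise StageError(stage, err) from err


def sensitivity_run(cfg: RunConfig) -> dict:
    """Paired min_years = 6 vs 10 runs plus a sign/significance agreement
    table per species and model term."""
    out = Path(cfg.out_dir)
    runs = {}
    for my in (6, 10):
        sub = dataclasses.replace(cfg, min_years=my,
                                  out_dir=str(out / f"min_years_{my}"))
        runs[my] = run_pipeline(sub)
    rows = []
    for sp in runs[6]["species"]:
        t6 = runs[6]["species"][sp].get("lmm_table")
        t10 = runs[10]["species"][sp].get("lmm_table")
        if t6 is None or t10 is None:
            continue
        merged = t6.merge(t10, on=["model", "term"], suffixes=("_6", "_10"))
        for r in merged.itertuples(index=False):
            rows.append(
                {"species": sp, "model": r.model, "term": r.term,
                 "sign_6": np.sign(r.estimate_6), "sign_10": np.sign(r.estimate_10),
                 "sig_6": r.p_value_6 < 0.05, "sig_10": r.p_value_10 < 0.05,
                 "sign_agrees": np.sign(r.estimate_6) == np.sign(r.estimate_10),
                 "sig_agrees": (r.p_value_6 < 0.05) == (r.p_value_10 < 0.05)}
            )
    comparison = pd.DataFrame(rows)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(comparison, out / "sensitivity_comparison.csv", cfg.seed, [])
    return {"runs": runs, "comparison": comparison}
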