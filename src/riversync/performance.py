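"""Fragment-level population performance metrics and their association
with synchrony.

Five metrics per fragment: occurrence rate, mean log-density, standard
deviation of log-density (site-level, averaged over the fragment's
sites), residual standard deviation and trajectory slope from per-site
detrending regressions (fragment-level). Each metric — plus the
portfolio effect — is regressed on fragment mean synchrony in a mixed
model with a catchment random intercept, and the six p-values per
species are Benjamini-Hochberg adjusted.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMConvergenceError, catchment_intercept, fit_lmm

__all__ = [
    "site_metrics",
    "site_metrics_table",
    "aggregate_to_fragment",
    "fragment_trend_model",
    "performance_table",
    "bh_adjust",
    "performance_associations",
]


def site_metrics(densities: np.ndarray) -> tuple[float, float, float]:
    """(occurrence rate, mean log-density, sd of log-density) of one site.

    Log-density is log(density + 1); occurrence is the fraction of
    sampled occasions with positive density; sd uses ddof=1 (0 for a
    single occasion).
    """
    x = np.asarray(densities, dtype=float)
    if len(x) < 1:
        raise ValueError("site has no sampled occasion")
    occ = float((x > 0).mean())
    logd = np.log(x + 1.0)
    sd = float(logd.std(ddof=1)) if len(x) > 1 else 0.0
    return occ, float(logd.mean()), sd


def site_metrics_table(density: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for site, g in density.groupby("site", sort=True):
        occ, ml, sd = site_metrics(g["density"].to_numpy())
        rows.append({"site": site, "occurrence": occ, "mean_log_density": ml,
                     "sd_log_density": sd, "n_occasions": len(g)})
    return pd.DataFrame(rows)


def aggregate_to_fragment(site_table: pd.DataFrame, fragment_of: dict) -> pd.DataFrame:
    """Unweighted fragment means of the site-level metrics."""
    t = site_table.copy()
    t["fragment"] = t["site"].map(fragment_of)
    agg = (
        t.groupby("fragment", sort=True)
        .agg(
            occurrence=("occurrence", "mean"),
            mean_log_density=("mean_log_density", "mean"),
            sd_log_density=("sd_log_density", "mean"),
            n_sites=("site", "size"),
        )
        .reset_index()
    )
    return agg


def fragment_trend_model(
    fragment_panel: pd.DataFrame, min_site_occasions: int = 3
) -> tuple[float, float] | None:
    """Detrended variability and mean trajectory of one fragment.

    Equivalent to regressing log(density+1) on year in interaction with
    site identity (separate intercept and slope per site): per-site OLS
    slopes are averaged with equal weights and the pooled residuals give
    the residual sd. Sites with fewer than ``min_site_occasions``
    occasions (or a single distinct year) are left out; returns None if
    no site qualifies.

    Adding a common linear trend to every site changes the trajectory,
    never the residual sd (the detrending property).
    """
    residuals = []
    slopes = []
    for _, g in fragment_panel.groupby("site"):
        if len(g) < min_site_occasions or g["year"].nunique() < 2:
            continue
        yr = g["year"].to_numpy(dtype=float)
        logd = np.log(g["density"].to_numpy(dtype=float) + 1.0)
        coef = np.polyfit(yr, logd, 1)
        slopes.append(coef[0])
        residuals.append(logd - np.polyval(coef, yr))
    if not slopes:
        return None
    resid = np.concatenate(residuals)
    rsd = float(resid.std(ddof=1)) if len(resid) > 1 else 0.0
    return rsd, float(np.mean(slopes))


def performance_table(
    density: pd.DataFrame, fragment_of: dict, min_site_occasions: int = 3
) -> pd.DataFrame:
    """All five performance metrics per fragment.

    Columns: fragment, occurrence, mean_log_density, sd_log_density,
    residual_sd, trajectory, n_sites. Fragments whose trend model is
    degenerate get NaN for the model-based metrics.
    """
    site_tab = site_metrics_table(density)
    agg = aggregate_to_fragment(site_tab, fragment_of)
    density = density.copy()
    density["fragment"] = density["site"].map(fragment_of)
    trend = {}
    for frag, panel in density.groupby("fragment", sort=True):
        res = fragment_trend_model(panel, min_site_occasions=min_site_occasions)
        trend[frag] = res if res is not None else (np.nan, np.nan)
    agg["residual_sd"] = agg["fragment"].map(lambda f: trend[f][0])
    agg["trajectory"] = agg["fragment"].map(lambda f: trend[f][1])
    return agg


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


PERFORMANCE_METRICS = [
    "pe",
    "occurrence",
    "mean_log_density",
    "sd_log_density",
    "residual_sd",
    "trajectory",
]


def performance_associations(
    perf_table: pd.DataFrame,
    fragment_synchrony: pd.DataFrame,
    pe_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mixed-model associations of each performance metric (and the
    portfolio effect) with fragment mean synchrony.

    One fit per response, catchment random intercept; the six nominal
    p-values are BH-adjusted as one family. Output rows mirror a
    metric-by-statistics table: estimate, t, nominal p, adjusted p,
    number of fragments and a singular-fit flag.
    """
    base = perf_table.merge(fragment_synchrony, on="fragment", how="inner")
    if pe_table is not None:
        pe = pe_table.loc[pe_table["eligible"], ["fragment", "pe"]]
        base = base.merge(pe, on="fragment", how="left")

    rows = []
    for metric in PERFORMANCE_METRICS:
        if metric not in base.columns:
            continue
        data = base.dropna(subset=[metric, "mean_rho"])
        if len(data) < 4:
            rows.append({"metric": metric, "n_fragments": len(data),
                         "estimate": np.nan, "t_value": np.nan,
                         "p_value": np.nan, "singular": False,
                         "note": "too few fragments"})
            continue
        X = pd.DataFrame({"(intercept)": np.ones(len(data)),
                          "mean_rho": data["mean_rho"].to_numpy()})
        try:
            fit = fit_lmm(X, data[metric].to_numpy(), [catchment_intercept(data)])
        except (LMMConvergenceError, np.linalg.LinAlgError) as err:
            rows.append({"metric": metric, "n_fragments": len(data),
                         "estimate": np.nan, "t_value": np.nan,
                         "p_value": np.nan, "singular": False, "note": str(err)})
            continue
        i = fit.terms.index("mean_rho")
        rows.append({"metric": metric, "n_fragments": len(data),
                     "estimate": float(fit.beta[i]), "t_value": float(fit.tvalues[i]),
                     "p_value": float(fit.pvalues[i]), "singular": fit.singular,
                     "note": ""})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    return out
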