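"""Portfolio effect of fragment metapopulations.

Taylor's power law (variance = c * mean^z across subpopulation time
series, fitted on log10-log10 axes) calibrates how a hypothetical single
uniform population of the same total size would fluctuate. The
mean-variance-CV portfolio effect of a fragment is the ratio of that
extrapolated uniform CV to the observed CV of the summed metapopulation
series; PE > 1 means the real, imperfectly synchronised metapopulation
is more stable than its uniform counterpart.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lmm import LMMFit, catchment_intercept, fit_lmm

__all__ = [
    "TaylorFit",
    "PEResult",
    "taylor_fit",
    "choose_pe_metric",
    "portfolio_effect",
    "portfolio_table",
    "pe_synchrony_association",
]


@dataclass
class TaylorFit:
    """Taylor power-law fit: log10 var = log10_c + z * log10 mean."""

    z: float
    log10_c: float
    se_z: float
    n_points: int
    points: pd.DataFrame  # columns: subpop, mean, variance


def taylor_fit(subpop_series: dict, min_points: int = 3) -> TaylorFit:
    """OLS of log10(variance) on log10(mean) across subpopulation series.

    ``subpop_series`` maps a subpopulation id to an array-like of
    densities (its time series, pooled over all metapopulations of one
    species). Series need >= 2 observations and positive mean and
    variance to contribute a point.
    """
    rows = []
    for sid, series in subpop_series.items():
        x = np.asarray(series, dtype=float)
        x = x[np.isfinite(x)]
        if len(x) < 2:
            continue
        m = x.mean()
        v = x.var(ddof=1)
        if m > 0 and v > 0:
            rows.append({"subpop": sid, "mean": m, "variance": v})
    pts = pd.DataFrame(rows)
    if len(pts) < min_points:
        raise ValueError(
            f"Taylor fit needs >= {min_points} usable (mean, variance) points, "
            f"got {len(pts)}"
        )
    X = sm.add_constant(np.log10(pts["mean"].to_numpy()))
    fit = sm.OLS(np.log10(pts["variance"].to_numpy()), X).fit()
    return TaylorFit(
        z=float(fit.params[1]),
        log10_c=float(fit.params[0]),
        se_z=float(fit.bse[1]),
        n_points=len(pts),
        points=pts,
    )


def choose_pe_metric(z: float, tol: float = 0.1) -> str:
    """Pick the PE metric from the Taylor exponent.

    The average-CV PE assumes z = 2; when |z - 2| exceeds ``tol`` the
    more conservative mean-variance CV is required.
    """
    return "average_cv" if abs(z - 2.0) <= tol else "mean_variance_cv"


@dataclass
class PEResult:
    fragment: str
    n_subpops: int
    n_years: int
    cv_observed: float
    cv_uniform: float
    pe: float
    eligible: bool
    reason: str | None = None


def portfolio_effect(
    fragment_panel: pd.DataFrame,
    taylor: TaylorFit,
    fragment: str = "",
    min_subpops: int = 4,
    min_occasions: int = 10,
) -> PEResult:
    """Mean-variance-CV portfolio effect of one fragment.

    ``fragment_panel`` is a long DataFrame (site, year, density) of the
    fragment's sites. Eligibility: at least ``min_subpops`` subpopulations
    each sampled on at least ``min_occasions`` occasions. The
    metapopulation series sums densities over the years in which *every*
    eligible subpopulation was sampled (strict common-year rule).
    """
    counts = fragment_panel.groupby("site")["year"].size()
    eligible_sites = counts.index[counts >= min_occasions]
    k = len(eligible_sites)
    if k < min_subpops:
        return PEResult(fragment, k, 0, np.nan, np.nan, np.nan, False,
                        f"only {k} subpopulations with >= {min_occasions} occasions")
    sub = fragment_panel[fragment_panel["site"].isin(eligible_sites)]
    wide = sub.pivot_table(index="year", columns="site", values="density")
    common = wide.dropna()
    if len(common) < 2:
        return PEResult(fragment, k, len(common), np.nan, np.nan, np.nan, False,
                        "fewer than 2 common sampling years")
    meta = common.sum(axis=1).to_numpy()
    mu = meta.mean()
    if mu <= 0:
        return PEResult(fragment, k, len(common), np.nan, np.nan, np.nan, False,
                        "metapopulation mean is zero")
    cv_obs = meta.std(ddof=1) / mu
    if cv_obs == 0:
        return PEResult(fragment, k, len(common), 0.0, np.nan, np.nan, False,
                        "constant metapopulation series")
    # Taylor-extrapolated CV of one uniform population of the same size
    var_uniform = 10.0 ** taylor.log10_c * mu ** taylor.z
    cv_uniform = float(np.sqrt(var_uniform) / mu)
    return PEResult(fragment, k, len(common), float(cv_obs), cv_uniform,
                    cv_uniform / float(cv_obs), True)


def portfolio_table(
    density: pd.DataFrame,
    fragment_of: dict,
    taylor: TaylorFit | None = None,
    min_subpops: int = 4,
    min_occasions: int = 10,
) -> pd.DataFrame:
    """Portfolio effect for every fragment of a species panel.

    ``fragment_of`` maps site -> fragment. When ``taylor`` is None the
    power law is first fitted across all subpopulation series of the
    panel (species-level pooling).
    """
    density = density.copy()
    density["fragment"] = density["site"].map(fragment_of)
    if taylor is None:
        taylor = taylor_fit(
            {s: g["density"].to_numpy() for s, g in density.groupby("site")}
        )
    rows = []
    for frag, panel in density.groupby("fragment", sort=True):
        r = portfolio_effect(panel, taylor, fragment=frag,
                             min_subpops=min_subpops, min_occasions=min_occasions)
        rows.append(
            {"fragment": frag, "n_subpops": r.n_subpops, "n_years": r.n_years,
             "cv_obs": r.cv_observed, "cv_uniform": r.cv_uniform, "pe": r.pe,
             "eligible": r.eligible, "reason": r.reason}
        )
    return pd.DataFrame(rows)


def pe_synchrony_association(
    pe_table: pd.DataFrame,
    fragment_synchrony: pd.DataFrame,
    min_fragments: int = 5,
) -> LMMFit:
    """Mixed model of the portfolio effect on fragment mean synchrony with
    a catchment random intercept. Sign and p of the slope are the result
    of interest."""
    right = fragment_synchrony
    if "catchment" in pe_table.columns and "catchment" in right.columns:
        right = right.drop(columns="catchment")
    data = pe_table.loc[pe_table["eligible"]].merge(right, on="fragment",
                                                    how="inner")
    if len(data) < min_fragments:
        raise ValueError(f"only {len(data)} eligible fragments (< {min_fragments})")
    X = pd.DataFrame(
        {"(intercept)": np.ones(len(data)), "mean_rho": data["mean_rho"].to_numpy()}
    )
    rand = [catchment_intercept(data)]
    return fit_lmm(X, data["pe"].to_numpy(), rand)
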