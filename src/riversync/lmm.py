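"""Linear mixed models for pairwise synchrony data.

Each observation is a site pair, so the random-effects structure combines
a catchment random intercept with a *multimembership* site effect: the
observation loads on both of its member sites (incidence weight 1 per
site by default). Variance components are estimated by profiled REML (or
ML for model comparison), with the Woodbury identity keeping every
likelihood evaluation in the (small) random-effects dimension.

Wald t statistics use the large-sample normal reference, appropriate for
the hundreds-to-thousands of pairs these datasets contain.
"""
from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp
from scipy.stats import chi2, norm

__all__ = [
    "RandomEffect",
    "LMMFit",
    "LMMConvergenceError",
    "DesignError",
    "multimembership_sites",
    "catchment_intercept",
    "build_design",
    "threeway_terms",
    "distance_barrier_terms",
    "main_effect_terms",
    "fit_lmm",
    "wald_tests",
    "r2_nakagawa",
    "type1_simulation",
]

SINGULAR_TOL = 1e-6  # variance ratio below which a component sits on the boundary


class LMMConvergenceError(RuntimeError):
    """REML/ML optimiser failed; message carries the optimiser trace."""


class DesignError(ValueError):
    """Fixed-effects design matrix is rank deficient."""


@dataclass
class RandomEffect:
    """One random-effects block: an n x q incidence matrix and its labels."""

    name: str
    Z: sp.csr_matrix
    labels: np.ndarray

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


def multimembership_sites(records: pd.DataFrame, weight: float = 1.0) -> RandomEffect:
    """Incidence matrix with ``weight`` in each of the two member-site
    columns of every observation (pair)."""
    sites = np.array(sorted(set(records["site_a"]) | set(records["site_b"]), key=str),
                     dtype=object)
    idx = {s: i for i, s in enumerate(sites)}
    n = len(records)
    rows = np.repeat(np.arange(n), 2)
    cols = np.empty(2 * n, dtype=int)
    cols[0::2] = [idx[s] for s in records["site_a"]]
    cols[1::2] = [idx[s] for s in records["site_b"]]
    Z = sp.csr_matrix(
        (np.full(2 * n, float(weight)), (rows, cols)), shape=(n, len(sites))
    )
    return RandomEffect("site", Z, sites)


def catchment_intercept(records: pd.DataFrame, column: str = "catchment") -> RandomEffect:
    """Indicator matrix of catchment membership (random intercept)."""
    levels = np.array(sorted(set(records[column]), key=str), dtype=object)
    idx = {c: i for i, c in enumerate(levels)}
    n = len(records)
    cols = np.array([idx[c] for c in records[column]])
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), cols)), shape=(n, len(levels)))
    return RandomEffect(column, Z, levels)


# ---------------------------------------------------------------------------
# fixed-effects design
# ---------------------------------------------------------------------------

def threeway_terms() -> list[str]:
    """Full factorial of sqrt-distance, flow-connectedness and barrier
    crossing (7 non-intercept columns)."""
    d, f, g = "sqrt_dw_km", "flow_connected", "barrier_crossed"
    return [d, f, g, f"{d}:{f}", f"{d}:{g}", f"{f}:{g}", f"{d}:{f}:{g}"]


def distance_barrier_terms() -> list[str]:
    """sqrt-distance x barrier crossing (flow-stratified models)."""
    d, g = "sqrt_dw_km", "barrier_crossed"
    return [d, g, f"{d}:{g}"]


def main_effect_terms() -> list[str]:
    return ["sqrt_dw_km", "barrier_crossed"]


def _term_columns(records: pd.DataFrame, term: str) -> pd.DataFrame:
    """Expand one term (possibly a ':' product) into design columns."""
    factors = term.split(":")
    parts: list[pd.DataFrame] = []
    for f in factors:
        if f not in records.columns:
            raise KeyError(f"term {term!r}: column {f!r} not in records")
        col = records[f]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique(), key=str)
            dummies = pd.DataFrame(
                {f"{f}[{lv}]": (col == lv).to_numpy(dtype=float)
                 for lv in levels[1:]}
            )
            parts.append(dummies)
        else:
            parts.append(pd.DataFrame({f: col.to_numpy(dtype=float)}))
    out = parts[0]
    for nxt in parts[1:]:
        cols = {}
        for a in out.columns:
            for b in nxt.columns:
                cols[f"{a}:{b}"] = out[a].to_numpy() * nxt[b].to_numpy()
        out = pd.DataFrame(cols)
    return out


def prepare_records(records: pd.DataFrame) -> pd.DataFrame:
    """Add derived model covariates (sqrt watercourse distance in km)."""
    out = records.copy()
    out["sqrt_dw_km"] = np.sqrt(out["d_w_m"].to_numpy(dtype=float) / 1000.0)
    return out


def build_design(
    records: pd.DataFrame,
    fixed_terms: list[str],
    random_terms: tuple = ("catchment", "site"),
    mm_weight: float = 1.0,
) -> tuple[pd.DataFrame, list[RandomEffect]]:
    """Fixed design matrix (with intercept) and random-effect blocks.

    Raises :class:`DesignError` naming the collinear columns when the
    fixed design is rank deficient.
    """
    blocks = [pd.DataFrame({"(intercept)": np.ones(len(records))})]
    for term in fixed_terms:
        blocks.append(_term_columns(records, term))
    X = pd.concat(blocks, axis=1)
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, _, piv = sla.qr(A, mode="economic", pivoting=True)
        bad = [X.columns[piv[i]] for i in range(rank, A.shape[1])]
        raise DesignError(f"rank-deficient fixed design; collinear columns: {bad}")

    random: list[RandomEffect] = []
    for rt in random_terms:
        if rt == "site":
            random.append(multimembership_sites(records, weight=mm_weight))
        else:
            random.append(catchment_intercept(records, column=rt))
    return X, random


# ---------------------------------------------------------------------------
# REML / ML estimation
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Fitted mixed model.

    ``varcomp`` maps each random-effect name to its variance on the
    response scale; ``sigma2_resid`` is the residual variance. ``loglik``
    is the REML or ML log-likelihood according to ``method``; ``aic`` is
    -2 loglik + 2k and is only meaningful for model comparison when
    ``method == 'ml'``.
    """

    terms: list
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    cov_beta: np.ndarray
    varcomp: dict
    sigma2_resid: float
    loglik: float
    method: str
    n: int
    p: int
    singular: bool
    converged: bool
    n_iter: int
    var_fixed: float
    message: str = ""

    @property
    def k_params(self) -> int:
        return self.p + len(self.varcomp) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.terms, name="estimate")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "std_error": self.se,
                "t_value": self.tvalues,
                "p_value": self.pvalues,
            }
        )


def _expand(tau: np.ndarray, sizes: list[int]) -> np.ndarray:
    return np.repeat(tau, sizes)


def fit_lmm(
    X,
    y,
    random: list[RandomEffect],
    method: str = "reml",
    tol: float = 1e-8,
) -> LMMFit:
    """Fit a Gaussian mixed model by profiled REML (or ML).

    The covariance is sigma2 * (I + sum_k tau_k Z_k Z_k'); the ratios
    tau_k are optimised numerically (bounded at zero) and sigma2 is
    profiled out analytically. Starting values put an equal share of the
    OLS residual variance in every component. Deterministic given data.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        terms = [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"n={n} observations for p={p} fixed-effect columns")

    K = len(random)
    sizes = [re.n_levels for re in random]
    if K:
        Z = sp.hstack([re.Z for re in random], format="csr")
        ZtZ = (Z.T @ Z).toarray()
        ZtX = Z.T @ Xm
        Zty = Z.T @ y
    XtX = Xm.T @ Xm
    Xty = Xm.T @ y
    yty = float(y @ y)

    df = n - p if method == "reml" else n

    def _profile(tau: np.ndarray):
        """Return (-2 log lik, beta, XtVinvX, sigma2) at variance ratios tau."""
        if K:
            d = _expand(np.maximum(tau, 0.0), sizes)
            s = np.sqrt(d)
            W = s[:, None] * ZtZ * s[None, :]
            W[np.diag_indices_from(W)] += 1.0
            cf = sla.cho_factor(W, lower=True)
            logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
            sZtX = s[:, None] * ZtX
            sZty = s * Zty
            A = sla.cho_solve(cf, sZtX)
            a = sla.cho_solve(cf, sZty)
            XtVinvX = XtX - sZtX.T @ A
            XtVinvy = Xty - sZtX.T @ a
            yVinvy = yty - sZty @ a
        else:
            logdetV = 0.0
            XtVinvX, XtVinvy, yVinvy = XtX, Xty, yty
        cfx = sla.cho_factor(XtVinvX)
        beta = sla.cho_solve(cfx, XtVinvy)
        quad = max(yVinvy - beta @ XtVinvy, 1e-300)
        sigma2 = quad / df
        neg2 = df * np.log(sigma2) + logdetV + df * (1.0 + np.log(2.0 * np.pi))
        if method == "reml":
            neg2 += 2.0 * np.log(np.diag(cfx[0])).sum()
        return neg2, beta, XtVinvX, sigma2

    # OLS start: every component gets an equal share of the OLS residual var
    beta0 = sla.lstsq(Xm, y)[0]
    n_iter = 0
    message = "OLS (no random effects)"
    converged = True
    if K:
        # a random effect with a single level is confounded with the fixed
        # intercept (flat REML ridge): pin it to the boundary
        bounds = [(0.0, 1e7) if re.n_levels > 1 else (0.0, 0.0) for re in random]
        x0 = np.array([1.0 if b[1] > 0 else 0.0 for b in bounds])
        res = sopt.minimize(
            lambda t: _profile(t)[0],
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if not res.success:
            res2 = sopt.minimize(
                lambda t: _profile(t)[0],
                res.x,
                method="Powell",
                bounds=bounds,
                options={"ftol": tol, "maxiter": 2000},
            )
            if res2.fun <= res.fun:
                res = res2
        if not res.success and not np.isfinite(res.fun):
            raise LMMConvergenceError(
                f"optimiser failed: {res.message}; trace: nit={res.nit}, "
                f"x={res.x}, fun={res.fun}"
            )
        tau = np.maximum(res.x, 0.0)
        n_iter = int(getattr(res, "nit", 0))
        message = str(res.message)
        converged = bool(res.success)
    else:
        tau = np.zeros(0)

    neg2, beta, XtVinvX, sigma2 = _profile(tau)
    cov_beta = sigma2 * np.linalg.inv(XtVinvX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * norm.sf(np.abs(tvals))
    varcomp = {re.name: float(t * sigma2) for re, t in zip(random, tau)}
    singular = bool(K and np.any(tau < SINGULAR_TOL))
    return LMMFit(
        terms=terms,
        beta=beta,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        cov_beta=cov_beta,
        varcomp=varcomp,
        sigma2_resid=float(sigma2),
        loglik=-0.5 * neg2,
        method=method,
        n=n,
        p=p,
        singular=singular,
        converged=converged,
        n_iter=n_iter,
        var_fixed=float(np.var(Xm @ beta)),
        message=message,
    )


def wald_tests(fit: LMMFit) -> pd.DataFrame:
    """Per-term Wald tests: t = estimate / SE, two-sided p from the
    standard normal reference."""
    return fit.summary()


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """(marginal, conditional) R-squared.

    Marginal: variance of the fixed-effects predictor over the total
    (fixed + all random components + residual); conditional adds the
    random components to the numerator.
    """
    var_rand = sum(fit.varcomp.values())
    total = fit.var_fixed + var_rand + fit.sigma2_resid
    return fit.var_fixed / total, (fit.var_fixed + var_rand) / total


def lrt(fit_null: LMMFit, fit_alt: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (statistic, df, p)."""
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    dof = fit_alt.p - fit_null.p
    return stat, dof, float(chi2.sf(stat, dof)) if dof > 0 else 1.0


# ---------------------------------------------------------------------------
# type-I error calibration
# ---------------------------------------------------------------------------

def type1_simulation(
    n_reps: int,
    alpha: float = 0.05,
    cfg=None,
    seed: int = 0,
    min_years: int = 6,
) -> pd.DataFrame:
    """Empirical type-I error of the three-way pairwise mixed model.

    For each replicate a null panel (identity correlation, no trends) is
    simulated on a fresh riverscape, pairwise synchrony computed and the
    full three-way model fitted; per term the proportion of p-values
    below ``alpha`` is reported with its binomial Monte Carlo standard
    error. Replicates whose fit fails are dropped and counted.
    """
    from .simulate import SimConfig, null_pairwise_dataset
    from .synchrony import synchrony_table, truncate_between_fragment_pairs

    if cfg is None:
        cfg = SimConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    pvals: dict[str, list[float]] = {}
    n_failed = 0
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rep_cfg = dc_replace(cfg, seed=rep_seed)
        _, pairs, density = null_pairwise_dataset(rep_cfg)
        records, _ = synchrony_table(density, pairs, min_years=min_years)
        if records.empty:
            n_failed += 1
            continue
        records = truncate_between_fragment_pairs(records)
        records = prepare_records(records)
        try:
            Xd, rand = build_design(records, threeway_terms())
            fit = fit_lmm(Xd, records["rho"].to_numpy(), rand)
        except (LMMConvergenceError, DesignError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for term, pv in zip(fit.terms, fit.pvalues):
            pvals.setdefault(term, []).append(float(pv))

    rows = []
    for term, ps in pvals.items():
        ps = np.asarray(ps)
        prop = float((ps < alpha).mean())
        mc_se = float(np.sqrt(alpha * (1 - alpha) / len(ps)))
        rows.append(
            {"term": term, "rejection_rate": prop, "mc_se": mc_se,
             "n_reps": len(ps), "n_failed": n_failed,
             "is_intercept": term == "(intercept)"}
        )
    return pd.DataFrame(rows)
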