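import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from riversync.lmm import (
    DesignError,
    build_design,
    catchment_intercept,
    fit_lmm,
    lrt,
    multimembership_sites,
    prepare_records,
    r2_nakagawa,
    threeway_terms,
    wald_tests,
)

from _oracles import dense_neg2_reml


def _pairwise_frame(n, n_sites=8, n_catchments=3, seed=0, beta_x=0.3,
                    site_sd=0.4, catch_sd=0.3, resid_sd=0.4):
    rng = np.random.default_rng(seed)
    sites = [f"s{i}" for i in range(n_sites)]
    site_eff = dict(zip(sites, rng.normal(0, site_sd, n_sites)))
    catchments = [f"C{i}" for i in range(n_catchments)]
    catch_eff = dict(zip(catchments, rng.normal(0, catch_sd, n_catchments)))
    ab = [tuple(rng.choice(n_sites, 2, replace=False)) for _ in range(n)]
    df = pd.DataFrame(
        {
            "site_a": [sites[i] for i, _ in ab],
            "site_b": [sites[j] for _, j in ab],
            "catchment": rng.choice(catchments, n),
            "x": rng.normal(size=n),
        }
    )
    df["y"] = (
        0.5 + beta_x * df["x"]
        + df["site_a"].map(site_eff) + df["site_b"].map(site_eff)
        + df["catchment"].map(catch_eff) + rng.normal(0, resid_sd, n)
    )
    return df


class TestBuildDesign:
    def _records(self):
        return pd.DataFrame(
            {
                "site_a": ["A", "A", "B"],
                "site_b": ["B", "C", "C"],
                "catchment": ["C0", "C0", "C0"],
                "d_w_m": [0.0, 4000.0, 9000.0],
                "flow_connected": [True, False, True],
                "barrier_crossed": [False, True, True],
            }
        )

    def test_multimembership_incidence(self):
        rec = self._records()
        re_site = multimembership_sites(rec)
        Z = re_site.Z.toarray()
        assert Z.shape == (3, 3)
        assert (Z.sum(axis=1) == 2).all()
        assert (np.sort(Z, axis=1)[:, -2:] == 1).all()

    def test_multimembership_weight_configurable(self):
        Z = multimembership_sites(self._records(), weight=0.5).Z.toarray()
        assert (Z.sum(axis=1) == 1.0).all()

    def test_sqrt_distance_zero_and_threeway_expansion(self):
        rng = np.random.default_rng(0)
        n = 24
        rec = prepare_records(pd.DataFrame(
            {
                "site_a": [f"s{i}" for i in range(n)],
                "site_b": [f"t{i}" for i in range(n)],
                "catchment": rng.choice(["C0", "C1"], n),
                "d_w_m": np.r_[0.0, 4000.0, rng.uniform(0, 2e4, n - 2)],
                "flow_connected": rng.random(n) < 0.5,
                "barrier_crossed": rng.random(n) < 0.5,
            }
        ))
        X, rand = build_design(rec, threeway_terms())
        assert X.shape[1] == 8  # 1, d, f, g, df, dg, fg, dfg
        assert X.loc[0, "sqrt_dw_km"] == 0.0
        assert X.loc[1, "sqrt_dw_km"] == pytest.approx(2.0)
        assert [r.name for r in rand] == ["catchment", "site"]

    def test_rank_deficiency_names_columns(self):
        rec = prepare_records(self._records())
        rec["dup"] = rec["sqrt_dw_km"]
        with pytest.raises(DesignError, match="dup|sqrt_dw_km"):
            build_design(rec, ["sqrt_dw_km", "dup"])


class TestFitLMM:
    def test_no_random_effects_equals_ols(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"(intercept)": np.ones(40), "x": rng.normal(size=40)})
        y = 1.0 + 2.0 * X["x"].to_numpy() + rng.normal(0, 0.5, 40)
        fit = fit_lmm(X, y, random=[])
        want = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, want, atol=1e-10)

    def test_duplication_invariance_in_ols_limit(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"(intercept)": np.ones(30), "x": rng.normal(size=30)})
        y = rng.normal(size=30)
        f1 = fit_lmm(X, y, random=[])
        f2 = fit_lmm(pd.concat([X, X], ignore_index=True), np.r_[y, y], random=[])
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-12)

    def test_matches_lme4_reml(self, tmp_path):
        """Independent oracle: R lme4 on the same single-random-intercept
        data must agree on coefficients, SEs, variance components and the
        REML log-likelihood."""
        rng = np.random.default_rng(42)
        n = 80
        df = pd.DataFrame({"g": rng.choice(list("abcde"), n),
                           "x": rng.normal(size=n)})
        geff = dict(zip("abcde", rng.normal(0, 0.5, 5)))
        df["y"] = 1.0 + 0.4 * df["x"] + df["g"].map(geff) + rng.normal(0, 0.3, n)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        X = pd.DataFrame({"(intercept)": np.ones(n), "x": df["x"]})
        fit = fit_lmm(X, df["y"].to_numpy(), [catchment_intercept(df, column="g")])

        rcode = (
            f'library(lme4); d <- read.csv("{csv}"); '
            "m <- lmer(y ~ x + (1|g), data=d, REML=TRUE); "
            'cat(fixef(m), sqrt(diag(as.matrix(vcov(m)))), '
            "as.data.frame(VarCorr(m))$vcov, logLik(m))"
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        vals = np.array(out.stdout.split(), dtype=float)
        np.testing.assert_allclose(fit.beta, vals[0:2], rtol=1e-4)
        np.testing.assert_allclose(fit.se, vals[2:4], rtol=1e-4)
        np.testing.assert_allclose(
            [fit.varcomp["g"], fit.sigma2_resid], vals[4:6], rtol=1e-3
        )
        assert fit.loglik == pytest.approx(vals[6], abs=1e-3)

    def test_reml_dominates_grid_oracle_tiny_dataset(self):
        """n = 12, 4 sites, 2 catchments: the fitted criterion must beat a
        refined dense-matrix grid search over variance components."""
        df = _pairwise_frame(12, n_sites=4, n_catchments=2, seed=7)
        X = pd.DataFrame({"(intercept)": np.ones(12), "x": df["x"]})
        rand = [catchment_intercept(df), multimembership_sites(df)]
        fit = fit_lmm(X, df["y"].to_numpy(), rand)
        Zb = [r.Z for r in rand]
        y = df["y"].to_numpy()
        s2_ols = np.var(y - X.to_numpy() @ np.linalg.lstsq(
            X.to_numpy(), y, rcond=None)[0], ddof=2)

        def grid_best(center, width, k=8):
            best = np.inf
            arg = None
            for sc in np.geomspace(center[0] / width, center[0] * width, k):
                for ss in np.geomspace(center[1] / width, center[1] * width, k):
                    for se in np.geomspace(center[2] / width, center[2] * width, k):
                        v = dense_neg2_reml(X, y, Zb, [sc, ss], se)
                        if v < best:
                            best, arg = v, (sc, ss, se)
            return best, arg

        best, arg = grid_best([s2_ols / 3] * 3, 50.0)
        for _ in range(4):  # nested refinement around the incumbent
            best, arg = grid_best(arg, 2.0)
        assert -2.0 * fit.loglik <= best + 1e-4

    def test_convergence_metadata(self):
        df = _pairwise_frame(100, seed=3)
        X = pd.DataFrame({"(intercept)": np.ones(100), "x": df["x"]})
        fit = fit_lmm(X, df["y"].to_numpy(),
                      [catchment_intercept(df), multimembership_sites(df)])
        assert fit.converged
        assert all(v >= 0 for v in fit.varcomp.values())
        assert fit.sigma2_resid > 0

    def test_boundary_variance_flagged_singular(self):
        rng = np.random.default_rng(9)
        # group-centred response: the between-catchment variance estimate is
        # forced onto the boundary at zero
        df = pd.DataFrame({"catchment": rng.choice(["C0", "C1"], 200)})
        y = rng.normal(size=200)
        df["y"] = y - pd.Series(y).groupby(df["catchment"]).transform("mean")
        X = pd.DataFrame({"(intercept)": np.ones(200)})
        fit = fit_lmm(X, df["y"].to_numpy(), [catchment_intercept(df)])
        assert fit.singular
        assert fit.varcomp["catchment"] == pytest.approx(0.0, abs=1e-8)


class TestWaldAndR2:
    def test_wald_trivials(self):
        df = _pairwise_frame(300, seed=11, beta_x=0.0)
        X = pd.DataFrame({"(intercept)": np.ones(300), "x": df["x"]})
        fit = fit_lmm(X, df["y"].to_numpy(),
                      [catchment_intercept(df), multimembership_sites(df)])
        tab = wald_tests(fit)
        # p follows the normal reference: |t| = 1.96 -> p ~ 0.05
        from scipy.stats import norm
        assert 2 * norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)
        np.testing.assert_allclose(
            tab["t_value"], tab["estimate"] / tab["std_error"], rtol=1e-12
        )

    def test_r2_arithmetic_oracle(self):
        df = _pairwise_frame(400, seed=13)
        X = pd.DataFrame({"(intercept)": np.ones(400), "x": df["x"]})
        fit = fit_lmm(X, df["y"].to_numpy(),
                      [catchment_intercept(df), multimembership_sites(df)])
        marg, cond = r2_nakagawa(fit)
        vf = np.var(X.to_numpy() @ fit.beta)
        vr = sum(fit.varcomp.values())
        tot = vf + vr + fit.sigma2_resid
        assert marg == pytest.approx(vf / tot)
        assert cond == pytest.approx((vf + vr) / tot)
        assert cond >= marg

    def test_intercept_only_marginal_zero(self):
        df = _pairwise_frame(200, seed=15)
        X = pd.DataFrame({"(intercept)": np.ones(200)})
        fit = fit_lmm(X, df["y"].to_numpy(), [catchment_intercept(df)])
        marg, _ = r2_nakagawa(fit)
        assert marg == pytest.approx(0.0, abs=1e-12)

    def test_multimembership_improves_loglik_when_sites_heterogeneous(self):
        df = _pairwise_frame(500, seed=17, site_sd=0.6)
        X = pd.DataFrame({"(intercept)": np.ones(500), "x": df["x"]})
        with_mm = fit_lmm(X, df["y"].to_numpy(),
                          [catchment_intercept(df), multimembership_sites(df)],
                          method="ml")
        without = fit_lmm(X, df["y"].to_numpy(), [catchment_intercept(df)],
                          method="ml")
        assert with_mm.loglik > without.loglik

    def test_lrt_nesting(self):
        df = _pairwise_frame(300, seed=19)
        X0 = pd.DataFrame({"(intercept)": np.ones(300)})
        X1 = pd.DataFrame({"(intercept)": np.ones(300), "x": df["x"]})
        rand = [catchment_intercept(df), multimembership_sites(df)]
        f0 = fit_lmm(X0, df["y"].to_numpy(), rand, method="ml")
        f1 = fit_lmm(X1, df["y"].to_numpy(), rand, method="ml")
        stat, dof, p = lrt(f0, f1)
        assert f1.loglik >= f0.loglik
        assert dof == 1
        assert 0 <= p <= 1
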