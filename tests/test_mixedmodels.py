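import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from symbiospec.mixedmodels import (
    MixedModelFit,
    ModelSpec,
    build_design,
    fit_gaussian_lmm,
    fit_poisson_glmm,
    morans_i,
    pairwise_guild_tests,
    r2_nakagawa,
    standardize,
    vif,
    wald_type3,
)


def simulate_lmm(
    seed, n_species=12, n_forests=10, sd_species=0.2, sd_forest=0.0,
    sd_resid=0.14, beta_env=0.1, beta_guild=0.15, intercept=0.5,
):
    """Crossed-design Gaussian data with known coefficients (response on the
    transformed scale, so transformation='none' via direct column)."""
    rng = np.random.default_rng(seed)
    rows = []
    u_sp = rng.normal(0, sd_species, n_species)
    u_fo = rng.normal(0, sd_forest, n_forests)
    guilds = ["cyanolichen" if i % 2 else "cephalolichen" for i in range(n_species)]
    env = rng.normal(0, 1, n_forests)
    for i in range(n_species):
        for f in range(n_forests):
            mu = (
                intercept
                + beta_env * env[f]
                + beta_guild * (guilds[i] == "cyanolichen")
                + u_sp[i]
                + u_fo[f]
            )
            rows.append(
                {
                    "species": f"sp{i:02d}",
                    "forest": f"F{f:02d}",
                    "guild": guilds[i],
                    "env": env[f],
                    "y": mu + rng.normal(0, sd_resid),
                }
            )
    return pd.DataFrame(rows)


def spec_for_sim(response="y"):
    return ModelSpec(
        response=response,
        family="gaussian",
        transformation="none",
        fixed_numeric=("env",),
        fixed_categorical=("guild",),
    )


class TestStandardize:
    def test_exact_on_three_points(self):
        z = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))["x"]
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert z.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(3, 2, 50)})
        once = standardize(X)
        twice = standardize(once)
        assert np.allclose(once["x"], twice["x"])


class TestModelSpec:
    def test_family_pairing_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec("richness", "gaussian", "ln")
        spec = ModelSpec.for_response("simpson")
        assert (spec.family, spec.transformation) == ("gaussian", "ln")


class TestGaussianLMM:
    def test_degenerate_matches_ols(self):
        """With no random variance, LMM estimates collapse to OLS."""
        df = simulate_lmm(1, sd_species=0.0, sd_forest=0.0, sd_resid=0.3)
        fit = fit_gaussian_lmm(spec_for_sim(), df)
        X, names, _ = build_design(df, ("env",), ("guild",))
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        assert np.linalg.norm(fit.params.to_numpy() - ols.params) < 1e-4
        # REML variance estimates stay near the zero boundary
        assert sum(fit.vc.values()) < 0.1 * fit.resid_var

    def test_balanced_one_way_closed_form(self):
        """Intercept-only model with one random factor matches the ANOVA
        REML estimator sigma2_a = (MSA - MSE)/n, sigma2_e = MSE."""
        rng = np.random.default_rng(2)
        n_groups, n_per = 15, 8
        u = rng.normal(0, 0.5, n_groups)
        rows = []
        for g in range(n_groups):
            for _ in range(n_per):
                rows.append({"species": f"g{g:02d}", "y": 1.0 + u[g] + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        spec = ModelSpec(
            "y", "gaussian", "none", fixed_numeric=(), fixed_categorical=(),
            random_groups=("species",),
        )
        fit = fit_gaussian_lmm(spec, df)
        gm = df.groupby("species")["y"].mean()
        grand = df["y"].mean()
        msa = n_per * ((gm - grand) ** 2).sum() / (n_groups - 1)
        mse = ((df["y"] - df["species"].map(gm)) ** 2).sum() / (
            len(df) - n_groups
        )
        assert fit.vc["species"] == pytest.approx((msa - mse) / n_per, rel=1e-3)
        assert fit.resid_var == pytest.approx(mse, rel=1e-3)

    def test_parameter_recovery(self):
        """Bias of each fixed effect < 10% of its value over replicates at the
        variance scale seen in real specialization data."""
        est_env, est_guild = [], []
        for seed in range(40):
            df = simulate_lmm(seed, sd_species=0.2, sd_forest=0.02, sd_resid=0.14)
            fit = fit_gaussian_lmm(spec_for_sim(), df)
            est_env.append(fit.params["env"])
            est_guild.append(fit.params["guild[cyanolichen]"])
        assert abs(np.mean(est_env) - 0.1) < 0.01
        assert abs(np.mean(est_guild) - 0.15) < 0.015


class TestPoissonGLMM:
    def _simulate(self, seed, n_species=15, n_forests=10, sd=0.3, beta_guild=0.3):
        rng = np.random.default_rng(seed)
        u_sp = rng.normal(0, sd, n_species)
        guilds = [
            "cyanolichen" if i % 2 else "cephalolichen" for i in range(n_species)
        ]
        rows = []
        for i in range(n_species):
            for f in range(n_forests):
                eta = 0.7 + beta_guild * (guilds[i] == "cyanolichen") + u_sp[i]
                rows.append(
                    {
                        "species": f"sp{i:02d}",
                        "forest": f"F{f:02d}",
                        "guild": guilds[i],
                        "richness": rng.poisson(np.exp(eta)),
                    }
                )
        return pd.DataFrame(rows)

    def _spec(self):
        return ModelSpec(
            "richness", "poisson", "none", fixed_numeric=(),
            fixed_categorical=("guild",),
        )

    def test_degenerate_matches_poisson_glm(self):
        df = self._simulate(3, sd=0.0)
        fit = fit_poisson_glmm(self._spec(), df)
        X, names, _ = build_design(df, (), ("guild",))
        glm = sm.GLM(df["richness"].to_numpy(), X, family=sm.families.Poisson()).fit()
        assert np.linalg.norm(fit.params.to_numpy() - glm.params) < 1e-3
        assert all(v < 1e-3 for v in fit.vc.values())

    def test_intercept_only_iid_variance_shrinks(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "richness": rng.poisson(3.0, 400),
                "species": [f"s{i % 20:02d}" for i in range(400)],
                "forest": [f"F{i % 10:02d}" for i in range(400)],
            }
        )
        spec = ModelSpec(
            "richness", "poisson", "none", fixed_numeric=(), fixed_categorical=()
        )
        fit = fit_poisson_glmm(spec, df)
        assert all(v < 0.02 for v in fit.vc.values())

    def test_parameter_recovery_within_2se(self):
        hits = 0
        reps = 30
        for seed in range(reps):
            df = self._simulate(seed, sd=0.3, beta_guild=0.3)
            fit = fit_poisson_glmm(self._spec(), df)
            b = fit.params["guild[cyanolichen]"]
            se = fit.bse["guild[cyanolichen]"]
            if abs(b - 0.3) <= 2 * se:
                hits += 1
        assert hits / reps >= 0.9


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_fits_match_lme4(tmp_path):
    """Independent oracle: lme4 lmer (REML) and glmer (Laplace) on the same
    crossed-design data."""
    df = simulate_lmm(7, sd_species=0.25, sd_forest=0.1, sd_resid=0.2)
    rng = np.random.default_rng(8)
    df["richness"] = rng.poisson(np.exp(0.5 + 0.3 * (df["guild"] == "cyanolichen")
                                        + 0.2 * rng.normal(size=len(df))))
    df.to_csv(tmp_path / "d.csv", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
        d <- read.csv("d.csv")
        d$env_s <- as.numeric(scale(d$env))
        g <- lmer(y ~ env_s + guild + (1|forest) + (1|species), data = d, REML = TRUE)
        vc <- as.data.frame(VarCorr(g))
        p <- glmer(richness ~ guild + (1|forest) + (1|species), data = d,
                   family = poisson)
        vcp <- as.data.frame(VarCorr(p))
        cat(toJSON(list(
          beta = as.numeric(fixef(g)), beta_p = as.numeric(fixef(p)),
          vc = vc$vcov, vcp = vcp$vcov), digits = 12))
        """
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)],
        cwd=tmp_path, capture_output=True, text=True, check=True,
    )
    ref = json.loads(out.stdout)

    fit_g = fit_gaussian_lmm(spec_for_sim(), df)
    # lme4 order: (Intercept), env_s, guildcyanolichen
    assert fit_g.params["Intercept"] == pytest.approx(ref["beta"][0], abs=2e-3)
    assert fit_g.params["env"] == pytest.approx(ref["beta"][1], abs=2e-3)
    assert fit_g.params["guild[cyanolichen]"] == pytest.approx(
        ref["beta"][2], abs=2e-3
    )
    # VarCorr rows: species, forest, Residual
    vc_ref = {"species": ref["vc"][0], "forest": ref["vc"][1]}
    for g in ("species", "forest"):
        assert fit_g.vc[g] == pytest.approx(vc_ref[g], abs=5e-3)

    spec_p = ModelSpec(
        "richness", "poisson", "none", fixed_numeric=(),
        fixed_categorical=("guild",),
    )
    fit_p = fit_poisson_glmm(spec_p, df)
    assert fit_p.params["Intercept"] == pytest.approx(ref["beta_p"][0], abs=5e-3)
    assert fit_p.params["guild[cyanolichen]"] == pytest.approx(
        ref["beta_p"][1], abs=5e-3
    )
    vcp_ref = {"species": ref["vcp"][0], "forest": ref["vcp"][1]}
    for g in ("species", "forest"):
        assert fit_p.vc[g] == pytest.approx(vcp_ref[g], abs=0.01)


def _manual_fit(params, cov, terms, vc=None, resid=1.0, X=None, family="gaussian"):
    names = list(params)
    values = np.array(list(params.values()))
    n = X.shape[0] if X is not None else 10
    return MixedModelFit(
        params=pd.Series(values, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_fixed=cov,
        term_indices=terms,
        vc=vc or {},
        resid_var=resid,
        family=family,
        converged=True,
        n=n,
        X=X if X is not None else np.ones((n, len(names))),
        residuals=np.zeros(n),
    )


class TestWaldType3:
    def test_single_df_term_is_z_squared(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        fit = _manual_fit(
            {"Intercept": 1.0, "x": 0.4},
            np.diag([0.04, 0.01]),
            {"x": [1]},
            X=X,
        )
        table = wald_type3(fit)
        assert table.loc[table["term"] == "x", "chi2"].iloc[0] == pytest.approx(
            (0.4 / 0.1) ** 2
        )

    def test_null_calibration(self):
        """Type-I error of the Wald chi2 near 0.05 under the OLS null."""
        rng = np.random.default_rng(9)
        n, reps = 60, 1000
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            ols = sm.OLS(y, X).fit()
            fit = _manual_fit(
                {"Intercept": ols.params[0], "x": ols.params[1]},
                ols.cov_params(),
                {"x": [1]},
                X=X,
            )
            p = wald_type3(fit)["p_value"].iloc[0]
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_reference_level_invariance_balanced(self):
        """Balanced 3-level factor: the term chi2 does not depend on which
        level is the reference."""
        rng = np.random.default_rng(10)
        df = simulate_lmm(11)
        df["mode"] = np.tile(["asexual", "both", "sexual"], len(df) // 3 + 1)[: len(df)]
        spec = ModelSpec(
            "y", "gaussian", "none", fixed_numeric=("env",),
            fixed_categorical=("mode",),
        )
        fit1 = fit_gaussian_lmm(spec, df)
        chi1 = wald_type3(fit1).set_index("term").loc["mode", "chi2"]
        relabel = {"asexual": "z_asexual", "both": "both", "sexual": "sexual"}
        df2 = df.assign(mode=df["mode"].map(relabel))
        fit2 = fit_gaussian_lmm(spec, df2)
        chi2_ = wald_type3(fit2).set_index("term").loc["mode", "chi2"]
        assert chi1 == pytest.approx(chi2_, rel=1e-4)


class TestR2Nakagawa:
    def test_no_random_variance_equalizes(self):
        X = np.column_stack([np.ones(8), np.linspace(-1, 1, 8)])
        fit = _manual_fit(
            {"Intercept": 0.0, "x": 1.0}, np.eye(2), {"x": [1]},
            vc={"species": 0.0, "forest": 0.0}, resid=0.5, X=X,
        )
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(r2c)
        # and on data simulated without random effects the gap stays small
        df = simulate_lmm(12, sd_species=0.0, sd_forest=0.0)
        real = fit_gaussian_lmm(spec_for_sim(), df)
        r2m, r2c = r2_nakagawa(real)
        assert r2c - r2m < 0.05

    def test_hand_computation(self):
        X = np.column_stack([np.ones(6), np.array([-1.0, 0, 1, -1, 0, 1])])
        fit = _manual_fit(
            {"Intercept": 0.0, "x": 2.0},
            np.eye(2),
            {"x": [1]},
            vc={"species": 1.0},
            resid=3.0,
            X=X,
        )
        var_f = np.var(X @ np.array([0.0, 2.0]), ddof=1)
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(var_f / (var_f + 1.0 + 3.0))
        assert r2c == pytest.approx((var_f + 1.0) / (var_f + 1.0 + 3.0))

    def test_ordering_invariant(self):
        df = simulate_lmm(13, sd_species=0.3)
        fit = fit_gaussian_lmm(spec_for_sim(), df)
        r2m, r2c = r2_nakagawa(fit)
        assert 0 <= r2m <= r2c <= 1


class TestVIF:
    def test_orthogonal_columns(self):
        rng = np.random.default_rng(14)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        assert (vif(X) < 1.05).all()

    def test_near_duplicate_column(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.01, 100)})
        assert (vif(X) > 100).all()

    def test_matches_bruteforce_regression(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X["d"] += X["a"] * 0.8
        got = vif(X)
        for col in X.columns:
            others = sm.add_constant(X.drop(columns=[col]).to_numpy())
            r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
            assert got[col] == pytest.approx(1 / (1 - r2))


class TestMoransI:
    def _coords(self, rng, n=11):
        return np.column_stack(
            [rng.uniform(-55, -38, n), rng.uniform(-73, -71, n)]
        )

    def test_iid_residuals_centered_at_expectation(self):
        rng = np.random.default_rng(17)
        coords = self._coords(rng)
        stats_ = [
            morans_i(rng.normal(size=11), coords)["I"] for _ in range(1000)
        ]
        assert np.mean(stats_) == pytest.approx(-1 / 10, abs=0.02)

    def test_clustered_residuals_positive(self):
        rng = np.random.default_rng(18)
        lat = np.linspace(-55, -38, 12)
        coords = np.column_stack([lat, np.full(12, -72.0)])
        resid = np.where(lat > -46, 1.0, -1.0) + rng.normal(0, 0.05, 12)
        res = morans_i(resid, coords)
        assert res["I"] > 0
        assert res["p_value"] < 0.05

    def test_duplicate_coordinates_aggregated(self):
        rng = np.random.default_rng(19)
        coords = np.repeat(self._coords(rng, 6), 4, axis=0)
        resid = rng.normal(size=24)
        res = morans_i(resid, coords)
        assert res["n_locations"] == 6


def test_pairwise_guild_tests_single_contrast():
    df = simulate_lmm(20, beta_guild=0.5)
    fit = fit_gaussian_lmm(spec_for_sim(), df)
    table = pairwise_guild_tests(fit, "guild")
    assert len(table) == 1
    z = fit.params["guild[cyanolichen]"] / fit.bse["guild[cyanolichen]"]
    assert table["z"].iloc[0] == pytest.approx(z)
    assert table["p_holm"].iloc[0] == table["p_value"].iloc[0]
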