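import itertools
import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from symbiospec.drivers import (
    rda,
    richness_gradient_lm,
    screen_predictors,
    variation_partition,
)


class TestScreenPredictors:
    def test_orthogonal_all_retained(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        assert screen_predictors(X, 0.7) == list("abcd")

    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = X["a"] * 1.0
        X["c"] = rng.normal(size=20)
        kept = screen_predictors(X, 0.7)
        assert "c" in kept and len(kept) == 2

    def test_one_redundant_pair_matches_exhaustive(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        X["e"] = X["a"] + rng.normal(0, 0.1, 40)  # redundant with a
        kept = screen_predictors(X, 0.7)
        assert len(kept) == 4
        # exhaustive: the only pair above threshold is (a, e)
        corr = X.corr().abs()
        over = [
            (i, j)
            for i, j in itertools.combinations(X.columns, 2)
            if corr.loc[i, j] > 0.7
        ]
        assert over == [("a", "e")]
        assert set(kept) == set("abcd") or set(kept) == {"b", "c", "d", "e"}


class TestRDA:
    def test_noiseless_linear_response(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(12, 3)))
        Y = pd.DataFrame(X.values @ rng.normal(size=(3, 6)))
        assert rda(Y, X).proportion_constrained == pytest.approx(1.0)

    def test_pure_noise_predictors_explain_little(self):
        """E[R^2] under the null is ~p/(n-1); stays below 0.2 at n=50, p=2."""
        rng = np.random.default_rng(4)
        props = []
        for _ in range(500):
            Y = rng.normal(size=(50, 5))
            X = rng.normal(size=(50, 2))
            props.append(rda(Y, X).proportion_constrained)
        assert np.mean(props) == pytest.approx(2 / 49, abs=0.01)
        assert np.quantile(props, 0.99) < 0.2

    def test_single_predictor_closed_form(self):
        """Proportion equals variance-weighted mean of per-column R^2."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=4)})
        Y = pd.DataFrame(rng.normal(size=(4, 3)))
        res = rda(Y, X)
        Yc = Y.values - Y.values.mean(0)
        xc = X["x"].to_numpy() - X["x"].mean()
        r2 = []
        var = []
        for j in range(3):
            b = xc @ Yc[:, j] / (xc @ xc)
            ss_fit = np.sum((b * xc) ** 2)
            ss_tot = np.sum(Yc[:, j] ** 2)
            r2.append(ss_fit / ss_tot)
            var.append(ss_tot)
        expected = np.average(r2, weights=var)
        assert res.proportion_constrained == pytest.approx(expected)

    def test_invariances(self):
        rng = np.random.default_rng(6)
        Y = pd.DataFrame(rng.poisson(4, size=(10, 6)).astype(float))
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        base = rda(Y, X).proportion_constrained
        perm = rda(Y[np.random.default_rng(0).permutation(Y.columns)], X)
        assert perm.proportion_constrained == pytest.approx(base)
        scaled = rda(Y * 3.7, X)
        assert scaled.proportion_constrained == pytest.approx(base)

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(size=8)})
        X["b"] = 2 * X["a"]
        Y = pd.DataFrame(rng.normal(size=(8, 3)))
        with pytest.raises(ValueError, match="rank"):
            rda(Y, X)


class TestVariationPartition:
    def _toy(self, seed=8, n=20):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        Y = pd.DataFrame(
            X.values @ rng.normal(size=(3, 4)) + rng.normal(size=(n, 4))
        )
        return Y, X

    def test_moebius_reconstruction_identity(self):
        """Exclusive fractions rebuild every subset adjusted R^2 exactly."""
        Y, X = self._toy()
        vp = variation_partition(Y, X, {g: [g] for g in "abc"})
        ex = vp["exclusive_fractions"]
        for k in range(1, 4):
            for combo in itertools.combinations("abc", k):
                rebuilt = sum(
                    v for key, v in ex.items()
                    if set(key.split("+")) & set(combo)
                )
                direct = vp["subset_adj_r2"]["+".join(sorted(combo))]
                assert rebuilt == pytest.approx(direct, abs=1e-10)

    def test_fractions_sum_to_total(self):
        Y, X = self._toy(9)
        vp = variation_partition(Y, X, {g: [g] for g in "abc"})
        assert sum(vp["exclusive_fractions"].values()) == pytest.approx(
            vp["total_adj_r2"], abs=1e-10
        )
        assert sum(vp["unique_plus_shared"].values()) == pytest.approx(
            vp["total_adj_r2"], abs=1e-10
        )

    def test_orthogonal_predictors_share_nothing(self):
        rng = np.random.default_rng(10)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        Y = pd.DataFrame(
            np.outer(X["a"], [1, 0.5]) + np.outer(X["b"], [0.5, 1])
            + 0.3 * rng.normal(size=(n, 2))
        )
        vp = variation_partition(Y, X, {"a": ["a"], "b": ["b"]})
        shared = vp["exclusive_fractions"]["a+b"]
        assert abs(shared) < 0.02
        assert vp["unique"]["a"] > 0.1 and vp["unique"]["b"] > 0.1

    def test_identical_predictors_all_shared(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(0, 1e-6, 30)})
        Y = pd.DataFrame(np.outer(a, [1.0, 2.0]) + 0.2 * rng.normal(size=(30, 2)))
        vp = variation_partition(Y, X, {"a": ["a"], "b": ["b"]})
        assert abs(vp["unique"]["a"]) < 0.01
        assert abs(vp["unique"]["b"]) < 0.01
        assert vp["exclusive_fractions"]["a+b"] > 0.5


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_rda_and_varpart_match_vegan(tmp_path):
    """Independent oracle: vegan's rda() and varpart() on the same data."""
    rng = np.random.default_rng(12)
    Y = pd.DataFrame(rng.poisson(5, size=(11, 8)).astype(float))
    X = pd.DataFrame(rng.normal(size=(11, 3)), columns=list("abc"))
    Y.to_csv(tmp_path / "Y.csv", index=False)
    X.to_csv(tmp_path / "X.csv", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages(library(vegan)); suppressMessages(library(jsonlite))
        Y <- read.csv("Y.csv"); X <- read.csv("X.csv")
        m <- rda(Y ~ ., data = X)
        v <- varpart(Y, ~a, ~b, ~c, data = X)
        fr <- v$part$indfract$Adj.R.square
        cat(toJSON(list(prop = m$CCA$tot.chi / m$tot.chi,
                        ua = fr[1], ub = fr[2], uc = fr[3]), digits = 12))
        """
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)],
        cwd=tmp_path, capture_output=True, text=True, check=True,
    )
    ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
    mine = rda(Y, X)
    vp = variation_partition(Y, X, {g: [g] for g in "abc"})
    assert mine.proportion_constrained == pytest.approx(ref["prop"], abs=1e-6)
    assert vp["unique"]["a"] == pytest.approx(ref["ua"], abs=1e-6)
    assert vp["unique"]["b"] == pytest.approx(ref["ub"], abs=1e-6)
    assert vp["unique"]["c"] == pytest.approx(ref["uc"], abs=1e-6)


class TestRichnessGradient:
    def test_flat_richness(self):
        res = richness_gradient_lm([5, 5, 5, 5], [-39, -45, -50, -55])
        assert res["slope"] == pytest.approx(0.0)

    def test_exact_line(self):
        lat = np.array([-39.0, -43.0, -47.0, -51.0, -55.0])
        res = richness_gradient_lm(2 * lat + 100, lat)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 2.0, 4.0, 3.5])
        res = richness_gradient_lm(y, x)
        slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        intercept = y.mean() - slope * x.mean()
        assert res["slope"] == pytest.approx(slope)
        assert res["intercept"] == pytest.approx(intercept)
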