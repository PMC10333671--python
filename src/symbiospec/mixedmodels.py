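"""Driver models for the specialization metrics.

Each specialization response (partner richness, Simpson's index, d') is
modeled on environmental and biological fixed effects with two *crossed*
random intercepts — forest and mycobiont species — following the standard
GLMM formulation:

* richness: Poisson family, log link, untransformed counts;
* Simpson:  Gaussian on ln(D);
* d':       Gaussian on sqrt(d').

The Gaussian models are fit by REML (statsmodels MixedLM with the two
intercepts as variance components under a single trivial grouping).  The
Poisson model is fit by maximum likelihood with a Laplace approximation to
the marginal likelihood: for candidate variance components the joint
penalized log-likelihood is maximized over (beta, u) by Newton iteration and
the marginal log-likelihood corrected by the log-determinant of the
conditional precision; the two log-variances are then optimized by bounded
quasi-Newton from a fixed deterministic start, so fits are reproducible
without seeds.

Diagnostics mirror common practice: Wald type-III chi-square tests per fixed
term, Nakagawa marginal/conditional R^2, variance inflation factors, and
Moran's I on residuals aggregated per forest coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import VCSpec

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "standardize",
    "build_design",
    "fit_gaussian_lmm",
    "fit_poisson_glmm",
    "wald_type3",
    "r2_nakagawa",
    "vif",
    "morans_i",
]

RESPONSE_FAMILIES = {
    "richness": ("poisson", "none"),
    "simpson": ("gaussian", "ln"),
    "dprime": ("gaussian", "sqrt"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Response / family / transformation triple for one driver model."""

    response: str
    family: str
    transformation: str
    fixed_numeric: tuple[str, ...] = ("bio01", "bio06", "bio14", "dbh")
    fixed_categorical: tuple[str, ...] = ("repro_mode", "guild")
    random_groups: tuple[str, ...] = ("forest", "species")

    def __post_init__(self) -> None:
        expected = RESPONSE_FAMILIES.get(self.response)
        if expected is not None and (self.family, self.transformation) != expected:
            raise ValueError(
                f"response {self.response!r} requires family/transformation "
                f"{expected}, got ({self.family!r}, {self.transformation!r})"
            )

    @classmethod
    def for_response(cls, response: str, **kw) -> "ModelSpec":
        family, transformation = RESPONSE_FAMILIES[response]
        return cls(response, family, transformation, **kw)

    def transform(self, y: np.ndarray) -> np.ndarray:
        if self.transformation == "none":
            return np.asarray(y, dtype=float)
        if self.transformation == "ln":
            return np.log(np.asarray(y, dtype=float))
        if self.transformation == "sqrt":
            return np.sqrt(np.asarray(y, dtype=float))
        raise ValueError(f"unknown transformation {self.transformation!r}")


@dataclass
class MixedModelFit:
    params: pd.Series
    bse: pd.Series
    cov_fixed: np.ndarray
    term_indices: dict[str, list[int]]
    vc: dict[str, float]
    resid_var: float
    family: str
    converged: bool
    n: int
    X: np.ndarray
    residuals: np.ndarray
    loglike: float = float("nan")
    random_effects: dict[str, pd.Series] = field(default_factory=dict)


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Center each numeric column to mean 0 and scale to sd 1 (ddof=1)."""
    X = pd.DataFrame(X).astype(float)
    sd = X.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    return (X - X.mean()) / sd


def build_design(
    data: pd.DataFrame,
    numeric: tuple[str, ...],
    categorical: tuple[str, ...],
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Fixed-effects design matrix with intercept, standardized numerics and
    treatment-coded categoricals (reference = first level alphabetically).

    Returns (X, column names, term -> column-index map excluding intercept).
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    terms: dict[str, list[int]] = {}
    if numeric:
        Z = standardize(data[list(numeric)])
        for c in numeric:
            terms[c] = [len(names)]
            names.append(c)
            cols.append(Z[c].to_numpy())
    for c in categorical:
        levels = sorted(data[c].astype(str).unique())
        if len(levels) < 2:
            continue
        idxs = []
        for lev in levels[1:]:
            idxs.append(len(names))
            names.append(f"{c}[{lev}]")
            cols.append((data[c].astype(str) == lev).to_numpy(float))
        terms[c] = idxs
    return np.column_stack(cols), names, terms


def _random_design(data: pd.DataFrame, groups: tuple[str, ...]):
    """Indicator matrix Z for the crossed random intercepts and the map of
    each Z column to its variance component."""
    mats, comp, labels = [], [], []
    for gi, g in enumerate(groups):
        dum = pd.get_dummies(data[g].astype(str), dtype=float)
        dum = dum[sorted(dum.columns)]
        mats.append(dum.to_numpy())
        comp += [gi] * dum.shape[1]
        labels.append(list(dum.columns))
    return np.hstack(mats), np.asarray(comp), labels


def fit_gaussian_lmm(spec: ModelSpec, data: pd.DataFrame) -> MixedModelFit:
    """REML fit of the Gaussian mixed model with crossed random intercepts."""
    y = spec.transform(data[spec.response].to_numpy())
    if not np.all(np.isfinite(y)):
        raise ValueError("transformed response contains non-finite values")
    X, names, terms = build_design(data, spec.fixed_numeric, spec.fixed_categorical)
    n = len(y)
    vc_names = list(spec.random_groups)
    dums = []
    colnames = []
    for g in vc_names:
        dum = pd.get_dummies(data[g].astype(str), dtype=float)
        dum = dum[sorted(dum.columns)]
        dums.append([dum.to_numpy()])
        colnames.append([list(dum.columns)])
    vcs = VCSpec(names=vc_names, colnames=colnames, mats=dums)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=np.zeros(n), exog_vc=vcs)
        res = model.fit(reml=True)
        if not res.converged:
            # variance components at the zero boundary often trip the
            # default optimizer; retry with alternatives
            for method in ("lbfgs", "cg", "powell"):
                res = model.fit(reml=True, method=method)
                if res.converged:
                    break
    k = X.shape[1]
    cov = np.asarray(res.cov_params())[:k, :k]
    vc = {g: float(v) for g, v in zip(vc_names, res.vcomp)}
    fit = MixedModelFit(
        params=pd.Series(res.fe_params, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_fixed=cov,
        term_indices=terms,
        vc=vc,
        resid_var=float(res.scale),
        family="gaussian",
        converged=bool(res.converged),
        n=n,
        X=X,
        residuals=np.asarray(res.resid),
        loglike=float(res.llf),
    )
    if not fit.converged:
        warnings.warn("Gaussian LMM did not converge; estimates are flagged")
    return fit


def _laplace_inner(y, X, Z, dinv, beta, u, max_iter=100, tol=1e-9):
    """Newton maximization of the joint penalized Poisson log-likelihood."""
    p, q = X.shape[1], Z.shape[1]
    for _ in range(max_iter):
        eta = X @ beta + Z @ u
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        g = np.concatenate([X.T @ (y - mu), Z.T @ (y - mu) - dinv * u])
        if np.max(np.abs(g)) < tol:
            break
        W = mu
        H = np.empty((p + q, p + q))
        XW = X * W[:, None]
        H[:p, :p] = X.T @ XW
        H[:p, p:] = XW.T @ Z
        H[p:, :p] = H[:p, p:].T
        H[p:, p:] = (Z * W[:, None]).T @ Z + np.diag(dinv)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving on the penalized objective
        def obj(b_, u_):
            e = np.clip(X @ b_ + Z @ u_, -30, 30)
            return float(y @ e - np.exp(e).sum() - 0.5 * np.sum(dinv * u_**2))
        base = obj(beta, u)
        scale_ = 1.0
        for _ in range(30):
            nb, nu = beta + scale_ * step[:p], u + scale_ * step[p:]
            if obj(nb, nu) >= base - 1e-12:
                break
            scale_ *= 0.5
        beta, u = beta + scale_ * step[:p], u + scale_ * step[p:]
    return beta, u


def _laplace_loglike(theta, y, X, Z, comp, state):
    """Negative Laplace marginal log-likelihood at log-variances theta."""
    v = np.exp(theta)
    dinv = 1.0 / v[comp]
    beta, u = _laplace_inner(y, X, Z, dinv, state["beta"], state["u"])
    state["beta"], state["u"] = beta, u
    eta = np.clip(X @ beta + Z @ u, -30, 30)
    mu = np.exp(eta)
    W = mu
    Huu = (Z * W[:, None]).T @ Z + np.diag(dinv)
    sign, logdet = np.linalg.slogdet(Huu)
    ll = (
        float(y @ eta - mu.sum() - gammaln(y + 1).sum())
        - 0.5 * float(np.sum(dinv * u**2))
        - 0.5 * float(np.sum(np.log(v[comp])))
        - 0.5 * logdet
    )
    return -ll


def fit_poisson_glmm(spec: ModelSpec, data: pd.DataFrame) -> MixedModelFit:
    """Laplace-approximation ML fit of the Poisson mixed model."""
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("Poisson response must be nonnegative counts")
    X, names, terms = build_design(data, spec.fixed_numeric, spec.fixed_categorical)
    Z, comp, labels = _random_design(data, spec.random_groups)
    n, p, q = len(y), X.shape[1], Z.shape[1]
    state = {"beta": np.zeros(p), "u": np.zeros(q)}
    state["beta"][0] = np.log(max(y.mean(), 1e-3))
    x0 = np.full(len(spec.random_groups), np.log(0.1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(
            _laplace_loglike,
            x0,
            args=(y, X, Z, comp, state),
            method="L-BFGS-B",
            bounds=[(-12.0, 5.0)] * len(x0),
            options={"maxiter": 200, "ftol": 1e-10},
        )
    v = np.exp(opt.x)
    dinv = 1.0 / v[comp]
    beta, u = _laplace_inner(y, X, Z, dinv, state["beta"], state["u"])
    eta = np.clip(X @ beta + Z @ u, -30, 30)
    mu = np.exp(eta)
    W = mu
    XW = X * W[:, None]
    Hbb = X.T @ XW
    Hbu = XW.T @ Z
    Huu = (Z * W[:, None]).T @ Z + np.diag(dinv)
    schur = Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T)
    cov = np.linalg.inv(schur)
    vc = {g: float(val) for g, val in zip(spec.random_groups, v)}
    ranef = {
        g: pd.Series(
            u[np.asarray(comp) == gi], index=labels[gi]
        )
        for gi, g in enumerate(spec.random_groups)
    }
    fit = MixedModelFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_fixed=cov,
        term_indices=terms,
        vc=vc,
        resid_var=float("nan"),
        family="poisson",
        converged=bool(opt.success),
        n=n,
        X=X,
        residuals=y - mu,
        loglike=-float(opt.fun),
        random_effects=ranef,
    )
    if not fit.converged:
        warnings.warn("Poisson GLMM optimizer did not report convergence")
    return fit


def wald_type3(fit: MixedModelFit) -> pd.DataFrame:
    """Wald chi-square test per fixed-effect term, other terms retained."""
    rows = []
    for term, idxs in fit.term_indices.items():
        b = fit.params.iloc[idxs].to_numpy()
        V = fit.cov_fixed[np.ix_(idxs, idxs)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idxs)
        rows.append(
            {
                "term": term,
                "chi2": chi2,
                "df": df,
                "p_value": float(stats.chi2.sf(chi2, df)),
            }
        )
    return pd.DataFrame(rows)


def r2_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for a mixed model.

    R^2_m = var_fixed / (var_fixed + var_random + var_resid); R^2_c adds the
    random-intercept variances to the numerator.  For the Poisson log link
    the residual variance uses the lognormal approximation ln(1 + 1/lambda)
    with lambda evaluated at the mean fixed linear predictor plus half the
    total random variance.
    """
    lin = fit.X @ fit.params.to_numpy()
    var_f = float(np.var(lin, ddof=1))
    var_r = float(sum(fit.vc.values()))
    if fit.family == "gaussian":
        var_e = fit.resid_var
    elif fit.family == "poisson":
        lam = float(np.exp(np.mean(lin) + 0.5 * var_r))
        var_e = float(np.log1p(1.0 / lam))
    else:
        raise ValueError(f"unknown family {fit.family!r}")
    denom = var_f + var_r + var_e
    return var_f / denom, (var_f + var_r) / denom


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1/(1 - R^2_k)."""
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = float(np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2))
    return pd.Series(out)


def morans_i(residuals, coordinates) -> dict:
    """Moran's I with inverse-distance weights on a sphere.

    Rows sharing a coordinate (multiple records per forest) are aggregated by
    their mean residual first, since inverse-distance weights are undefined
    at zero distance.  Returns I, its null expectation -1/(n-1), a
    normal-approximation z and two-sided p.
    """
    from .ranges import great_circle_km

    r = np.asarray(residuals, dtype=float)
    xy = np.asarray(coordinates, dtype=float)
    if r.shape[0] != xy.shape[0]:
        raise ValueError("residuals and coordinates must align")
    df = pd.DataFrame({"lat": xy[:, 0], "lon": xy[:, 1], "r": r})
    agg = df.groupby(["lat", "lon"], as_index=False)["r"].mean()
    n = len(agg)
    if n < 3:
        raise ValueError("need at least 3 distinct locations")
    lat, lon, rv = agg["lat"].to_numpy(), agg["lon"].to_numpy(), agg["r"].to_numpy()
    rv = rv - rv.mean()
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = great_circle_km(lat[i], lon[i], lat[j], lon[j])
            if d <= 0:
                raise ValueError("duplicate locations after aggregation")
            W[i, j] = W[j, i] = 1.0 / d
    s0 = W.sum()
    i_stat = (n / s0) * float(rv @ W @ rv) / float(rv @ rv)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((W + W.T) ** 2)
    s2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
    var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    z = (i_stat - e_i) / np.sqrt(var_i)
    return {
        "I": float(i_stat),
        "expected": float(e_i),
        "z": float(z),
        "p_value": float(2 * stats.norm.sf(abs(z))),
        "n_locations": int(n),
    }


def pairwise_guild_tests(fit: MixedModelFit, term: str = "guild") -> pd.DataFrame:
    """Pairwise Wald z-tests among a categorical term's levels (Holm-adjusted).

    With a two-level factor this reduces to the single treatment-contrast
    test, matching what a Tukey post-hoc would report.
    """
    idxs = fit.term_indices.get(term)
    if not idxs:
        raise ValueError(f"term {term!r} not in the model")
    rows = []
    for i in idxs:
        b, se = fit.params.iloc[i], fit.bse.iloc[i]
        z = b / se
        rows.append(
            {
                "contrast": fit.params.index[i],
                "estimate": float(b),
                "se": float(se),
                "z": float(z),
                "p_value": float(2 * stats.norm.sf(abs(z))),
            }
        )
    out = pd.DataFrame(rows)
    order = np.argsort(out["p_value"].to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out["p_value"].iloc[idx])
        adj[idx] = min(1.0, running)
    out["p_holm"] = adj
    return out
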