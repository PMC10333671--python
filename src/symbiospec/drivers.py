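"""Environmental drivers of symbiont community composition.

Forest-level phylogroup abundance matrices are related to environmental
predictors by redundancy analysis (RDA): the community matrix is regressed on
standardized predictors and the fitted values eigen-decomposed, so the
proportion of constrained variance measures how much of the compositional
variation the environment explains.  Variation partitioning splits the
full-model adjusted R^2 (Ezekiel correction) into unique and shared fractions
per predictor group by inclusion-exclusion over all predictor subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RDAResult",
    "screen_predictors",
    "rda",
    "variation_partition",
    "richness_gradient_lm",
]


@dataclass
class RDAResult:
    constrained_eigenvalues: np.ndarray
    total_variance: float
    proportion_constrained: float
    predictor_names: list[str] = field(default_factory=list)


def screen_predictors(
    env: pd.DataFrame, r_threshold: float = 0.7
) -> list[str]:
    """Greedy collinearity screen: drop predictors until no pair has |r| above
    the threshold.

    At each step the worst-correlated pair is found and the member with the
    larger mean absolute correlation to all remaining predictors is dropped
    (ties: the later column).  Deterministic by construction.
    """
    if env.shape[1] < 2:
        return list(env.columns)
    if not (0.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must lie in (0, 1)")
    keep = list(env.columns)
    while len(keep) > 1:
        corr = env[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_threshold:
            break
        mean_i = corr[i].sum() / (len(keep) - 1)
        mean_j = corr[j].sum() / (len(keep) - 1)
        # drop the more redundant member; ties -> the later column
        drop = keep[j] if mean_j >= mean_i else keep[i]
        keep.remove(drop)
    return keep


def _prepare(Y, X) -> tuple[np.ndarray, np.ndarray]:
    Yv = np.asarray(Y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    if Yv.shape[0] != Xv.shape[0]:
        raise ValueError("Y and X must have aligned rows")
    n = Yv.shape[0]
    if n <= Xv.shape[1]:
        raise ValueError("need more sites than predictors")
    Yc = Yv - Yv.mean(axis=0)
    Xs = Xv - Xv.mean(axis=0)
    sd = Xs.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    Xs = Xs / sd
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        cols = list(X.columns) if hasattr(X, "columns") else list(range(Xv.shape[1]))
        raise ValueError(f"rank-deficient predictor matrix: columns {cols}")
    return Yc, Xs


def _constrained_fraction(Yc: np.ndarray, Xs: np.ndarray) -> tuple[np.ndarray, float]:
    """Fitted values' eigenvalues and trace fraction from multivariate OLS."""
    coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    Yhat = Xs @ coef
    n = Yc.shape[0]
    cov = Yhat.T @ Yhat / (n - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = eig[: Xs.shape[1]]
    total = float(np.trace(Yc.T @ Yc) / (n - 1))
    frac = float(np.trace(cov) / total) if total > 0 else 0.0
    return np.clip(eig, 0, None), frac


def rda(Y, X) -> RDAResult:
    """Redundancy analysis of a site x taxon matrix on site predictors.

    Y columns are centered; X columns centered and standardized.  The
    proportion of constrained variance is trace(Yhat' Yhat)/trace(Y' Y).
    """
    Yc, Xs = _prepare(Y, X)
    eig, frac = _constrained_fraction(Yc, Xs)
    n = Yc.shape[0]
    total = float(np.trace(Yc.T @ Yc) / (n - 1))
    names = list(X.columns) if hasattr(X, "columns") else [
        f"x{i}" for i in range(Xs.shape[1])
    ]
    return RDAResult(
        constrained_eigenvalues=eig,
        total_variance=total,
        proportion_constrained=frac,
        predictor_names=names,
    )


def hellinger(Y) -> np.ndarray:
    """Hellinger transformation: sqrt of row-relative abundances."""
    Yv = np.asarray(Y, dtype=float)
    row_sums = Yv.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("Hellinger transform needs positive row totals")
    return np.sqrt(Yv / row_sums)


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment, reported as-is even when negative."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partition(
    Y, X, groups: dict[str, list[str]]
) -> dict:
    """Partition constrained variance among up to 4 predictor groups.

    Computes raw and adjusted R^2 for every nonempty subset of groups, then
    derives the 2^k - 1 exclusive Venn fractions by Moebius inversion.
    Exclusive fractions may be negative (standard for adjusted R^2) and sum
    exactly to the full-model adjusted R^2.  Per-group contributions are
    reported two ways: the unique fraction alone, and unique plus equal
    shares of every overlap containing the group.
    """
    names = list(groups)
    if not 1 <= len(names) <= 4:
        raise ValueError("need between 1 and 4 predictor groups")
    Xdf = pd.DataFrame(X)
    n = len(Xdf)

    subset_r2: dict[frozenset, float] = {}
    subset_adj: dict[frozenset, float] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            cols = [c for g in combo for c in groups[g]]
            Yc, Xs = _prepare(Y, Xdf[cols])
            _, frac = _constrained_fraction(Yc, Xs)
            key = frozenset(combo)
            subset_r2[key] = frac
            subset_adj[key] = _adjusted_r2(frac, n, len(cols))

    full = frozenset(names)
    total_adj = subset_adj[full]

    def joint(subset: frozenset) -> float:
        """Adjusted R^2 of the union of groups in subset (0 for empty)."""
        return subset_adj[subset] if subset else 0.0

    # F(V) = adjR2(all) - adjR2(all minus V); exclusive e(S) by Moebius
    exclusive: dict[frozenset, float] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            S = frozenset(combo)
            e = 0.0
            for k2 in range(0, len(combo) + 1):
                for sub in combinations(combo, k2):
                    V = frozenset(sub)
                    F = total_adj - joint(full - V) if V else 0.0
                    e += (-1) ** (len(S) - len(V)) * F
            exclusive[S] = e

    unique = {g: exclusive[frozenset([g])] for g in names}
    shared_split = {}
    for g in names:
        contrib = unique[g]
        for S, e in exclusive.items():
            if g in S and len(S) > 1:
                contrib += e / len(S)
        shared_split[g] = contrib

    return {
        "groups": names,
        "subset_r2": {"+".join(sorted(k)): v for k, v in subset_r2.items()},
        "subset_adj_r2": {"+".join(sorted(k)): v for k, v in subset_adj.items()},
        "exclusive_fractions": {"+".join(sorted(k)): v for k, v in exclusive.items()},
        "unique": unique,
        "unique_plus_shared": shared_split,
        "total_adj_r2": total_adj,
    }


def richness_gradient_lm(richness, latitude) -> dict:
    """OLS of per-forest phylogroup richness on latitude."""
    y = np.asarray(richness, dtype=float)
    x = np.asarray(latitude, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need aligned vectors with n >= 3")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": int(y.size),
    }
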