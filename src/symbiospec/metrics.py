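"""Species-level specialization metrics and sampling-efficiency statistics.

Three complementary metrics quantify how specialized a mycobiont species is
towards its cyanobiont partners:

* partner richness — the count of distinct phylogroups used;
* Simpson's index ``D_i = sum_j p_ij^2`` over the species' partner-use
  frequencies (1 = always the same partner; low = even use of many);
* d' — the standardized Kullback-Leibler divergence of partner use from
  partner availability, ``d_i = sum_j p_ij ln(p_ij / q_j)`` rescaled to
  [0, 1].  A species using partners proportionally to their availability
  scores 0 (opportunism); exclusive use of the locally rarest partner scores
  1 (the reciprocal-specialization end).

Sampling efficiency contrasts observed richness against the bias-corrected
Chao1 estimate, with exact (hypergeometric) rarefaction curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .interactions import REGIONAL, InteractionTable, availability, eligible_pairs

__all__ = [
    "SpecializationRecord",
    "partner_richness",
    "simpson_index",
    "dprime",
    "chao1",
    "rarefaction_curve",
    "efficiency_test",
    "specialization_table",
]


@dataclass(frozen=True)
class SpecializationRecord:
    """Metrics for one species in one scope (a forest or the whole gradient)."""

    species: str
    scope: str
    n: int
    partner_richness: int
    simpson: float
    dprime: float
    chao1: float
    efficiency: float


def _as_counts(counts_row) -> np.ndarray:
    arr = np.asarray(counts_row, dtype=float)
    if arr.ndim != 1 or arr.sum() < 1:
        raise ValueError("counts row must be 1-D with a positive total")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be nonnegative integers")
    return arr


def partner_richness(counts_row) -> int:
    """Number of partners with at least one observed interaction."""
    return int(np.count_nonzero(_as_counts(counts_row)))


def simpson_index(counts_row) -> float:
    """Simpson's index of partner use, sum of squared frequencies."""
    arr = _as_counts(counts_row)
    p = arr / arr.sum()
    return float(np.sum(p * p))


def dprime(counts_row, q, bounds: str = "continuous") -> float:
    """Standardized Kullback-Leibler specialization index d'.

    ``q`` holds the availability of every phylogroup present in the scope
    (positive, summing to 1) aligned with ``counts_row``.  The raw divergence
    ``d = sum p ln(p/q)`` is rescaled by scope-level bounds: ``d_min = 0`` and
    ``d_max = ln(1/min(q))`` under the default continuous convention.
    ``bounds="integer"`` instead derives ``d_min`` from the closest
    integer-count allocation to proportional use (largest-remainder rounding
    of n*q), approximating the discrete-allocation convention of the
    reference d' implementation.
    """
    counts = _as_counts(counts_row)
    qv = np.asarray(q, dtype=float)
    if qv.shape != counts.shape:
        raise ValueError("counts and availability must align")
    if np.any(qv <= 0) and np.any(counts[qv <= 0] > 0):
        raise ValueError("interaction recorded with a partner of zero availability")
    if not np.isclose(qv.sum(), 1.0, atol=1e-8):
        raise ValueError("availability must sum to 1")
    p = counts / counts.sum()
    nz = p > 0
    d = float(np.sum(p[nz] * np.log(p[nz] / qv[nz])))

    d_max = float(np.log(1.0 / qv[qv > 0].min()))
    if bounds == "continuous":
        d_min = 0.0
    elif bounds == "integer":
        n = int(counts.sum())
        ideal = qv * n
        alloc = np.floor(ideal)
        remainder = ideal - alloc
        short = int(n - alloc.sum())
        if short > 0:
            top = np.argsort(-remainder, kind="stable")[:short]
            alloc[top] += 1
        pa = alloc / n
        nza = pa > 0
        d_min = float(np.sum(pa[nza] * np.log(pa[nza] / qv[nza])))
    else:
        raise ValueError(f"unknown bounds convention {bounds!r}")

    if d_max - d_min <= 0:
        return 0.0
    return float(np.clip((d - d_min) / (d_max - d_min), 0.0, 1.0))


def chao1(counts_row, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate (bias-corrected by default)."""
    arr = _as_counts(counts_row).astype(int)
    return float(_skbio_chao1(arr, bias_corrected=bias_corrected))


def rarefaction_curve(counts_row, m: int) -> float:
    """Exact expected richness in a random subsample of m individuals.

    ``E[S_m] = sum_j [1 - C(N - n_j, m) / C(N, m)]`` for the hypergeometric
    draw without replacement.
    """
    arr = _as_counts(counts_row)
    arr = arr[arr > 0]
    total = int(arr.sum())
    if not (1 <= m <= total):
        raise ValueError(f"m must be in [1, {total}]")

    def lchoose(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    expected = 0.0
    for nj in arr:
        if total - nj < m:
            expected += 1.0
        else:
            expected += 1.0 - np.exp(lchoose(total - nj, m) - lchoose(total, m))
    return float(expected)


def efficiency_test(observed, estimated) -> tuple[float, float, float]:
    """Welch two-sample t-test of observed richness vs Chao1 estimates.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(estimated, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        df = float(2 * a.size - 2)
    else:
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
    return float(t), float(df), float(p)


def specialization_table(
    table: InteractionTable,
    min_regional: int = 10,
    min_local: int = 4,
    dprime_bounds: str = "continuous",
) -> pd.DataFrame:
    """Per-(species, scope) metrics for every eligible species.

    Regional rows (scope="regional") are produced for every species passing
    the regional filter; forest rows only where the local filter also passes.
    """
    rows: list[SpecializationRecord] = []
    pairs = eligible_pairs(table, min_regional, min_local)
    # species passing only the regional filter still get a regional row
    from .interactions import filter_species_regional

    q_cache: dict[str | None, pd.Series] = {}

    def scoped_metrics(species: str, forest: str | None) -> SpecializationRecord:
        row = table.species_counts_row(species, forest)
        key = forest
        if key not in q_cache:
            q_cache[key] = availability(table, forest)
        q = q_cache[key].reindex(q_cache[key].index)
        aligned = row.reindex(q.index, fill_value=0).to_numpy()
        rich = partner_richness(aligned)
        ch = chao1(aligned)
        return SpecializationRecord(
            species=species,
            scope=forest if forest is not None else REGIONAL,
            n=int(row.sum()),
            partner_richness=rich,
            simpson=simpson_index(aligned),
            dprime=dprime(aligned, q.to_numpy(), bounds=dprime_bounds),
            chao1=ch,
            efficiency=rich / ch,
        )

    for species in filter_species_regional(table, min_regional):
        rows.append(scoped_metrics(species, None))
    for species, forest in pairs:
        rows.append(scoped_metrics(species, forest))
    return pd.DataFrame([r.__dict__ for r in rows])
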