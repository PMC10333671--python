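"""Beta-diversity partition of within-species partner turnover across scales.

Total pairwise beta diversity (Jaccard-family, incidence-based) splits
additively into a replacement and a richness-difference component: with
``a`` shared partners and ``b``, ``c`` unique to either side,

    beta_total = (b + c) / (a + b + c)
    beta_repl  = 2 min(b, c) / (a + b + c)
    beta_rich  = |b - c| / (a + b + c)

Each comparison is classified into one of four turnover scenarios:
no turnover (identical partner sets), nested loss/gain (pure gain or loss),
partial replacement, or total replacement.  Because a species' local partner
set is always a subset of its regional set, forest-vs-regional comparisons
can only be no_turnover or nested — the structural reason nested outcomes
dominate across spatial scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .interactions import REGIONAL, InteractionTable, eligible_pairs

SCENARIOS = ("no_turnover", "nested", "partial_replacement", "total_replacement")


@dataclass(frozen=True)
class TurnoverResult:
    species: str
    comparison: str
    a: int
    b: int
    c: int
    beta_total: float
    beta_repl: float
    beta_rich: float
    scenario: str


def beta_partition(set_a: set, set_b: set) -> tuple[float, float, float]:
    """(beta_total, beta_repl, beta_rich) for two incidence sets."""
    if not set_a and not set_b:
        raise ValueError("both partner sets are empty: comparison undefined")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    denom = a + b + c
    return ((b + c) / denom, 2 * min(b, c) / denom, abs(b - c) / denom)


def classify_scenario(a: int, b: int, c: int) -> str:
    """Turnover scenario from shared/unique partner counts."""
    if a + b + c < 1:
        raise ValueError("empty comparison")
    if b == 0 and c == 0:
        return "no_turnover"
    if min(b, c) == 0:
        return "nested"
    if a == 0:
        return "total_replacement"
    return "partial_replacement"


def _compare(species: str, label: str, set_a: set, set_b: set) -> TurnoverResult:
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    bt, br, brich = beta_partition(set_a, set_b)
    return TurnoverResult(
        species=species, comparison=label, a=a, b=b, c=c,
        beta_total=bt, beta_repl=br, beta_rich=brich,
        scenario=classify_scenario(a, b, c),
    )


def local_vs_regional(
    table: InteractionTable,
    species: str,
    min_regional: int = 10,
    min_local: int = 4,
) -> tuple[list[TurnoverResult], dict]:
    """Compare each eligible forest's partner set with the regional set.

    Returns the per-forest results plus a species summary with per-scenario
    counts and an ``exclusive_no_turnover`` flag (True iff every comparison
    is no_turnover — the species keeps its exact partner set at all scales).
    """
    pairs = [
        (sp, f) for sp, f in eligible_pairs(table, min_regional, min_local)
        if sp == species
    ]
    if not pairs:
        raise ValueError(
            f"species {species!r} has no eligible forest under the filters"
        )
    regional_set = set(table.species_counts_row(species).index)
    results = []
    for _, forest in pairs:
        local_set = set(table.species_counts_row(species, forest).index)
        results.append(
            _compare(species, f"{forest}_vs_{REGIONAL}", local_set, regional_set)
        )
    scen_counts = {s: sum(r.scenario == s for r in results) for s in SCENARIOS}
    summary = {
        "species": species,
        "n_comparisons": len(results),
        "scenario_counts": scen_counts,
        "exclusive_no_turnover": scen_counts["no_turnover"] == len(results),
    }
    return results, summary


def forest_pairs(
    table: InteractionTable,
    species: str,
    min_regional: int = 10,
    min_local: int = 4,
) -> list[TurnoverResult]:
    """Pairwise forest-vs-forest comparisons for one species.

    Unlike forest-vs-regional comparisons these can show partial or total
    replacement.
    """
    forests = sorted(
        f for sp, f in eligible_pairs(table, min_regional, min_local)
        if sp == species
    )
    results = []
    for i, fa in enumerate(forests):
        set_a = set(table.species_counts_row(species, fa).index)
        for fb in forests[i + 1:]:
            set_b = set(table.species_counts_row(species, fb).index)
            results.append(_compare(species, f"{fa}_vs_{fb}", set_a, set_b))
    return results


def turnover_table(
    table: InteractionTable, min_regional: int = 10, min_local: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All species' turnover results (long table) plus per-species summaries."""
    rows, summaries = [], []
    species_with_pairs = sorted(
        {sp for sp, _ in eligible_pairs(table, min_regional, min_local)}
    )
    for sp in species_with_pairs:
        results, summary = local_vs_regional(table, sp, min_regional, min_local)
        results += forest_pairs(table, sp, min_regional, min_local)
        rows += [r.__dict__ for r in results]
        summaries.append(
            {
                "species": sp,
                "n_comparisons": summary["n_comparisons"],
                **{f"n_{s}": summary["scenario_counts"][s] for s in SCENARIOS},
                "exclusive_no_turnover": summary["exclusive_no_turnover"],
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(summaries)
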