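"""Distributional ranges along the gradient and partner-limitation screening.

A species' (or phylogroup's) distributional range is the maximum great-circle
distance between the forests it occupies — on a quasi-linear latitudinal
transect this equals the endpoint distance.  The partner-limitation screen
flags species whose range coincides with that of a narrowly distributed
partner; the paper-style question is whether lichen distributions are capped
by the distributions of their cyanobionts (mostly they are not: most species
use at least one widely distributed partner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interactions import InteractionTable, filter_species_regional

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class RangeRecord:
    entity: str
    entity_type: str  # "species" or "phylogroup"
    occupied_forests: tuple[str, ...]
    range_km: float
    n_occurrences: int


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance on a 6371-km sphere."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def distributional_range(
    entity: str,
    entity_type: str,
    occurrences: pd.DataFrame,
    forest_coords: dict[str, tuple[float, float]],
) -> RangeRecord:
    """Max pairwise great-circle distance among occupied forests.

    ``occurrences`` is the long count table filtered to the entity; rows with
    zero count are ignored.
    """
    occ = occurrences[occurrences["count"] > 0]
    forests = sorted(occ["forest"].unique())
    if not forests:
        raise ValueError(f"{entity_type} {entity!r} has no occurrences")
    missing = [f for f in forests if f not in forest_coords]
    if missing:
        raise ValueError(f"missing coordinates for forests {missing}")
    best = 0.0
    for i, fa in enumerate(forests):
        for fb in forests[i + 1:]:
            d = great_circle_km(*forest_coords[fa], *forest_coords[fb])
            best = max(best, d)
    return RangeRecord(
        entity=entity,
        entity_type=entity_type,
        occupied_forests=tuple(forests),
        range_km=best,
        n_occurrences=int(occ["count"].sum()),
    )


def range_table(
    table: InteractionTable, forest_coords: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Ranges for every species and every phylogroup in the table."""
    rows = []
    for sp in table.species:
        occ = table.counts[table.counts["species"] == sp]
        rows.append(distributional_range(sp, "species", occ, forest_coords))
    for pg in table.phylogroups:
        occ = table.counts[table.counts["phylogroup"] == pg]
        rows.append(distributional_range(pg, "phylogroup", occ, forest_coords))
    return pd.DataFrame(
        [
            {
                "entity": r.entity,
                "entity_type": r.entity_type,
                "n_forests": len(r.occupied_forests),
                "range_km": r.range_km,
                "n_occurrences": r.n_occurrences,
                "occupied_forests": ",".join(r.occupied_forests),
            }
            for r in rows
        ]
    )


def richness_vs_range_lm(
    table: InteractionTable,
    forest_coords: dict[str, tuple[float, float]],
    min_regional: int = 10,
) -> dict:
    """OLS of species range (km) on regional partner richness.

    Only species with at least ``min_regional`` thalli along the gradient
    enter, mirroring the inclusion rule used for the metrics.
    """
    species = filter_species_regional(table, min_regional)
    if len(species) < 3:
        raise ValueError("need at least 3 eligible species")
    rich, rng = [], []
    for sp in species:
        occ = table.counts[table.counts["species"] == sp]
        rec = distributional_range(sp, "species", occ, forest_coords)
        rng.append(rec.range_km)
        rich.append(int((table.species_counts_row(sp) > 0).sum()))
    fit = stats.linregress(rich, rng)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": len(species),
    }


def partner_limitation(
    table: InteractionTable,
    forest_coords: dict[str, tuple[float, float]],
    tolerance: float = 0.05,
    max_richness: int = 2,
    span_fraction: float = 0.75,
) -> pd.DataFrame:
    """Flag species whose distribution may be capped by their partners'.

    A species is "potentially limited" when its range matches its partners'
    maximum range within ``tolerance`` (relative), it uses at most
    ``max_richness`` partners, no used partner ranges more broadly, and the
    binding partner's range is itself restricted — below ``span_fraction``
    of the full sampled gradient (a gradient-wide partner cannot cap a
    distribution).  A "reciprocal match" is an exclusive one-to-one pair
    occupying exactly the same forests.  All thresholds are heuristics and
    are exposed as parameters.
    """
    ranges = range_table(table, forest_coords)
    all_forests = list(forest_coords)
    gradient_span = max(
        (
            great_circle_km(*forest_coords[a], *forest_coords[b])
            for i, a in enumerate(all_forests)
            for b in all_forests[i + 1:]
        ),
        default=0.0,
    )
    sp_ranges = ranges[ranges["entity_type"] == "species"].set_index("entity")
    pg_ranges = ranges[ranges["entity_type"] == "phylogroup"].set_index("entity")
    pg_partners = {
        pg: set(table.counts[table.counts["phylogroup"] == pg]["species"])
        for pg in table.phylogroups
    }
    rows = []
    for sp in table.species:
        partners = list(table.species_counts_row(sp).index)
        max_partner_range = float(pg_ranges.loc[partners, "range_km"].max())
        sp_range = float(sp_ranges.loc[sp, "range_km"])
        denom = max(sp_range, max_partner_range, 1e-9)
        close = abs(sp_range - max_partner_range) / denom <= tolerance
        limited = (
            close
            and len(partners) <= max_richness
            and max_partner_range < span_fraction * gradient_span
            and not any(
                float(pg_ranges.loc[pg, "range_km"]) > sp_range * (1 + tolerance)
                for pg in partners
            )
        )
        reciprocal = False
        if len(partners) == 1:
            pg = partners[0]
            if pg_partners[pg] == {sp}:
                sp_forests = set(sp_ranges.loc[sp, "occupied_forests"].split(","))
                pg_forests = set(pg_ranges.loc[pg, "occupied_forests"].split(","))
                reciprocal = sp_forests == pg_forests
        rows.append(
            {
                "species": sp,
                "partner_richness": len(partners),
                "range_km": sp_range,
                "max_partner_range_km": max_partner_range,
                "potentially_limited": limited,
                "reciprocal_match": reciprocal,
            }
        )
    return pd.DataFrame(rows)
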