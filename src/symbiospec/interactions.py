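"""Interaction tables: who associates with whom, where, and how often.

Counts are indexed by (forest, mycobiont species, cyanobiont phylogroup); one
thallus contributes one interaction event.  Availability ``q_f`` is the
community-wide relative frequency of each phylogroup in a forest — computed
over *all* thalli in the forest, including the focal species' own (the
column-marginal convention of the standard d' implementation).  Species that
fail the inclusion filters still contribute to availability: they are part of
the realized community.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ThallusRecord

REGIONAL = "regional"


@dataclass
class InteractionTable:
    """Long-format interaction counts with derived marginals."""

    counts: pd.DataFrame  # columns: forest, species, phylogroup, count

    @classmethod
    def from_records(cls, records: list[ThallusRecord]) -> "InteractionTable":
        return build_table(records)

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())

    @property
    def forests(self) -> list[str]:
        return sorted(self.counts["forest"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.counts["species"].unique())

    @property
    def phylogroups(self) -> list[str]:
        return sorted(self.counts["phylogroup"].unique())

    def regional_counts(self) -> pd.DataFrame:
        """Collapse over forests: counts n(i, j)."""
        return (
            self.counts.groupby(["species", "phylogroup"], as_index=False)["count"]
            .sum()
        )

    def species_counts_row(self, species: str, forest: str | None = None) -> pd.Series:
        """Partner-use counts of one species, locally or regionally."""
        df = self.counts[self.counts["species"] == species]
        if forest is not None:
            df = df[df["forest"] == forest]
        row = df.groupby("phylogroup")["count"].sum()
        return row[row > 0].sort_index()

    def forest_matrix(self) -> pd.DataFrame:
        """Forest x phylogroup abundance matrix (all species pooled)."""
        return (
            self.counts.groupby(["forest", "phylogroup"])["count"]
            .sum()
            .unstack(fill_value=0)
            .sort_index()
        )

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def build_table(records: list[ThallusRecord]) -> InteractionTable:
    """Tally thallus records into an interaction table."""
    if not records:
        return InteractionTable(
            counts=pd.DataFrame(columns=["forest", "species", "phylogroup", "count"])
        )
    unlabeled = [r.thallus_id for r in records if not r.phylogroup]
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} records lack a phylogroup label "
            f"(first: {unlabeled[0]!r}); run delimitation first"
        )
    df = pd.DataFrame(
        {
            "forest": [r.forest for r in records],
            "species": [r.species for r in records],
            "phylogroup": [r.phylogroup for r in records],
        }
    )
    counts = (
        df.groupby(["forest", "species", "phylogroup"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["forest", "species", "phylogroup"], ignore_index=True)
    )
    return InteractionTable(counts=counts)


def filter_species_regional(table: InteractionTable, min_total: int) -> list[str]:
    """Species with at least ``min_total`` thalli across the whole gradient."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = table.counts.groupby("species")["count"].sum()
    return sorted(totals.index[totals >= min_total])


def filter_species_local(
    table: InteractionTable, species: str, forest: str, min_local: int
) -> bool:
    """True iff the species has >= ``min_local`` thalli in that forest."""
    n = table.counts[
        (table.counts["species"] == species) & (table.counts["forest"] == forest)
    ]["count"].sum()
    return bool(n >= min_local)


def eligible_pairs(
    table: InteractionTable, min_regional: int, min_local: int
) -> list[tuple[str, str]]:
    """(species, forest) pairs passing both inclusion filters, sorted."""
    regional = set(filter_species_regional(table, min_regional))
    local = table.counts.groupby(["species", "forest"])["count"].sum()
    return sorted(
        (sp, f)
        for (sp, f), n in local.items()
        if sp in regional and n >= min_local
    )


def availability(table: InteractionTable, forest: str | None = None) -> pd.Series:
    """Relative availability q of each phylogroup in a forest (or regionally).

    Computed over all thalli in the scope; sums to 1.
    """
    df = table.counts
    if forest is not None:
        df = df[df["forest"] == forest]
        if df.empty:
            raise ValueError(f"forest {forest!r} has no records")
    elif df.empty:
        raise ValueError("empty interaction table")
    q = df.groupby("phylogroup")["count"].sum().astype(float)
    q = q[q > 0].sort_index()
    return q / q.sum()
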