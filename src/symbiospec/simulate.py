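"""Synthetic lichen-symbiont communities with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any external download:

* 11 forests on a latitudinal gradient, each with a stand-level environment
  (mean annual temperature declining with latitude plus noise, and
  correlated covariates);
* ~60 cyanobiont phylogroups whose forest-level availability q combines a
  geometric rank-abundance decay (a few abundant, most locally rare) with
  Gaussian niche filtering on the temperature axis;
* mycobiont species with a guild (cyanolichen/cephalolichen), a reproductive
  mode, and a latent partner-preference vector w drawn from a symmetric
  Dirichlet whose concentration alpha is the single specialist<->generalist
  knob (alpha -> 0: one partner only; alpha -> infinity: opportunist);
* per-thallus partner draws with probability proportional to q_f * w_i, and
  marker sequences evolved i.i.d. per site (Jukes-Cantor generative model)
  from mutually divergent phylogroup root sequences.

True preference vectors and true phylogroup labels are returned for
parameter-recovery and delimitation-recovery tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlignedSequenceSet, ForestMeta, ThallusRecord

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


class DegenerateConfigError(ValueError):
    """Raised when a configuration cannot produce a valid community."""


@dataclass
class CommunityConfig:
    """Knobs of the synthetic community; defaults are the study conditions."""

    n_forests: int = 11
    lat_north: float = -38.63
    lat_south: float = -54.96
    env_noise_sd: float = 0.5
    n_phylogroups: int = 60
    niche_breadth_range: tuple[float, float] = (1.5, 4.0)
    abundance_decay: float = 0.80
    n_mycobionts: int = 40
    p_cyanolichen: float = 0.6
    alpha_log10_range: tuple[float, float] = (-1.5, 1.0)
    occupancy_prob: float = 0.5
    thalli_min: int = 4
    thalli_max: int = 8
    sequence_length: int = 600
    within_divergence_cap: float = 0.004
    between_divergence_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_forests, self.n_phylogroups, self.n_mycobionts) < 1:
            raise ValueError("all counts must be positive")
        if not (1 <= self.thalli_min <= self.thalli_max):
            raise ValueError("need 1 <= thalli_min <= thalli_max")
        if not (
            0 < self.within_divergence_cap
            < self.between_divergence_floor
            < 0.75
        ):
            raise ValueError(
                "need 0 < within_divergence_cap < between_divergence_floor < 0.75"
            )
        if not 0.0 < self.abundance_decay < 1.0:
            raise ValueError("abundance_decay must lie in (0, 1)")


@dataclass
class SyntheticCommunity:
    """A generated community with its complete ground truth."""

    config: CommunityConfig
    forests: list[ForestMeta]
    pools: pd.DataFrame  # forest x phylogroup availability, rows sum to 1
    species_traits: pd.DataFrame  # guild, repro_mode, alpha per species
    true_preferences: pd.DataFrame  # species x phylogroup Dirichlet draws
    records: list[ThallusRecord] = field(default_factory=list)
    alignment: AlignedSequenceSet | None = None

    @property
    def true_partition(self) -> dict[str, str]:
        """Sequence id -> true phylogroup label."""
        return {r.thallus_id: r.phylogroup for r in self.records}


def _phylogroup_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"pg{i + 1:0{width}d}" for i in range(n)]


def _species_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"sp{i + 1:0{width}d}" for i in range(n)]


def generate_forest_meta(
    config: CommunityConfig, rng: np.random.Generator
) -> list[ForestMeta]:
    """Forests evenly spaced on the latitudinal span with correlated covariates."""
    lats = np.linspace(config.lat_north, config.lat_south, config.n_forests)
    forests = []
    for i, lat in enumerate(lats):
        # mean annual temperature declines towards the pole
        bio01 = 25.0 + 0.35 * lat + rng.normal(0.0, config.env_noise_sd)
        # related but not collinear with bio01 (screening keeps both)
        bio06 = bio01 - 8.0 + rng.normal(0.0, 2.5)
        bio14 = max(5.0, 45.0 + 0.4 * (lat - lats.mean()) + rng.normal(0.0, 6.0))
        forests.append(
            ForestMeta(
                forest=f"F{i + 1:02d}",
                latitude=float(lat),
                longitude=float(-72.0 + rng.normal(0.0, 0.6)),
                elevation=float(rng.normal(900.0, 150.0)),
                slope=float(rng.uniform(5.0, 30.0)),
                orientation=float(rng.uniform(0.0, 360.0)),
                canopy_openness=float(rng.uniform(10.0, 40.0)),
                dbh=float(rng.normal(45.0, 8.0)),
                bio01=float(bio01),
                bio06=float(bio06),
                bio14=float(bio14),
            )
        )
    return forests


def generate_forest_pools(
    config: CommunityConfig,
    forests: list[ForestMeta] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-forest availability vectors q (rows sum to 1).

    q_fj is proportional to a geometric rank-abundance weight times a
    Gaussian niche response of phylogroup j to the forest's temperature.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if forests is None:
        forests = generate_forest_meta(config, rng)
    g = config.abundance_decay
    ranks = np.arange(config.n_phylogroups)
    weights = (1 - g) * g**ranks
    env = np.array([f.bio01 for f in forests])
    lo, hi = env.min() - 1.0, env.max() + 1.0
    optima = rng.uniform(lo, hi, size=config.n_phylogroups)
    breadths = rng.uniform(*config.niche_breadth_range, size=config.n_phylogroups)
    q = weights[None, :] * np.exp(
        -((env[:, None] - optima[None, :]) ** 2) / (2 * breadths[None, :] ** 2)
    )
    q[q < np.finfo(float).eps] = 0.0
    row_sums = q.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = [forests[i].forest for i in np.flatnonzero(row_sums <= 0)]
        raise DegenerateConfigError(f"all-zero phylogroup pool for forests {bad}")
    q = q / row_sums[:, None]
    return pd.DataFrame(
        q, index=[f.forest for f in forests],
        columns=_phylogroup_names(config.n_phylogroups),
    )


def generate_species_traits(
    config: CommunityConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Guild, reproductive mode, Dirichlet concentration, and true preferences."""
    names = _species_names(config.n_mycobionts)
    guilds = np.where(
        rng.random(config.n_mycobionts) < config.p_cyanolichen,
        "cyanolichen",
        "cephalolichen",
    )
    modes = rng.choice(
        ["sexual", "asexual", "both", "none"],
        size=config.n_mycobionts,
        p=[0.40, 0.35, 0.20, 0.05],
    )
    alphas = 10.0 ** rng.uniform(*config.alpha_log10_range, size=config.n_mycobionts)
    prefs = np.vstack(
        [
            rng.dirichlet(np.full(config.n_phylogroups, a))
            for a in alphas
        ]
    )
    traits = pd.DataFrame(
        {"guild": guilds, "repro_mode": modes, "alpha": alphas}, index=names
    )
    pref_df = pd.DataFrame(
        prefs, index=names, columns=_phylogroup_names(config.n_phylogroups)
    )
    return traits, pref_df


def generate_interactions(
    config: CommunityConfig,
    pools: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    preferences: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ThallusRecord], pd.DataFrame]:
    """Draw thallus records: partner ~ q_f * w_i per thallus.

    Returns the records and the true preference matrix used (for
    parameter-recovery tests).  Species whose preference-times-pool product
    has zero support in an occupied forest have that occupancy resampled to
    absent (logged).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if traits is None or preferences is None:
        traits, preferences = generate_species_traits(config, rng)
    phylogroups = list(pools.columns)
    records: list[ThallusRecord] = []
    counter = 0
    m = config.occupancy_prob
    # per-species occupancy around the configured mean: some species are
    # widespread, some rare enough to fail the regional inclusion filter
    if m >= 1.0:
        occupancy = np.ones(len(traits.index))
    else:
        occupancy = rng.beta(1.5, 1.5 * (1.0 - m) / m, size=len(traits.index))
    for sp, occ_p in zip(traits.index, occupancy):
        w = preferences.loc[sp].to_numpy()
        for forest in pools.index:
            if rng.random() >= occ_p:
                continue
            probs = pools.loc[forest].to_numpy() * w
            total = probs.sum()
            if total <= 0:
                logger.info(
                    "species %s occupancy in %s resampled: zero preference-pool"
                    " support", sp, forest,
                )
                continue
            probs = probs / total
            n_thalli = int(rng.integers(config.thalli_min, config.thalli_max + 1))
            draws = rng.choice(len(phylogroups), size=n_thalli, p=probs)
            for d in draws:
                counter += 1
                records.append(
                    ThallusRecord(
                        thallus_id=f"t{counter:06d}",
                        forest=forest,
                        species=sp,
                        guild=str(traits.loc[sp, "guild"]),
                        repro_mode=str(traits.loc[sp, "repro_mode"]),
                        phylogroup=phylogroups[d],
                    )
                )
    return records, preferences


def _jc_p_from_d(d: float) -> float:
    """Raw mismatch proportion corresponding to a JC69 distance."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def generate_sequences(
    records: list[ThallusRecord],
    config: CommunityConfig,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> AlignedSequenceSet:
    """One aligned marker sequence per record, evolved from phylogroup roots.

    Roots are random sequences kept mutually divergent enough that any two
    copies from different phylogroups stay at or above the between-group
    floor; each copy mutates at most floor(p_cap * L / 2) sites so any two
    copies of the same phylogroup stay below the within-group cap.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    length = config.sequence_length
    labels = sorted({r.phylogroup for r in records})
    p_cap = _jc_p_from_d(config.within_divergence_cap)
    m_max = int(np.floor(p_cap * length / 2.0))
    p_floor = _jc_p_from_d(config.between_divergence_floor)
    # roots must stay >= floor even after both copies drift by m_max sites
    required = p_floor + 2.0 * m_max / length
    # roots radiate from one ancestor at ~3x the floor so between-group
    # distances stay far below saturation (realistic marker-scale divergence)
    p_target = min(_jc_p_from_d(3.0 * config.between_divergence_floor), 0.4)
    m_root = int(np.ceil(p_target * length / 2.0))
    if required >= 2.0 * m_root / length:
        raise DegenerateConfigError(
            "between-group divergence floor unreachable at this length"
        )
    ancestor = rng.integers(0, 4, size=length)
    roots: list[np.ndarray] = []
    for _ in labels:
        for _try in range(max_tries):
            cand = ancestor.copy()
            sites = rng.choice(length, size=m_root, replace=False)
            cand[sites] = (cand[sites] + rng.integers(1, 4, size=m_root)) % 4
            if all(np.mean(cand != r) >= required for r in roots):
                roots.append(cand)
                break
        else:
            raise DegenerateConfigError(
                f"cannot place {len(labels)} phylogroup roots at pairwise "
                f"divergence >= {config.between_divergence_floor} with "
                f"length {length}"
            )
    root_of = dict(zip(labels, roots))
    ids, seqs, meta = [], [], {}
    for rec in records:
        seq = root_of[rec.phylogroup].copy()
        if m_max > 0:
            m = int(rng.integers(0, m_max + 1))
            if m:
                sites = rng.choice(length, size=m, replace=False)
                shift = rng.integers(1, 4, size=m)
                seq[sites] = (seq[sites] + shift) % 4
        ids.append(rec.thallus_id)
        seqs.append("".join(BASES[seq]))
        meta[rec.thallus_id] = {"forest": rec.forest, "species": rec.species}
    return AlignedSequenceSet(ids=ids, sequences=seqs, metadata=meta)


def generate_community(config: CommunityConfig) -> SyntheticCommunity:
    """Full synthetic community: forests, pools, records, sequences, truth."""
    rng = np.random.default_rng(config.seed)
    forests = generate_forest_meta(config, rng)
    pools = generate_forest_pools(config, forests, rng)
    traits, prefs = generate_species_traits(config, rng)
    records, _ = generate_interactions(config, pools, traits, prefs, rng)
    alignment = generate_sequences(records, config, rng)
    return SyntheticCommunity(
        config=config,
        forests=forests,
        pools=pools,
        species_traits=traits,
        true_preferences=prefs,
        records=records,
        alignment=alignment,
    )


def config_to_json(config: CommunityConfig, path) -> None:
    import json
    from pathlib import Path

    Path(path).write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n", encoding="utf-8"
    )


def config_from_json(path) -> CommunityConfig:
    import json
    from pathlib import Path

    data = json.loads(Path(path).read_text(encoding="utf-8"))
    for key in ("niche_breadth_range", "alpha_log10_range"):
        if key in data:
            data[key] = tuple(data[key])
    return CommunityConfig(**data)
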