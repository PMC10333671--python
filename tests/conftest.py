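import numpy as np
import pandas as pd
import pytest

from symbiospec.core import ThallusRecord
from symbiospec.interactions import build_table
from symbiospec.simulate import (
    CommunityConfig,
    generate_community,
    generate_forest_meta,
    generate_forest_pools,
    generate_interactions,
)


def small_config(seed: int = 0, **overrides) -> CommunityConfig:
    """A reduced community that keeps every structural feature of the default."""
    kw = dict(
        n_forests=5,
        n_phylogroups=10,
        n_mycobionts=8,
        occupancy_prob=0.7,
        thalli_min=4,
        thalli_max=6,
        sequence_length=600,
        seed=seed,
    )
    kw.update(overrides)
    return CommunityConfig(**kw)


@pytest.fixture(scope="session")
def small_community():
    return generate_community(small_config(seed=11))


@pytest.fixture(scope="session")
def default_community():
    """Full-size community at the study conditions (shared, read-only)."""
    return generate_community(CommunityConfig(seed=7))


def records_only(seed: int, **overrides):
    """Thallus records without the (slow) sequence stage."""
    cfg = small_config(seed, **overrides)
    rng = np.random.default_rng(cfg.seed)
    forests = generate_forest_meta(cfg, rng)
    pools = generate_forest_pools(cfg, forests, rng)
    records, prefs = generate_interactions(cfg, pools, rng=rng)
    return cfg, forests, pools, records, prefs


def make_records(triples, guild="cyanolichen", mode="sexual"):
    """ThallusRecords from (forest, species, phylogroup) triples."""
    return [
        ThallusRecord(
            thallus_id=f"t{k}", forest=f, species=s, guild=guild,
            repro_mode=mode, phylogroup=p,
        )
        for k, (f, s, p) in enumerate(triples)
    ]


@pytest.fixture()
def toy_table():
    """Hand-countable table: 2 forests, 3 species, 3 phylogroups."""
    triples = (
        [("F1", "spA", "pg1")] * 3 + [("F1", "spA", "pg2")] * 1
        + [("F1", "spB", "pg2")] * 4
        + [("F2", "spA", "pg1")] * 2 + [("F2", "spA", "pg3")] * 2
        + [("F2", "spC", "pg3")] * 5
    )
    return build_table(make_records(triples))
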