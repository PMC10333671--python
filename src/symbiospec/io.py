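"""Readers and writers for the pipeline's external formats.

Aligned marker sequences travel as FASTA with ``|forest=<id>|species=<name>``
key-value tags appended to the record id; thallus records and forest metadata
are UTF-8 TSV with fixed column orders.  Every writer/reader pair is an
identity on valid files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignedSequenceSet,
    ForestMeta,
    GUILDS,
    MetadataError,
    REPRO_MODES,
    ThallusRecord,
)

THALLUS_COLUMNS = ["thallus_id", "forest", "species", "guild", "repro_mode", "phylogroup"]
FOREST_COLUMNS = [
    "forest", "latitude", "longitude", "elevation", "slope", "orientation",
    "canopy_openness", "dbh", "bio01", "bio06", "bio14",
]


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration; echoed (with the seed) into every output."""

    threshold_band: tuple[float, float] = (0.001, 0.01)
    min_regional_sequences: int = 10
    min_local_sequences: int = 4
    seed: int = 0
    alignment_path: str | None = None
    thallus_path: str | None = None
    forest_path: str | None = None
    output_dir: str = "symbiospec_out"

    def __post_init__(self) -> None:
        lo, hi = self.threshold_band
        if not (0.0 < lo < hi < 0.75):
            raise ValueError(
                f"threshold band must satisfy 0 < lo < hi < 0.75, got ({lo}, {hi})"
            )
        if self.min_regional_sequences < 1 or self.min_local_sequences < 1:
            raise ValueError("minimum sequence counts must be >= 1")
        self.seed = int(self.seed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        if "threshold_band" in data:
            data["threshold_band"] = tuple(data["threshold_band"])
        return cls(**data)


def _parse_header(header: str) -> tuple[str, dict[str, str]]:
    parts = header.split("|")
    sid = parts[0]
    tags = {}
    for part in parts[1:]:
        if "=" in part:
            key, value = part.split("=", 1)
            tags[key] = value
    missing = {"forest", "species"} - tags.keys()
    if missing:
        raise MetadataError(
            f"sequence {sid!r} is missing header tags: {sorted(missing)}"
        )
    return sid, tags


def read_alignment(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA whose headers carry forest/species tags."""
    ids, seqs, meta = [], [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid, tags = _parse_header(rec.id)
        ids.append(sid)
        seqs.append(str(rec.seq).upper())
        meta[sid] = tags
    return AlignedSequenceSet(ids=ids, sequences=seqs, metadata=meta)


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    records = []
    for sid, seq in zip(aln.ids, aln.sequences):
        tags = aln.metadata.get(sid, {})
        header = sid + "".join(f"|{k}={v}" for k, v in tags.items())
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_thallus_table(path: str | Path) -> list[ThallusRecord]:
    """Read per-thallus records; fails listing every offending row."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = set(THALLUS_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"thallus table missing columns: {sorted(missing)}")
    bad_rows = []
    for idx, row in df.iterrows():
        if row["guild"] not in GUILDS or row["repro_mode"] not in REPRO_MODES:
            bad_rows.append(
                f"row {idx}: guild={row['guild']!r} repro_mode={row['repro_mode']!r}"
            )
    if bad_rows:
        from .core import ValidationError

        raise ValidationError(
            "invalid guild/repro_mode tokens:\n" + "\n".join(bad_rows)
        )
    return [
        ThallusRecord(
            thallus_id=row["thallus_id"],
            forest=row["forest"],
            species=row["species"],
            guild=row["guild"],
            repro_mode=row["repro_mode"],
            phylogroup=row["phylogroup"],
        )
        for _, row in df.iterrows()
    ]


def write_thallus_table(records: list[ThallusRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=THALLUS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_forest_table(path: str | Path) -> list[ForestMeta]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(FOREST_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"forest table missing columns: {sorted(missing)}")
    return [
        ForestMeta(**{k: (str(row[k]) if k == "forest" else float(row[k]))
                      for k in FOREST_COLUMNS})
        for _, row in df.iterrows()
    ]


def write_forest_table(forests: list[ForestMeta], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(f) for f in forests], columns=FOREST_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
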