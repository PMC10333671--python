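"""Core domain containers shared across the pipeline.

A *thallus* is one collected lichen individual: it carries the identity of
the principal fungus (mycobiont species), the forest it was collected in,
whether the lichen is bipartite (cyanolichen: the cyanobacterium is the only
photobiont) or tripartite (cephalolichen: green-algal primary photobiont,
cyanobacteria confined to cephalodia), its observed reproductive mode, and —
after delimitation — the cyanobiont phylogroup its marker sequence belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GUILDS = ("cyanolichen", "cephalolichen")
REPRO_MODES = ("sexual", "asexual", "both", "none")

ALPHABET = frozenset("ACGTN-")
#: unambiguous nucleotide states used in distance computation
BASES = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for ragged or otherwise invalid alignments."""


class MetadataError(ValueError):
    """Raised when sequence headers lack required forest/species tags."""


class ValidationError(ValueError):
    """Raised for invalid tabular records (bad guild/mode tokens, ...)."""


@dataclass(frozen=True)
class ThallusRecord:
    """One collected lichen thallus (= one interaction event)."""

    thallus_id: str
    forest: str
    species: str
    guild: str
    repro_mode: str
    phylogroup: str = ""

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValidationError(
                f"unknown guild {self.guild!r} for thallus {self.thallus_id!r}; "
                f"expected one of {GUILDS}"
            )
        if self.repro_mode not in REPRO_MODES:
            raise ValidationError(
                f"unknown reproductive mode {self.repro_mode!r} for thallus "
                f"{self.thallus_id!r}; expected one of {REPRO_MODES}"
            )


@dataclass
class AlignedSequenceSet:
    """Equal-length aligned marker sequences with per-sequence metadata.

    ``metadata[id]`` is a dict with at least ``forest`` and ``species`` keys.
    """

    ids: list[str]
    sequences: list[str]
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if self.sequences:
            length = len(self.sequences[0])
            for sid, seq in zip(self.ids, self.sequences):
                if len(seq) != length:
                    raise AlignmentError(
                        f"ragged alignment: {sid!r} has length {len(seq)}, "
                        f"expected {length}"
                    )
                bad = set(seq) - ALPHABET
                if bad:
                    raise AlignmentError(
                        f"sequence {sid!r} contains invalid symbols {sorted(bad)}"
                    )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass(frozen=True)
class ForestMeta:
    """Stand-level covariates for one forest."""

    forest: str
    latitude: float
    longitude: float
    elevation: float
    slope: float
    orientation: float
    canopy_openness: float
    dbh: float
    bio01: float
    bio06: float
    bio14: float
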