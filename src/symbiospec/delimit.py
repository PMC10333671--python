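"""Phylogroup delimitation from aligned marker sequences.

Cyanobiont phylogroups are operational taxa delimited from pairwise
Jukes-Cantor (JC69) distances: a clustering threshold is chosen inside a
biologically motivated band (default 0.001-0.01 substitutions/site) at the
widest "barcode gap" — the largest jump between consecutive observed distance
values — and sequences are grouped by single-linkage (connected components of
the graph joining pairs at or below the threshold).

JC69 corrects the raw mismatch proportion p for multiple hits:
``d = -(3/4) ln(1 - (4/3) p)``.  Sites where either sequence has an ambiguous
state (N) or a gap are excluded pairwise.  Pairs with p >= 3/4 are saturated
(the correction diverges) and are flagged and excluded from clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import AlignedSequenceSet

__all__ = [
    "DistanceMatrix",
    "PhylogroupPartition",
    "jc69_distance",
    "pairwise_distance_matrix",
    "select_threshold",
    "delimit_phylogroups",
]

SATURATION_P = 0.75


class IncomparablePairError(ValueError):
    """Raised when two sequences share no comparable (unambiguous) site."""


@dataclass
class DistanceMatrix:
    """Symmetric JC69 distance matrix with per-pair comparable-site counts.

    Saturated pairs carry ``np.inf`` in ``distances`` and True in
    ``saturated``.
    """

    ids: list[str]
    distances: np.ndarray
    comparable_sites: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.distances.shape == (n, n)
        assert np.allclose(np.diag(self.distances), 0.0)

    @property
    def finite_values(self) -> np.ndarray:
        """Sorted distinct finite off-diagonal distances."""
        iu = np.triu_indices(len(self.ids), k=1)
        vals = self.distances[iu]
        return np.unique(vals[np.isfinite(vals)])


@dataclass
class PhylogroupPartition:
    """Mapping id -> phylogroup label; labels "1".."K" by decreasing size."""

    assignments: dict[str, str]
    threshold: float
    linkage: str = "single"

    @property
    def n_groups(self) -> int:
        return len(set(self.assignments.values()))

    def as_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sid, label in self.assignments.items():
            out.setdefault(label, set()).add(sid)
        return out


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return arr


_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True


def jc69_distance(seq_a: str, seq_b: str) -> tuple[float, int, bool]:
    """JC69 distance between two aligned sequences.

    Returns ``(distance, n_comparable_sites, saturated)``.  Saturated pairs
    (p >= 3/4) get ``inf`` distance.  Raises if the sequences differ in length
    or share no comparable site.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a, b = _encode(seq_a), _encode(seq_b)
    comparable = _VALID[a] & _VALID[b]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise IncomparablePairError("no comparable sites between the pair")
    p = float(np.count_nonzero((a != b) & comparable)) / n_comp
    if p >= SATURATION_P:
        return float("inf"), n_comp, True
    d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    return float(d), n_comp, False


def pairwise_distance_matrix(aln: AlignedSequenceSet) -> DistanceMatrix:
    """All-pairs JC69 distances for an aligned set."""
    n = len(aln)
    enc = np.vstack([_encode(s) for s in aln.sequences]) if n else np.empty((0, 0))
    valid = _VALID[enc] if n else np.empty((0, 0), dtype=bool)
    dist = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    sat = np.zeros((n, n), dtype=bool)
    if n:
        np.fill_diagonal(comp, valid.sum(axis=1))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1:]
        n_comp = both.sum(axis=1)
        if np.any(n_comp == 0):
            j = i + 1 + int(np.argmax(n_comp == 0))
            raise IncomparablePairError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        mism = ((enc[i] != enc[i + 1:]) & both).sum(axis=1)
        p = mism / n_comp
        is_sat = p >= SATURATION_P
        with np.errstate(invalid="ignore"):
            d = np.where(is_sat, np.inf, -0.75 * np.log1p(-(4.0 / 3.0) * np.minimum(p, SATURATION_P - 1e-12)))
        dist[i, i + 1:] = dist[i + 1:, i] = d
        comp[i, i + 1:] = comp[i + 1:, i] = n_comp
        sat[i, i + 1:] = sat[i + 1:, i] = is_sat
    n_sat = int(sat[np.triu_indices(n, 1)].sum()) if n else 0
    if n_sat:
        warnings.warn(
            f"{n_sat} saturated pairs (p >= {SATURATION_P}) excluded from "
            "clustering",
            stacklevel=2,
        )
    return DistanceMatrix(
        ids=list(aln.ids), distances=dist, comparable_sites=comp, saturated=sat
    )


def select_threshold(
    matrix: DistanceMatrix, band: tuple[float, float] = (0.001, 0.01)
) -> float:
    """Pick the clustering threshold at the widest barcode gap inside the band.

    Candidates are all distinct observed distances inside ``band`` plus the
    band endpoints; each is scored by the gap to the next-larger observed
    distance, and the largest gap wins (ties -> smaller threshold).  If no
    observed distance falls in the band, the band midpoint is returned with a
    warning.
    """
    lo, hi = band
    if not (0.0 < lo < hi < SATURATION_P):
        raise ValueError(f"band must satisfy 0 < lo < hi < {SATURATION_P}")
    values = matrix.finite_values
    values = values[values > 0]
    inside = values[(values >= lo) & (values <= hi)]
    if inside.size == 0:
        warnings.warn(
            f"no pairwise distances inside band [{lo}, {hi}]; "
            "falling back to the band midpoint",
            stacklevel=2,
        )
        return (lo + hi) / 2.0
    candidates = np.unique(np.concatenate([inside, [lo, hi]]))
    best_t, best_gap = None, -1.0
    for t in candidates:
        larger = values[values > t]
        gap = float(larger.min() - t) if larger.size else 0.0
        if gap > best_gap + 1e-15:
            best_t, best_gap = float(t), gap
    return best_t


def delimit_phylogroups(
    matrix: DistanceMatrix, threshold: float
) -> PhylogroupPartition:
    """Single-linkage clustering: connected components at ``d <= threshold``.

    Saturated pairs never join clusters.  Labels are "1".."K" in decreasing
    cluster size, ties broken by first occurrence in the input order.
    """
    n = len(matrix.ids)
    adj = np.isfinite(matrix.distances) & (matrix.distances <= threshold)
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    # order components by (-size, first index)
    order = sorted(
        np.unique(comp),
        key=lambda c: (-int(np.sum(comp == c)), int(np.argmax(comp == c))),
    )
    relabel = {c: str(rank + 1) for rank, c in enumerate(order)}
    assignments = {sid: relabel[c] for sid, c in zip(matrix.ids, comp)}
    return PhylogroupPartition(assignments=assignments, threshold=float(threshold))
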