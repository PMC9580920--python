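"""Atom-pair distance statistics for statistical-potential construction.

Distances d = |rᵃᵢ − rᵇⱼ| are computed between heavy atoms of the
85-type scheme sitting in *different* nucleotides, excluding the single
covalent O3'(i)–P(i+1) backbone linkage, each unordered pair once.
Distances are binned per unordered atom-type pair into half-open bins
[lo, hi) of configurable width (default 0.1 Å) up to ``d_max``
(default 100 Å); distances beyond ``d_max`` are dropped with a logged
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .structure_model import ATOM_TYPE_TABLE, Structure, atom_type_of

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceHistogram", "pairwise_distances", "distance_histogram",
    "phosphate_extracts",
]

TypePair = tuple[tuple[str, str], tuple[str, str]]


class UnknownAtomTypeError(ValueError):
    pass


@dataclass
class DistanceHistogram:
    type_pair: Optional[TypePair]   # None for the pooled histogram
    bin_width: float
    d_max: float
    counts: np.ndarray              # integer counts, len = d_max / bin_width

    @property
    def edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.bin_width

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def modal_bin(self) -> tuple[float, float]:
        k = int(np.argmax(self.counts))
        return k * self.bin_width, (k + 1) * self.bin_width


def _normalise_pair(a: tuple[str, str], b: tuple[str, str]) -> TypePair:
    return (a, b) if a <= b else (b, a)


def _typed_atoms(structure: Structure):
    """(coords, residue index, type) for every typed heavy atom."""
    coords, res_idx, types = [], [], []
    for res in structure.residues:
        for atom in res.atoms:
            t = atom_type_of(res.base, atom.name)
            if t is None:
                continue
            coords.append(atom.pos)
            res_idx.append(res.index)
            types.append(t)
    return (np.array(coords, dtype=float).reshape(-1, 3),
            np.array(res_idx, dtype=int), types)


def pairwise_distances(structure: Structure,
                       selection: Optional[TypePair] = None,
                       ) -> Iterator[tuple[TypePair, float]]:
    """Yield (type-pair, distance) for qualifying atom pairs.

    ``selection`` restricts output to one unordered atom-type pair, e.g.
    ``(("A","P"), ("G","P"))``; ``None`` emits every pair.  Pairs within
    one residue and the bonded O3'–P linkage are excluded; each unordered
    pair is emitted once.
    """
    if selection is not None:
        for t in selection:
            if tuple(t) not in ATOM_TYPE_TABLE:
                valid = ", ".join(sorted(f"{b}.{n}" for b, n in ATOM_TYPE_TABLE))
                raise UnknownAtomTypeError(
                    f"unknown atom type {t!r}; valid types are: {valid}")
        selection = _normalise_pair(tuple(selection[0]), tuple(selection[1]))

    coords, res_idx, types = _typed_atoms(structure)
    n = coords.shape[0]
    residues = structure.residues
    bonded: set[tuple[int, int]] = set()
    # map (residue, atom name) -> flat atom index for the O3'-P exclusion
    flat: dict[tuple[int, str], int] = {}
    k = 0
    for res in residues:
        for atom in res.atoms:
            if atom_type_of(res.base, atom.name) is not None:
                flat[(res.index, atom.name)] = k
                k += 1
    for i in range(len(residues) - 1):
        if structure.connected(i, i + 1):
            a = flat.get((i, "O3'"))
            b = flat.get((i + 1, "P"))
            if a is not None and b is not None:
                bonded.add((min(a, b), max(a, b)))

    for a in range(n - 1):
        d = np.linalg.norm(coords[a + 1:] - coords[a], axis=1)
        for off, dist in enumerate(d):
            b = a + 1 + off
            if res_idx[a] == res_idx[b]:
                continue
            if (a, b) in bonded:
                continue
            tp = _normalise_pair(types[a], types[b])
            if selection is not None and tp != selection:
                continue
            yield tp, float(dist)


def distance_histogram(stream: Iterable[tuple[TypePair, float]],
                       bin_width: float = 0.1,
                       d_max: float = 100.0,
                       ) -> dict[Optional[TypePair], DistanceHistogram]:
    """Bin a distance stream per type pair; key ``None`` pools everything.

    Bins are half-open [lo, hi); counts over all per-type histograms are
    conserved (distances ≥ d_max are dropped and logged).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nbins = int(np.ceil(d_max / bin_width))
    hists: dict[Optional[TypePair], np.ndarray] = {None: np.zeros(nbins, dtype=np.int64)}
    dropped = 0
    for tp, dist in stream:
        k = int(dist / bin_width)
        if k >= nbins or dist < 0:
            dropped += 1
            continue
        hists[None][k] += 1
        h = hists.get(tp)
        if h is None:
            h = hists[tp] = np.zeros(nbins, dtype=np.int64)
        h[k] += 1
    if dropped:
        logger.info("distance_histogram: dropped %d distances ≥ %.1f Å", dropped, d_max)
    return {tp: DistanceHistogram(tp, bin_width, d_max, counts)
            for tp, counts in hists.items()}


def phosphate_extracts(structure: Structure,
                       pairs: Iterable = ()) -> dict[str, list[float]]:
    """Named P–P distance extracts.

    Returns nearest-neighbour (i, i+1), second-neighbour (i, i+2) and
    paired-nucleotide P–P distances (the latter from a base-pair list),
    the three features that dominate the pooled P–P distribution.
    """
    residues = structure.residues
    p_pos = {r.index: r.atom("P").pos for r in residues if r.atom("P") is not None}

    def dist(i: int, j: int) -> Optional[float]:
        if i in p_pos and j in p_pos:
            return float(np.linalg.norm(p_pos[i] - p_pos[j]))
        return None

    out: dict[str, list[float]] = {"nearest": [], "second": [], "paired": []}
    for i in range(len(residues) - 1):
        if residues[i].chain_id == residues[i + 1].chain_id:
            d = dist(i, i + 1)
            if d is not None:
                out["nearest"].append(d)
    for i in range(len(residues) - 2):
        if residues[i].chain_id == residues[i + 2].chain_id:
            d = dist(i, i + 2)
            if d is not None:
                out["second"].append(d)
    for p in pairs:
        d = dist(p.i, p.j)
        if d is not None:
            out["paired"].append(d)
    return out
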