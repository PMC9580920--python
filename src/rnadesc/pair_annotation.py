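"""Base-pair and base-stack annotation.

Two interchangeable sources are supported:

* a built-in geometric detector (hydrogen-bond-distance + base-plane
  criteria in the base-local frames of :mod:`rnadesc.base_geometry`) —
  self-contained, thresholds configurable, deliberately simpler than a
  full annotation program;
* ingestion of DSSR-dialect JSON, preserving Leontis–Westhof labels
  verbatim.

A pair is *canonical* iff its unordered base set is one of
{C,G}, {A,U}, {G,U} **and** both partners interact through their
Watson–Crick edges.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .base_geometry import (
    BaseFrame,
    CylCoord,
    IncompleteBaseError,
    build_base_frame,
    edge_sector_of,
    relative_cylindrical,
)
from .structure_model import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "BasePair", "StackPair", "DetectionParams",
    "detect_base_pairs", "detect_stacking",
    "ingest_dssr_json", "export_annotations", "IngestionError",
    "is_canonical", "base_frames",
]

CANONICAL_SETS = (frozenset("CG"), frozenset("AU"), frozenset("GU"))

#: Base-atom hydrogen-bond donors / acceptors (heavy atoms only).
HB_DONORS = {"A": ("N6",), "C": ("N4",), "G": ("N1", "N2"), "U": ("N3",)}
HB_ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "C": ("N3", "O2"),
    "G": ("O6", "N3", "N7"),
    "U": ("O2", "O4"),
}


@dataclass(frozen=True)
class DetectionParams:
    """Geometric thresholds; standard structural-biology heuristics, all in Å/degrees."""
    hb_dist: float = 3.4          # max donor–acceptor heavy-atom distance
    hb_min: int = 2               # min number of such contacts per pair
    plane_max: float = 65.0       # max inter-base-plane angle for pairing
    z_pair_max: float = 2.5       # max |z| offset for pairing, each frame
    z_stack_min: float = 2.5      # stacking band, |z|
    z_stack_max: float = 4.5
    rho_stack_max: float = 5.0    # max in-plane offset for stacking
    stack_plane_max: float = 30.0
    neighbor_cutoff: float = 12.0  # candidate origin-distance prefilter


@dataclass(frozen=True)
class BasePair:
    i: int
    j: int
    bases: tuple[str, str]
    canonical: bool
    edges: tuple[str, str]          # sector of j seen from i, and vice versa
    source: str                     # "builtin" | "dssr"
    geometry: Optional[CylCoord]    # j's origin in i's frame
    lw_label: Optional[str] = None  # e.g. "cWW"; DSSR source only
    n_hbonds: int = 0


@dataclass(frozen=True)
class StackPair:
    i: int
    j: int
    geometry: Optional[CylCoord]
    source: str
    adjacent: bool = False          # sequence neighbours on a continuous backbone


class IngestionError(ValueError):
    """Malformed or incomplete DSSR JSON."""


def is_canonical(base_i: str, base_j: str, edge_i: str, edge_j: str) -> bool:
    """Canonical ⟺ bases ∈ {{C,G},{A,U},{G,U}} and both edges Watson–Crick."""
    return (frozenset((base_i, base_j)) in CANONICAL_SETS
            and edge_i == "WC" and edge_j == "WC")


def base_frames(structure: Structure) -> dict[int, BaseFrame]:
    """Frames for every residue whose base is complete; incomplete ones are skipped."""
    frames: dict[int, BaseFrame] = {}
    for res in structure.residues:
        try:
            frames[res.index] = build_base_frame(res)
        except IncompleteBaseError as exc:
            logger.info("skipping residue: %s", exc)
    return frames


def _hb_contacts(res_i, res_j, hb_dist: float) -> int:
    """Donor–acceptor heavy-atom contacts between the two bases."""
    n = 0
    for donors, acceptors, a, b in (
        (HB_DONORS[res_i.base], HB_ACCEPTORS[res_j.base], res_i, res_j),
        (HB_DONORS[res_j.base], HB_ACCEPTORS[res_i.base], res_j, res_i),
    ):
        for dn in donors:
            da = a.atom(dn)
            if da is None:
                continue
            for ac in acceptors:
                aa = b.atom(ac)
                if aa is None:
                    continue
                if float(np.linalg.norm(da.pos - aa.pos)) < hb_dist:
                    n += 1
    return n


def _plane_angle(fi: BaseFrame, fj: BaseFrame) -> float:
    """Angle between base normals, folded to [0°, 90°]."""
    c = abs(float(np.dot(fi.z, fj.z)))
    return math.degrees(math.acos(min(c, 1.0)))


def _candidates(frames: dict[int, BaseFrame], cutoff: float):
    idx = sorted(frames)
    if len(idx) < 2:
        return
    origins = np.array([frames[k].origin for k in idx])
    tree = cKDTree(origins)
    for a, b in sorted(tree.query_pairs(cutoff)):
        yield idx[min(a, b)], idx[max(a, b)]


def detect_base_pairs(structure: Structure,
                      params: DetectionParams | None = None) -> list[BasePair]:
    """Geometric base-pair detection.

    A candidate (i, j) is accepted iff it has ≥ ``hb_min`` donor–acceptor
    base-atom contacts under ``hb_dist``, an inter-plane angle below
    ``plane_max``, and |z| < ``z_pair_max`` in *each* partner's frame.
    A residue may belong to several pairs (multiplets are allowed).
    Output is independent of atom ordering and global rigid motion.
    """
    p = params or DetectionParams()
    frames = base_frames(structure)
    residues = structure.residues
    pairs: list[BasePair] = []
    for i, j in _candidates(frames, p.neighbor_cutoff):
        fi, fj = frames[i], frames[j]
        if _plane_angle(fi, fj) >= p.plane_max:
            continue
        g_ij = relative_cylindrical(fi, fj)
        g_ji = relative_cylindrical(fj, fi)
        if abs(g_ij.z) >= p.z_pair_max or abs(g_ji.z) >= p.z_pair_max:
            continue
        nhb = _hb_contacts(residues[i], residues[j], p.hb_dist)
        if nhb < p.hb_min:
            continue
        edges = (edge_sector_of(g_ij.theta), edge_sector_of(g_ji.theta))
        bases = (residues[i].base, residues[j].base)
        pairs.append(BasePair(
            i=i, j=j, bases=bases,
            canonical=is_canonical(*bases, *edges),
            edges=edges, source="builtin", geometry=g_ij, n_hbonds=nhb))
    return pairs


def detect_stacking(structure: Structure,
                    params: DetectionParams | None = None) -> list[StackPair]:
    """Geometric base-stack detection.

    Accepts (i, j) with |z| inside [``z_stack_min``, ``z_stack_max``] and
    ρ ≤ ``rho_stack_max`` in both frames, and near-parallel planes.
    Sequence-adjacent (covalently linked neighbours) and non-adjacent
    stacks are both reported, distinguished by the ``adjacent`` flag.
    """
    p = params or DetectionParams()
    frames = base_frames(structure)
    stacks: list[StackPair] = []
    for i, j in _candidates(frames, p.rho_stack_max + p.z_stack_max + 1.0):
        fi, fj = frames[i], frames[j]
        if _plane_angle(fi, fj) > p.stack_plane_max:
            continue
        g_ij = relative_cylindrical(fi, fj)
        g_ji = relative_cylindrical(fj, fi)
        if not all(p.z_stack_min <= abs(g.z) <= p.z_stack_max for g in (g_ij, g_ji)):
            continue
        if g_ij.rho > p.rho_stack_max or g_ji.rho > p.rho_stack_max:
            continue
        stacks.append(StackPair(
            i=i, j=j, geometry=g_ij, source="builtin",
            adjacent=structure.connected(i, j)))
    return stacks


# ---------------------------------------------------------------------------
# DSSR JSON ingestion

_NT_ID = re.compile(r"^(?:[^:]*:)?(?P<chain>[^.]+)\.(?P<base>[A-Za-z0-9]+?)(?P<num>-?\d+)$")


def _parse_nt_id(nt: str) -> tuple[str, str, int]:
    """Split a DSSR nucleotide id like ``"A.G12"`` into (chain, base, number)."""
    m = _NT_ID.match(nt.strip())
    if not m:
        raise IngestionError(f"cannot parse nucleotide id {nt!r}")
    return m.group("chain"), m.group("base"), int(m.group("num"))


_LW_EDGE = {"W": "WC", "H": "Hoogsteen", "S": "Sugar", "C": "Hoogsteen"}


def _edges_from_lw(lw: Optional[str]) -> tuple[str, str]:
    if lw and len(lw) >= 3:
        e1 = _LW_EDGE.get(lw[1].upper())
        e2 = _LW_EDGE.get(lw[2].upper())
        if e1 and e2:
            return e1, e2
    return "WC", "WC"


def ingest_dssr_json(path: str | Path, structure: Structure | None = None
                     ) -> tuple[list[BasePair], list[StackPair], dict]:
    """Read pairs/stacks/motif blocks from DSSR-dialect JSON.

    LW labels are preserved verbatim; the canonical flag is recomputed
    from the base identities and the LW edge letters.  When ``structure``
    is given, nucleotide ids are mapped onto its residue indices and pair
    geometry is recomputed in the base-local frames; otherwise indices
    follow (chain, number) order of appearance.

    Raises :class:`IngestionError` on malformed JSON or when the
    ``"pairs"`` block is absent.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise IngestionError(f"{path}: malformed JSON: {exc}") from exc
    if "pairs" not in doc:
        raise IngestionError(f"{path}: missing required key 'pairs'")

    index_of: dict[tuple[str, int], int] = {}
    frames: dict[int, BaseFrame] = {}
    if structure is not None:
        index_of = {(r.chain_id, r.seq_id): r.index for r in structure.residues}
        frames = base_frames(structure)

    def resolve(nt: str) -> tuple[int | None, str, tuple[str, int]]:
        chain, base, num = _parse_nt_id(nt)
        base = base if base in "ACGU" else base[-1]
        return index_of.get((chain, num)), base, (chain, num)

    raw: list[tuple] = []
    for rec in doc["pairs"]:
        try:
            nt1, nt2 = rec["nt1"], rec["nt2"]
        except KeyError as exc:
            raise IngestionError(f"{path}: pair record missing {exc}") from exc
        raw.append((resolve(nt1), resolve(nt2), rec.get("LW")))

    # without a structure, order residues by (chain, number) of appearance
    if structure is None:
        keys = sorted({r[2] for a, b, _ in raw for r in (a, b)})
        order = {k: n for n, k in enumerate(keys)}
        raw = [((order[a[2]], a[1], a[2]), (order[b[2]], b[1], b[2]), lw)
               for a, b, lw in raw]

    pairs: list[BasePair] = []
    for (ia, base_a, key_a), (ib, base_b, key_b), lw in raw:
        if ia is None or ib is None:
            logger.warning("DSSR pair %s-%s not in structure; skipped", key_a, key_b)
            continue
        if ia > ib:
            ia, ib, base_a, base_b = ib, ia, base_b, base_a
            if lw and len(lw) >= 3:
                lw = lw[0] + lw[2] + lw[1]
        geometry = None
        if ia in frames and ib in frames:
            geometry = relative_cylindrical(frames[ia], frames[ib])
            edges = (edge_sector_of(geometry.theta),
                     edge_sector_of(relative_cylindrical(frames[ib], frames[ia]).theta))
        else:
            edges = _edges_from_lw(lw)
        pairs.append(BasePair(
            i=ia, j=ib, bases=(base_a, base_b),
            canonical=is_canonical(base_a, base_b, *edges),
            edges=edges, source="dssr", geometry=geometry, lw_label=lw))

    stacks: list[StackPair] = []
    for rec in doc.get("stacks", []):
        nts = rec.get("nts", "")
        members = [s for s in nts.split(",") if s.strip()]
        resolved = [resolve(m) for m in members]
        if structure is None:
            continue
        for (ia, _, _), (ib, _, _) in zip(resolved, resolved[1:]):
            if ia is None or ib is None:
                continue
            i, j = min(ia, ib), max(ia, ib)
            geometry = (relative_cylindrical(frames[i], frames[j])
                        if i in frames and j in frames else None)
            stacks.append(StackPair(i=i, j=j, geometry=geometry, source="dssr",
                                    adjacent=structure.connected(i, j)))

    motifs = {k: doc[k] for k in
              ("stems", "hairpins", "bulges", "iloops", "junctions") if k in doc}
    return pairs, stacks, motifs


def export_annotations(structure: Structure, pairs: list[BasePair],
                       stacks: list[StackPair], path: str | Path) -> None:
    """Write annotations as DSSR-dialect JSON (round-trips through ingestion)."""
    residues = structure.residues

    def nt_id(idx: int) -> str:
        r = residues[idx]
        return f"{r.chain_id}.{r.base}{r.seq_id}"

    doc = {
        "pairs": [
            {"nt1": nt_id(p.i), "nt2": nt_id(p.j),
             "bp": f"{p.bases[0]}-{p.bases[1]}",
             **({"LW": p.lw_label} if p.lw_label else {})}
            for p in pairs
        ],
        "stacks": [
            {"nts": f"{nt_id(s.i)},{nt_id(s.j)}"} for s in stacks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def reconcile(dssr_pairs: list[BasePair],
              builtin_pairs: list[BasePair]) -> dict[str, list[tuple[int, int]]]:
    """Compare the two pair sources; DSSR wins, disagreements are reported."""
    d = {(p.i, p.j) for p in dssr_pairs}
    b = {(p.i, p.j) for p in builtin_pairs}
    return {"dssr_only": sorted(d - b), "builtin_only": sorted(b - d),
            "agree": sorted(d & b)}
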