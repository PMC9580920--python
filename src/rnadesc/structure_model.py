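"""Coordinate model for RNA 3D structures.

Reads mmCIF / legacy PDB files into a light hierarchical model
(:class:`Structure` → :class:`Chain` → :class:`Residue` → :class:`Atom`)
restricted to the four standard ribonucleotides and their heavy atoms,
and defines the 85-entry heavy-atom-type scheme used throughout the
package (12 shared backbone/ribose names per base plus the base-specific
ring and exocyclic atoms: A=22, C=20, G=23, U=20).

Terminal OP3 phosphate oxygens are retained in the coordinate model but
carry no atom type, keeping the type table at exactly 85 entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")

#: Sugar-phosphate heavy atoms common to all four nucleotides (OP3 excluded).
BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
    "C3'", "O3'", "C2'", "O2'", "C1'",
)

#: Base (ring + exocyclic) heavy atoms per nucleotide.
BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

#: The 85 heavy-atom types: (base, atom name) pairs.
ATOM_TYPE_TABLE = frozenset(
    (base, name)
    for base in RNA_BASES
    for name in BACKBONE_ATOMS + BASE_ATOMS[base]
)

HEAVY_ELEMENTS = frozenset({"C", "N", "O", "P"})

#: Common modified nucleotides mapped to their parent base (opt-in).
MODIFIED_PARENT = {
    "PSU": "U", "H2U": "U", "4SU": "U", "5MU": "U", "UR3": "U", "OMU": "U",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "1MA": "A", "A2M": "A", "MIA": "A", "2MA": "A",
    "2MG": "G", "7MG": "G", "M2G": "G", "1MG": "G", "OMG": "G", "G7M": "G",
}

#: O3'(i)–P(i+1) distance above which the backbone is considered broken (Å).
CHAIN_BREAK_CUTOFF = 2.5


def atom_type_of(base: str, atom_name: str) -> Optional[tuple[str, str]]:
    """Return the (base, atom-name) heavy-atom type, or ``None``.

    Total function: hydrogens, OP3, and atoms of non-standard residues
    map to ``None`` rather than raising.
    """
    key = (base, atom_name)
    return key if key in ATOM_TYPE_TABLE else None


class StructureError(Exception):
    """Raised for unparseable files or structures with no usable RNA."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    base: str
    atoms: list[Atom] = field(default_factory=list)
    #: 0-based sequential index over the whole structure; set by Structure.
    index: int = -1

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def base_atoms(self) -> list[Atom]:
        names = set(BASE_ATOMS[self.base])
        return [a for a in self.atoms if a.name in names]

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        i = 0
        for ch in self.chains:
            for res in ch.residues:
                res.index = i
                res.chain_id = ch.id
                i += 1

    @property
    def residues(self) -> list[Residue]:
        return [r for ch in self.chains for r in ch.residues]

    @property
    def length(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)

    def coords(self) -> np.ndarray:
        """Positions of all heavy atoms, pooled over chains, shape (N, 3)."""
        rows = [a.pos for r in self.residues for a in r.atoms]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def chain_of(self, index: int) -> str:
        return self.residues[index].chain_id

    def connected(self, i: int, j: int) -> bool:
        """True if residues i and j=i+1 are covalently linked O3'(i)–P(j)."""
        if j != i + 1:
            return False
        res = self.residues
        if res[i].chain_id != res[j].chain_id:
            return False
        o3 = res[i].atom("O3'")
        p = res[j].atom("P")
        if o3 is None or p is None:
            return False
        return float(np.linalg.norm(o3.pos - p.pos)) <= CHAIN_BREAK_CUTOFF


def _select_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occ, -ord(a.altloc or "z")) > (prev.occ, -ord(prev.altloc or "z")):
            by_name[a.name] = a
    return list(by_name.values())


def read_structure(
    path: str | Path,
    format: str = "auto",
    map_modified: bool = False,
) -> Structure:
    """Read an mmCIF or PDB file into a heavy-atom RNA :class:`Structure`.

    Only standard ribonucleotides (A, C, G, U) and heavy atoms (C, N, O, P)
    are retained; waters, ions, ligands, protein/DNA chains and hydrogens
    are dropped and logged.  Multi-model (NMR) files contribute model 1
    only.  With ``map_modified=True``, residues listed in
    :data:`MODIFIED_PARENT` are renamed to their parent base (extra atoms
    not in the 85-type scheme simply carry no type).

    Raises :class:`StructureError` on unparseable input or when no RNA
    residues survive filtering.
    """
    path = Path(path)
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use auto, mmcif or pdb")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    if len(st) > 1:
        logger.info("%s: %d models; using model 1 only", path.name, len(st))
    model = st[0]

    chains: list[Chain] = []
    dropped_residues: dict[str, int] = {}
    dropped_h = 0
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip()
            base = None
            if name in RNA_BASES:
                base = name
            elif map_modified and name in MODIFIED_PARENT:
                base = MODIFIED_PARENT[name]
            if base is None:
                dropped_residues[name] = dropped_residues.get(name, 0) + 1
                continue
            atoms: list[Atom] = []
            for gatom in _select_altloc(list(gres)):
                el = gatom.element.name.upper()
                if el not in HEAVY_ELEMENTS:
                    dropped_h += 1
                    continue
                atoms.append(Atom(gatom.name, el, np.array(
                    [gatom.pos.x, gatom.pos.y, gatom.pos.z])))
            if atoms:
                residues.append(Residue(gchain.name, gres.seqid.num, base, atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))

    if dropped_residues:
        logger.info("%s: dropped non-RNA components: %s", path.name,
                    ", ".join(f"{k}×{v}" for k, v in sorted(dropped_residues.items())))
    if dropped_h:
        logger.debug("%s: dropped %d non-heavy atoms", path.name, dropped_h)

    if not chains:
        raise StructureError(f"{path}: no standard RNA residues after filtering")
    return Structure(id=path.stem, chains=chains)


def write_mmcif(structure: Structure, path: str | Path) -> None:
    """Write the model as a minimal valid mmCIF file (atom_site loop)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for ch in structure.chains:
        gchain = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.base
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(Path(path)))
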