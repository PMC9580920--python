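from __future__ import annotations

import numpy as np
import pytest

from rnadesc import fixtures as fx


@pytest.fixture(scope="session")
def gc_duplex():
    """8-bp mixed-sequence duplex with its ground truth."""
    return fx.make_duplex(fx.HelixSpec("GCAUGCGC"))


@pytest.fixture(scope="session")
def wobble_duplex():
    """Duplex containing one G·U wobble (strand-I position 2)."""
    return fx.make_duplex(fx.HelixSpec("GCGAGC", wobble_sites=(2,)))


@pytest.fixture(scope="session")
def hairpin_3_4():
    return fx.make_hairpin(3, 4, seed=11)


def random_coil(n: int, seed: int, spacing: float = 20.0):
    """Single strand with bases far apart: no close base contacts.

    Nucleotides are strung along a seeded self-avoiding random walk whose
    anchor separation (≥ spacing, default 20 Å) exceeds the base extent
    plus every detector reach, so no two bases can pair or stack.
    """
    import rnadesc.fixtures as fxm
    from rnadesc.structure_model import Chain, Structure

    rng = np.random.default_rng(seed)
    anchors = [np.zeros(3)]
    while len(anchors) < n:
        step = rng.normal(size=3)
        cand = anchors[-1] + spacing * step / np.linalg.norm(step)
        if all(np.linalg.norm(cand - a) >= spacing for a in anchors):
            anchors.append(cand)
    residues = []
    for k, pos in enumerate(anchors):
        base = "ACGU"[k % 4]
        tmpl = fxm._template_atoms(base, 32.7, 2.81)
        rot, _ = fxm.random_rotation(int(rng.integers(0, 2**31 - 1)))
        atoms = [(a, rot @ p + pos) for a, p in tmpl]
        residues.append(fxm._residue("A", k + 1, base, atoms))
    return Structure(id=f"coil_{n}", chains=[Chain("A", residues)])


# -- minimal hand-written PDB with noise components -------------------------

def _pdb_atom(serial, name, resname, chain, resseq, xyz, element, altloc=" ",
              occ=1.0, record="ATOM"):
    x, y, z = xyz
    aname = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {aname}{altloc}{resname:>3s} {chain:1s}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


@pytest.fixture()
def mixed_pdb(tmp_path):
    """Two-model PDB: one RNA G (with hydrogens + altlocs), one ALA, one water."""
    lines = ["MODEL     1"]
    serial = 1
    g_atoms = [("P", "P", (0, 0, 0)), ("C1'", "C", (1, 1, 0)),
               ("N9", "N", (2, 0, 0)), ("H1", "H", (9, 9, 9))]
    for name, el, xyz in g_atoms:
        lines.append(_pdb_atom(serial, name, "G", "A", 1, xyz, el))
        serial += 1
    # altloc pair on O2': B has the higher occupancy and must win
    lines.append(_pdb_atom(serial, "O2'", "G", "A", 1, (3, 0, 0), "O", "A", 0.4))
    serial += 1
    lines.append(_pdb_atom(serial, "O2'", "G", "A", 1, (4, 0, 0), "O", "B", 0.6))
    serial += 1
    lines.append(_pdb_atom(serial, "CA", "ALA", "B", 1, (8, 8, 8), "C"))
    serial += 1
    lines.append(_pdb_atom(serial, "O", "HOH", "C", 1, (5, 5, 5), "O",
                           record="HETATM"))
    lines += ["ENDMDL", "MODEL     2"]
    lines.append(_pdb_atom(serial + 1, "P", "G", "A", 1, (50, 50, 50), "P"))
    lines += ["ENDMDL", "END"]
    p = tmp_path / "mixed.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p
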