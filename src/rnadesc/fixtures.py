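"""Synthetic structures and point sets with machine-readable ground truth.

Everything here is a *geometric oracle*, not a physical simulation: the
generated coordinates are idealised (standard planar nucleobase
geometries on a uniform twist/rise helix, loop nucleotides fanned out on
a wide arc) so that the intended annotation — pair list, stack list,
secondary structure — is known exactly by construction and detectors can
be tested without downloads.

The per-base heavy-atom template coordinates are standard nucleobase
geometries in the base reference-frame convention (x–y base plane,
glycosidic C1' included); the sugar-phosphate positions are a synthetic
idealisation chosen so that an assembled duplex has A-form-like
phosphate spacing (nearest-neighbour P–P ≈ 5.9 Å, cross-strand paired
P–P ≈ 18.4 Å) and a covalently continuous O3'–P backbone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .motif_decomposition import SecondaryStructure, Stem, Loop, dot_bracket
from .structure_model import Atom, Chain, Residue, Structure, write_mmcif

__all__ = [
    "HelixSpec", "PointCloud", "DuplexTruth",
    "make_point_cloud", "make_duplex", "make_hairpin",
    "apply_rigid", "random_rotation", "write_fixture",
    "STD_BASE_COORDS", "SUGAR_PHOSPHATE_TEMPLATE",
]

#: Standard nucleobase heavy-atom coordinates (Å) in the base reference
#: frame (base in the z=0 plane, WC edge toward −y/−x), including C1'.
STD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000), "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000), "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000), "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000), "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000), "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000), "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000), "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000), "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000), "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001), "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000), "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001), "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000), "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000), "C6": (-0.023, 5.068, 0.000),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000), "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000), "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000), "O4": (1.935, 2.094, -0.001),
        "C5": (1.089, 4.311, 0.000), "C6": (-0.024, 5.053, 0.000),
    },
}

#: Synthetic sugar-phosphate positions in the same pair frame (strand I).
#: P sits at helix radius ≈ 9.3 Å so neighbour / paired P–P distances come
#: out A-form-like; O3' is recomputed per helix geometry for continuity.
SUGAR_PHOSPHATE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "P": (-1.70, 8.90, -2.30), "OP1": (-0.80, 9.90, -2.80),
    "OP2": (-1.10, 7.70, -2.90), "O5'": (-2.60, 8.50, -1.40),
    "C5'": (-3.90, 7.90, -0.90), "C4'": (-4.50, 6.90, -0.30),
    "O4'": (-3.30, 6.10, 0.60), "C3'": (-4.40, 6.20, -1.70),
    "C2'": (-3.60, 5.60, -1.00), "O2'": (-3.80, 4.30, -1.50),
}

#: Displacement of the helix axis from the pair-frame origin (Å), giving
#: an A-form-like deep major groove.
AXIS_X = -4.40

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
WOBBLE_COMPLEMENT = {"G": "U", "U": "G"}

#: Target donor–acceptor distance used to place wobble partners (Å).
WOBBLE_HB = 2.85


@dataclass(frozen=True)
class HelixSpec:
    """Ideal regular duplex: sequence of strand I plus twist/rise per step.

    Defaults follow the A-form convention (32.7°/bp twist, 2.81 Å/bp
    rise — a documented generator constant).  ``wobble_sites`` lists
    strand-I positions (0-based) paired as G·U wobbles instead of WC.
    """
    sequence: str
    twist: float = 32.7   # degrees per base-pair step
    rise: float = 2.81    # Å per base-pair step
    wobble_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence or any(b not in "ACGU" for b in self.sequence):
            raise ValueError(f"invalid sequence {self.sequence!r}")
        if self.twist <= 0 or self.rise <= 0:
            raise ValueError("twist and rise must be positive")
        for k in self.wobble_sites:
            if self.sequence[k] not in WOBBLE_COMPLEMENT:
                raise ValueError(f"position {k} ({self.sequence[k]}) cannot form a wobble")


@dataclass
class PointCloud:
    kind: str
    coords: np.ndarray


@dataclass
class DuplexTruth:
    """Intended annotation of a generated duplex."""
    pairs: list[tuple[int, int]]
    stacks: list[tuple[int, int]]          # sequence-adjacent intra-strand
    canonical: list[bool] = field(default_factory=list)


def make_point_cloud(kind: str, n: int = 50, seed: int = 0) -> PointCloud:
    """Geometric point sets with known shape descriptors.

    ``rod`` → exactly collinear (Δ=1, S=2); ``disc`` → coplanar isotropic
    ring (Δ=1/4, S=−1/4); ``sphere_octahedron`` → equal principal moments
    (Δ=S=0); ``uniform_random`` → seeded uniform cube.
    """
    if kind == "sphere_octahedron":
        a = 1.0
        pts = np.array([[a, 0, 0], [-a, 0, 0], [0, a, 0],
                        [0, -a, 0], [0, 0, a], [0, 0, -a]], dtype=float)
    elif kind == "rod":
        if n < 2:
            raise ValueError("rod needs n ≥ 2")
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n, dtype=float)
    elif kind == "disc":
        if n < 3:
            raise ValueError("disc needs n ≥ 3")
        ang = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
    elif kind == "uniform_random":
        if n < 2:
            raise ValueError("uniform_random needs n ≥ 2")
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1.0, 1.0, size=(n, 3))
    else:
        raise ValueError(f"unknown point-cloud kind {kind!r}")
    return PointCloud(kind=kind, coords=pts)


def _rz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP = np.diag([1.0, -1.0, -1.0])  # strand-II bases: rotate 180° about x


def _wobble_shift(strand1_base: str) -> np.ndarray:
    """In-plane translation of the flipped strand-II partner making a G·U wobble.

    Solves the two-circle intersection putting the wobble hydrogen bonds
    G:O6–U:N3 and G:N1–U:O2 (donor–acceptor heavy atoms) at
    :data:`WOBBLE_HB`; of the two solutions the smaller shift is taken.
    """
    g = {k: np.array(v) for k, v in STD_BASE_COORDS["G"].items()}
    u = {k: np.array(v) for k, v in STD_BASE_COORDS["U"].items()}
    if strand1_base == "G":      # U on strand II is shifted
        c1 = (g["O6"] - _FLIP @ u["N3"])[:2]
        c2 = (g["N1"] - _FLIP @ u["O2"])[:2]
    elif strand1_base == "U":    # G on strand II is shifted
        c1 = (u["N3"] - _FLIP @ g["O6"])[:2]
        c2 = (u["O2"] - _FLIP @ g["N1"])[:2]
    else:
        raise ValueError(f"no wobble geometry for strand-I base {strand1_base!r}")
    r = WOBBLE_HB
    d = float(np.linalg.norm(c2 - c1))
    if d == 0.0 or d > 2 * r:
        raise ValueError("wobble geometry unsolvable for this base combination")
    mid = (c1 + c2) / 2
    h = math.sqrt(r * r - (d / 2) ** 2)
    perp = np.array([-(c2 - c1)[1], (c2 - c1)[0]]) / d
    cands = [mid + h * perp, mid - h * perp]
    s2 = min(cands, key=lambda s: float(np.linalg.norm(s)))
    # shift is expressed on the flipped coordinates
    return np.array([s2[0], s2[1], 0.0])


def _template_atoms(base: str, twist: float, rise: float) -> list[tuple[str, np.ndarray]]:
    """Strand-I nucleotide template in the pair frame, backbone included.

    O3' is placed 1.6 Å from the *next* residue's phosphate position
    (one twist/rise step ahead) toward C3', which makes any helix built
    from this template covalently continuous.
    """
    atoms = [(name, np.array(xyz)) for name, xyz in STD_BASE_COORDS[base].items()]
    bb = {name: np.array(xyz) for name, xyz in SUGAR_PHOSPHATE_TEMPLATE.items()}
    # template point that lands on the next residue's P under the helix
    # transform a ↦ Rz(k·twist)·(a − axis) + k·rise·ẑ
    axis = np.array([AXIS_X, 0.0, 0.0])
    next_p = _rz(twist) @ (bb["P"] - axis) + np.array([0.0, 0.0, rise]) + axis
    u = bb["C3'"] - next_p
    o3 = next_p + 1.6 * u / np.linalg.norm(u)
    order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'"]
    bb["O3'"] = o3
    return [(name, bb[name]) for name in order] + atoms


def _element_of(name: str) -> str:
    return name[0]


def _residue(chain_id: str, seq_id: int, base: str,
             atoms: list[tuple[str, np.ndarray]]) -> Residue:
    return Residue(chain_id, seq_id, base,
                   [Atom(n, _element_of(n), p) for n, p in atoms])


def make_duplex(spec: HelixSpec, seed: int | None = None
                ) -> tuple[Structure, DuplexTruth]:
    """Build an ideal duplex and its exact intended annotation.

    Chain A carries ``spec.sequence`` 5'→3'; chain B the (antiparallel)
    complement.  Pair k joins residue index k with 2n−1−k.  With a seed,
    the whole structure is placed by a random rigid motion (annotation
    unchanged).
    """
    n = len(spec.sequence)
    axis = np.array([AXIS_X, 0.0, 0.0])

    strand1: list[Residue] = []
    strand2_by_pair: list[Residue] = []
    for k, base in enumerate(spec.sequence):
        wobble = k in spec.wobble_sites
        partner = WOBBLE_COMPLEMENT[base] if wobble else COMPLEMENT[base]
        rz = _rz(k * spec.twist)
        lift = np.array([0.0, 0.0, k * spec.rise])

        atoms1 = [(a, rz @ (p - axis) + lift)
                  for a, p in _template_atoms(base, spec.twist, spec.rise)]
        strand1.append(_residue("A", k + 1, base, atoms1))

        shift = _wobble_shift(base) if wobble else np.zeros(3)
        atoms2 = []
        for a, p in _template_atoms(partner, spec.twist, spec.rise):
            q = _FLIP @ p
            if wobble and a in STD_BASE_COORDS[partner]:
                q = q + shift   # shift base + C1' only; backbone stays ideal
            atoms2.append((a, rz @ (q - axis) + lift))
        strand2_by_pair.append(_residue("B", n - k, partner, atoms2))

    chain_a = Chain("A", strand1)
    chain_b = Chain("B", list(reversed(strand2_by_pair)))
    structure = Structure(id=f"duplex_{spec.sequence}", chains=[chain_a, chain_b])

    pairs = [(k, 2 * n - 1 - k) for k in range(n)]
    stacks = [(k, k + 1) for k in range(n - 1)]
    stacks += [(n + m, n + m + 1) for m in range(n - 1)]
    canonical = [True] * n   # WC and G·U wobble pairs are all canonical
    if seed is not None:
        structure = apply_rigid(structure, *random_rotation(seed))
    return structure, DuplexTruth(pairs=pairs, stacks=sorted(stacks),
                                  canonical=canonical)


def make_hairpin(stem_len: int, loop_len: int, seed: int = 0
                 ) -> tuple[Structure, SecondaryStructure]:
    """Single-chain hairpin: ideal stem plus a non-pairing loop arc.

    The loop nucleotides are fanned out along a wide arc above the stem
    with ≥ 9 Å spacing and bases pointing outward, guaranteeing (and
    asserting) that no two loop bases come within hydrogen-bonding
    range.  Different seeds give different coordinates (rigid placement
    and arc azimuth) with identical ground-truth annotation.
    """
    if stem_len < 1:
        raise ValueError("stem_len must be ≥ 1")
    if loop_len < 3:
        raise ValueError("loop_len must be ≥ 3 (steric convention)")

    seq = ("GCAU" * ((stem_len + 3) // 4))[:stem_len]
    spec = HelixSpec(sequence=seq)
    duplex, _ = make_duplex(spec)
    rng = np.random.default_rng(seed)

    n, m = stem_len, loop_len
    z_top = (n - 1) * spec.rise
    radius = max(8.0, 9.0 * (m + 1) / math.pi)
    centre = np.array([0.0, 0.0, z_top + 8.0])
    azimuth = _rz(float(rng.uniform(0.0, 360.0)))

    loop_res: list[Residue] = []
    loop_bases = ("ACGU" * ((m + 3) // 4))[:m]
    for t, base in enumerate(loop_bases, start=1):
        phi = math.pi * t / (m + 1)
        e_r = np.array([-math.cos(phi), 0.0, math.sin(phi)])
        anchor = centre + radius * e_r
        a1 = np.array([0.0, 1.0, 0.0])       # std x̂ → out of the arc plane
        a2 = -e_r                             # std ŷ → inward (base extends outward)
        a3 = np.cross(a1, a2)
        rot = np.column_stack([a1, a2, a3])
        tmpl = _template_atoms(base, spec.twist, spec.rise)
        c1p = dict((a, p) for a, p in tmpl)["C1'"]
        atoms = [(a, azimuth @ (anchor + rot @ (p - c1p))) for a, p in tmpl]
        loop_res.append(_residue("A", 0, base, atoms))

    # rotate stem coordinates by the same azimuth so the chain is one unit
    def rot_res(r: Residue) -> Residue:
        return Residue(r.chain_id, r.seq_id, r.base,
                       [Atom(a.name, a.element, azimuth @ a.pos) for a in r.atoms])

    s1 = [rot_res(r) for r in duplex.chains[0].residues]
    s2 = [rot_res(r) for r in duplex.chains[1].residues]
    residues = s1 + loop_res + s2
    for t, r in enumerate(residues):
        r.seq_id = t + 1
    structure = Structure(id=f"hairpin_{stem_len}_{loop_len}",
                          chains=[Chain("A", residues)])
    if seed:
        structure = apply_rigid(structure, *random_rotation(seed + 1))

    _assert_loop_separation(structure, n, m)

    total = 2 * n + m
    pairs = [(k, total - 1 - k) for k in range(n)]
    loop_positions = tuple(range(n, n + m))
    stems = [Stem(tuple(pairs))] if n >= 2 else []
    lone = [pairs[0]] if n == 1 else []
    truth = SecondaryStructure(
        length=total, stems=stems,
        loops=[Loop("hairpin", loop_positions, 1)],
        lone_pairs=lone, pseudoknot_pairs=[],
        dotbracket=dot_bracket(total, pairs))
    return structure, truth


def _assert_loop_separation(structure: Structure, stem_len: int, loop_len: int,
                            min_sep: float = 3.5) -> None:
    """Construction invariant: loop bases H-bond with nothing."""
    res = structure.residues
    loop_idx = range(stem_len, stem_len + loop_len)
    others = [r for r in res if r.index not in loop_idx]
    for li in loop_idx:
        la = np.array([a.pos for a in res[li].base_atoms()])
        for other in list(others) + [res[k] for k in loop_idx if k > li]:
            if other.index == li:
                continue
            ob = np.array([a.pos for a in other.base_atoms()])
            d = np.linalg.norm(la[:, None, :] - ob[None, :, :], axis=2).min()
            if d < min_sep:
                raise AssertionError(
                    f"loop construction violated separation: residues "
                    f"{li} and {other.index} at {d:.2f} Å")


def random_rotation(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random rotation matrix and translation vector (Å)."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot, trans


def apply_rigid(structure: Structure, rot: np.ndarray,
                trans: np.ndarray) -> Structure:
    """Return a copy of the structure under r ↦ R·r + t."""
    chains = []
    for ch in structure.chains:
        residues = [Residue(r.chain_id, r.seq_id, r.base,
                            [Atom(a.name, a.element, rot @ a.pos + trans)
                             for a in r.atoms])
                    for r in ch.residues]
        chains.append(Chain(ch.id, residues))
    return Structure(id=structure.id, chains=chains)


def write_fixture(structure: Structure, truth, directory: str | Path) -> tuple[Path, Path]:
    """Write the fixture as mmCIF plus a ground-truth JSON side file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cif = directory / f"{structure.id}.cif"
    write_mmcif(structure, cif)
    meta = directory / f"{structure.id}.truth.json"
    if isinstance(truth, DuplexTruth):
        payload = {"pairs": truth.pairs, "stacks": truth.stacks,
                   "canonical": truth.canonical}
    elif isinstance(truth, SecondaryStructure):
        payload = {
            "length": truth.length,
            "stems": [list(map(list, st.pairs)) for st in truth.stems],
            "loops": [{"kind": lp.kind, "positions": list(lp.positions)}
                      for lp in truth.loops],
            "lone_pairs": [list(p) for p in truth.lone_pairs],
            "dotbracket": truth.dotbracket,
        }
    else:
        payload = truth
    meta.write_text(json.dumps(payload, indent=1))
    return cif, meta
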