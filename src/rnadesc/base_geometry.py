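"""Base-local reference frames and cylindrical pair/stack geometry.

Each nucleobase (plus its glycosidic carbon C1') is treated as a rigid
group carrying an orthonormal right-handed frame:

* origin O — geometric centre of the base heavy atoms and C1';
* in-plane vectors u, v — u = C8−N1 (purines) or C4−N1 (pyrimidines),
  v = N3−N1;
* Z = unit(u × v), normal to the base plane;
* X — unit vector from O toward the Watson–Crick edge nitrogen
  (N1 in purines, N3 in pyrimidines), Gram–Schmidt-projected into the
  plane orthogonal to Z;
* Y = Z × X.

The position of base j in the frame of base i is reported in cylindrical
coordinates (ρ, θ, z): ρ ≥ 0 in-plane distance (Å), θ ∈ [0°, 360°)
measured from X toward Y, z the signed out-of-plane offset (Å).  θ is
defined as 0 when ρ = 0.  With X anchored on the WC edge, the three
interacting edges of a base map onto fixed θ sectors: Watson–Crick near
0°, Hoogsteen (C–H for pyrimidines) near 100°, sugar near 280°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_model import Residue

__all__ = [
    "BaseFrame",
    "CylCoord",
    "build_base_frame",
    "relative_cylindrical",
    "edge_sector_of",
    "IncompleteBaseError",
    "SECTOR_BOUNDARIES",
]

PURINES = ("A", "G")

#: θ sector boundaries in degrees: WC = [0,60) ∪ [300,360),
#: Hoogsteen = [60,180), Sugar = [180,300).  The sugar sector contains
#: the sterically occluded arc (≈180–260°).
SECTOR_BOUNDARIES = {"wc_hoogsteen": 60.0, "hoogsteen_sugar": 180.0, "sugar_wc": 300.0}


class IncompleteBaseError(ValueError):
    """The residue lacks the ring atoms needed to build a frame."""


@dataclass(frozen=True)
class BaseFrame:
    origin: np.ndarray  # (3,) Å
    x: np.ndarray       # unit vectors
    y: np.ndarray
    z: np.ndarray


@dataclass(frozen=True)
class CylCoord:
    rho: float    # Å, ≥ 0
    theta: float  # degrees, [0, 360)
    z: float      # Å, signed


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise IncompleteBaseError("degenerate base geometry (zero-length vector)")
    return v / n


def build_base_frame(residue: Residue) -> BaseFrame:
    """Construct the rigid-group frame of a nucleobase.

    Requires N1, N3 and C8 (purines) / C4 (pyrimidines).  Raises
    :class:`IncompleteBaseError` when they are missing so callers can
    skip the residue.
    """
    purine = residue.base in PURINES
    n1 = residue.atom("N1")
    n3 = residue.atom("N3")
    tip = residue.atom("C8" if purine else "C4")
    if n1 is None or n3 is None or tip is None:
        raise IncompleteBaseError(
            f"residue {residue.chain_id}:{residue.seq_id} {residue.base} "
            "is missing ring atoms for frame construction")

    group = residue.base_atoms()
    c1p = residue.atom("C1'")
    if c1p is not None:
        group = group + [c1p]
    origin = np.mean([a.pos for a in group], axis=0)

    u = _unit(tip.pos - n1.pos)
    v = _unit(n3.pos - n1.pos)
    z = _unit(np.cross(u, v))
    wc_atom = n1 if purine else n3
    x_raw = wc_atom.pos - origin
    x = _unit(x_raw - np.dot(x_raw, z) * z)
    y = np.cross(z, x)
    return BaseFrame(origin=origin, x=x, y=y, z=z)


def relative_cylindrical(frame_i: BaseFrame, frame_j: BaseFrame) -> CylCoord:
    """Cylindrical coordinates of frame_j's origin in frame_i.

    Invariant under any global rigid motion applied to both frames.
    """
    d = frame_j.origin - frame_i.origin
    dx = float(np.dot(d, frame_i.x))
    dy = float(np.dot(d, frame_i.y))
    dz = float(np.dot(d, frame_i.z))
    rho = math.hypot(dx, dy)
    theta = 0.0 if rho == 0.0 else math.degrees(math.atan2(dy, dx)) % 360.0
    return CylCoord(rho=rho, theta=theta, z=dz)


def edge_sector_of(theta: float, boundaries: dict | None = None) -> str:
    """Map an in-plane angle θ (degrees) to its interacting-edge sector.

    Returns one of ``"WC"``, ``"Hoogsteen"``, ``"Sugar"``.  Total and
    piecewise constant on [0, 360); inputs outside the range are wrapped.
    """
    b = boundaries or SECTOR_BOUNDARIES
    t = float(theta) % 360.0
    if t < b["wc_hoogsteen"] or t >= b["sugar_wc"]:
        return "WC"
    if t < b["hoogsteen_sugar"]:
        return "Hoogsteen"
    return "Sugar"
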