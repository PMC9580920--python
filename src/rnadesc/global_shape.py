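"""Global size and shape descriptors of an RNA structure.

All heavy atoms are treated as equal point masses and pooled over every
chain of the structure.  The radius of gyration is

    Rg² = (1/N) Σᵢ |rᵢ − r₀|²,      r₀ = (1/N) Σᵢ rᵢ ,

and the gyration tensor is the second-moment tensor

    T = (1/N) Σᵢ (rᵢ − r₀)(rᵢ − r₀)ᵀ,

normalised so that tr(T) = Rg².  (The equivalent pairwise double-sum
form carries a 1/(2N²) prefactor; the centred single sum is what is
implemented.)  With eigenvalues λ₁ ≥ λ₂ ≥ λ₃ and λ̄ = tr(T)/3, the
asphericity and shape parameter are

    Δ = (3/2) Σᵢ (λᵢ − λ̄)² / tr(T)²          ∈ [0, 1]
    S = 27 Πᵢ (λᵢ − λ̄) / tr(T)³              ∈ [−1/4, 2]

Δ = 0 for a spherically symmetric cloud; S > 0 marks prolate and
S < 0 oblate shapes, with S = 2 attained by a collinear rod and
S = −1/4 by a symmetric planar disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeDescriptors",
    "radius_of_gyration",
    "gyration_tensor",
    "shape_descriptors",
]


class DegenerateGeometryError(ValueError):
    """All atoms coincide; Δ and S are undefined."""


def _coords(obj) -> np.ndarray:
    """Accept a Structure, anything with .coords(), or an (N,3) array."""
    if hasattr(obj, "coords"):
        x = obj.coords()
        x = x() if callable(x) else x
    else:
        x = obj
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 1:
        raise ValueError("expected an (N, 3) coordinate array with N ≥ 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    return x


@dataclass(frozen=True)
class ShapeDescriptors:
    rg: float                       # Å
    eigenvalues: tuple[float, float, float]  # λ1 ≥ λ2 ≥ λ3, Å²
    asphericity: float              # Δ, dimensionless
    shape: float                    # S, dimensionless
    n_atoms: int


def radius_of_gyration(structure) -> float:
    """Root-mean-square heavy-atom distance from the geometric centre (Å)."""
    x = _coords(structure)
    centred = x - x.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", centred, centred))))


def gyration_tensor(structure) -> np.ndarray:
    """Symmetric 3×3 gyration tensor with tr(T) = Rg²."""
    x = _coords(structure)
    centred = x - x.mean(axis=0)
    t = centred.T @ centred / x.shape[0]
    return (t + t.T) / 2.0


def eigenvalues_of(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of the gyration tensor, sorted descending, clamped ≥ 0."""
    lam = np.linalg.eigvalsh(np.asarray(tensor, dtype=float))[::-1]
    tol = 1e-12 * max(lam.sum(), 1.0)
    return np.where(lam < 0, np.where(lam > -tol, 0.0, lam), lam)


def shape_descriptors(structure) -> ShapeDescriptors:
    """Rg, principal moments, asphericity Δ and shape parameter S.

    Raises :class:`DegenerateGeometryError` when all atoms coincide
    (tr(T) = 0, so the ratios are undefined).
    """
    x = _coords(structure)
    t = gyration_tensor(x)
    lam = eigenvalues_of(t)
    tr = float(lam.sum())
    if tr <= 0.0:
        raise DegenerateGeometryError("all atoms coincident: shape undefined")
    dev = lam - tr / 3.0
    delta = 1.5 * float(np.sum(dev * dev)) / tr**2
    s = 27.0 * float(np.prod(dev)) / tr**3
    return ShapeDescriptors(
        rg=float(np.sqrt(tr)),
        eigenvalues=(float(lam[0]), float(lam[1]), float(lam[2])),
        asphericity=delta,
        shape=s,
        n_atoms=x.shape[0],
    )
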