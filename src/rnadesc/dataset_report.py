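"""Dataset-level aggregation, scaling-law fits and pair-geometry Gaussians.

Per-structure descriptors are collected into a table; the size–length
relation is fitted as a Flory-type power law Rg = a·L^b by unweighted
least squares in log–log space (with a second, restricted fit for short
chains, L < 100), base-pair counts are fitted as lines through the
origin (Nbp = k·L), and per-class cylindrical pair geometry is summarised
by independent per-coordinate Gaussians with θ treated circularly.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from . import pair_annotation
from .base_geometry import CylCoord
from .global_shape import ShapeDescriptors, shape_descriptors
from .motif_decomposition import (MotifStatistics, SecondaryStructure,
                                  best_partner_filter, decompose,
                                  motif_histograms, resolve_pseudoknots)
from .pair_annotation import BasePair, StackPair, detect_base_pairs, detect_stacking
from .structure_model import Structure

__all__ = [
    "StructureReport", "DatasetSummary", "GaussianFit",
    "fit_power_law", "fit_linear_through_origin", "fit_pair_gaussians",
    "analyze_structure", "summarize",
]


@dataclass
class StructureReport:
    """Everything computed for one structure."""
    id: str
    length: int
    shape: ShapeDescriptors
    pairs: list[BasePair]
    stacks: list[StackPair]
    secondary: SecondaryStructure

    @property
    def n_bp(self) -> int:
        return len(self.pairs)

    @property
    def n_bp_canonical(self) -> int:
        return sum(p.canonical for p in self.pairs)

    @property
    def n_bp_noncanonical(self) -> int:
        return self.n_bp - self.n_bp_canonical


@dataclass(frozen=True)
class GaussianFit:
    n: int
    rho_mean: float
    rho_sd: float
    theta_mean: float   # circular, degrees
    theta_sd: float
    z_mean: float
    z_sd: float


@dataclass
class DatasetSummary:
    n_structures: int
    table: pd.DataFrame                      # id, L, n_atoms, rg, Δ, S, Nbp, Nbp_non
    power_law: Optional[tuple[float, float]]            # (a, b) over all L
    power_law_short: Optional[tuple[float, float]]      # restricted to L < 100
    nbp_slope: Optional[float]
    nbp_non_slope: Optional[float]
    fraction_delta_below: dict[float, float]
    motifs: MotifStatistics
    pair_gaussians: dict[tuple, GaussianFit]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_structures": self.n_structures,
            "power_law": self.power_law,
            "power_law_short": self.power_law_short,
            "nbp_slope": self.nbp_slope,
            "nbp_non_slope": self.nbp_non_slope,
            "fraction_delta_below": {str(k): v for k, v
                                     in self.fraction_delta_below.items()},
            "nucleotide_freq": self.motifs.nucleotide_freq,
            "pair_freq": self.motifs.pair_freq,
            "stem_lengths": dict(self.motifs.stem_lengths),
            "hairpin_lengths": dict(self.motifs.hairpin_lengths),
            "bulge_lengths": dict(self.motifs.bulge_lengths),
            "internal_lengths": dict(self.motifs.internal_lengths),
            "junction_lengths": dict(self.motifs.junction_lengths),
            "pair_gaussians": {"|".join(map(str, k)): vars(v).copy()
                               for k, v in self.pair_gaussians.items()},
            "table": json.loads(self.table.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(doc, indent=1, default=float))


def fit_power_law(points: Sequence[tuple[float, float]],
                  l_max: Optional[float] = None) -> tuple[float, float]:
    """Least-squares fit of Rg = a·L^b in log–log space.

    ``l_max`` restricts the fit to points with L < l_max (e.g. 100 for
    the short-chain regime).  Requires ≥ 2 distinct positive L values.
    """
    pts = [(float(l), float(r)) for l, r in points
           if l_max is None or l < l_max]
    if any(l <= 0 or r <= 0 for l, r in pts):
        raise ValueError("power-law fit requires positive L and Rg")
    ls = np.array([l for l, _ in pts])
    if len(np.unique(ls)) < 2:
        raise ValueError("power-law fit requires ≥ 2 distinct L values")
    rs = np.array([r for _, r in pts])
    b, loga = np.polyfit(np.log(ls), np.log(rs), 1)
    return float(np.exp(loga)), float(b)


def fit_linear_through_origin(points: Sequence[tuple[float, float]]) -> float:
    """Slope k minimising Σ (count − k·L)²; needs ≥ 1 point with L > 0."""
    pts = [(float(l), float(c)) for l, c in points]
    if not pts or all(l == 0 for l, _ in pts):
        raise ValueError("need at least one point with L > 0")
    ls = np.array([l for l, _ in pts])
    cs = np.array([c for _, c in pts])
    return float(np.dot(ls, cs) / np.dot(ls, ls))


def fit_pair_gaussians(records: Iterable[tuple[tuple, CylCoord]],
                       min_records: int = 2) -> dict[tuple, GaussianFit]:
    """Per-class independent Gaussians over (ρ, θ, z); θ is circular.

    ``records`` pairs a hashable class key — e.g. (base_i, base_j, LW
    label) or (base_i, base_j, edge_i, edge_j) — with a cylindrical
    geometry record.  Classes with fewer than ``min_records`` members
    are reported with NaN spreads and their observed means.
    """
    grouped: dict[tuple, list[CylCoord]] = defaultdict(list)
    for key, cyl in records:
        grouped[tuple(key)].append(cyl)
    fits: dict[tuple, GaussianFit] = {}
    for key, cyls in grouped.items():
        rho = np.array([c.rho for c in cyls])
        theta = np.array([c.theta for c in cyls])
        z = np.array([c.z for c in cyls])
        n = len(cyls)
        tmean = float(circmean(theta, high=360.0, low=0.0)) % 360.0
        if n >= min_records:
            fit = GaussianFit(
                n=n,
                rho_mean=float(rho.mean()), rho_sd=float(rho.std(ddof=1)),
                theta_mean=tmean,
                theta_sd=float(circstd(theta, high=360.0, low=0.0)),
                z_mean=float(z.mean()), z_sd=float(z.std(ddof=1)))
        else:
            fit = GaussianFit(n=n, rho_mean=float(rho.mean()), rho_sd=math.nan,
                              theta_mean=tmean, theta_sd=math.nan,
                              z_mean=float(z.mean()), z_sd=math.nan)
        fits[key] = fit
    return fits


def geometry_records(reports: Iterable[StructureReport]
                     ) -> list[tuple[tuple, CylCoord]]:
    """Pair-geometry records keyed by (base_i, base_j, LW label or edges)."""
    out = []
    for rep in reports:
        for p in rep.pairs:
            if p.geometry is None:
                continue
            cls = p.lw_label if p.lw_label else f"{p.edges[0]}/{p.edges[1]}"
            out.append(((p.bases[0], p.bases[1], cls), p.geometry))
    return out


def analyze_structure(structure: Structure,
                      params: pair_annotation.DetectionParams | None = None,
                      dssr_json: str | Path | None = None) -> StructureReport:
    """Run the full per-structure pipeline.

    Pairs/stacks come from the built-in detector, or from a DSSR JSON
    annotation file when one is supplied (DSSR wins per policy).
    """
    if dssr_json is not None:
        pairs, stacks, _ = pair_annotation.ingest_dssr_json(dssr_json, structure)
    else:
        pairs = detect_base_pairs(structure, params)
        stacks = detect_stacking(structure, params)

    canonical = [p for p in pairs if p.canonical]
    chain_of = [r.chain_id for r in structure.residues]
    intra = [p for p in canonical if chain_of[p.i] == chain_of[p.j]]
    inter = [p for p in canonical if chain_of[p.i] != chain_of[p.j]]
    filtered = best_partner_filter(intra)
    nested, removed = resolve_pseudoknots(filtered)
    # inter-chain pairs join the stem statistics but close no loops
    nested_all = sorted(nested + [(p.i, p.j) for p in best_partner_filter(inter)
                                  if not _crosses_any(p, nested)])
    secondary = decompose(structure.length, nested_all, removed,
                          chain_of=chain_of)
    return StructureReport(
        id=structure.id, length=structure.length,
        shape=shape_descriptors(structure),
        pairs=pairs, stacks=stacks, secondary=secondary)


def _crosses_any(p, nested: list[tuple[int, int]]) -> bool:
    return any(a < p.i < b < p.j or p.i < a < p.j < b for a, b in nested)


def summarize(reports: Sequence[StructureReport],
              delta_thresholds: Sequence[float] = (0.2,),
              structures: Optional[Sequence[Structure]] = None) -> DatasetSummary:
    """Aggregate per-structure reports into a dataset summary.

    Deterministic and invariant to the order of the input reports.
    Fits are skipped (None) when fewer than two distinct lengths exist.
    """
    if not reports:
        raise ValueError("need at least one structure report")
    reports = sorted(reports, key=lambda r: r.id)

    rows = [{
        "id": r.id, "L": r.length, "n_atoms": r.shape.n_atoms,
        "rg": r.shape.rg,
        "lambda1": r.shape.eigenvalues[0], "lambda2": r.shape.eigenvalues[1],
        "lambda3": r.shape.eigenvalues[2],
        "asphericity": r.shape.asphericity, "shape": r.shape.shape,
        "n_bp": r.n_bp_canonical, "n_bp_non": r.n_bp_noncanonical,
    } for r in reports]
    table = pd.DataFrame(rows)

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError:
            return None

    pts = list(zip(table["L"], table["rg"]))
    power = _try(fit_power_law, pts)
    power_short = _try(fit_power_law, pts, l_max=100.0)
    nbp = _try(fit_linear_through_origin, list(zip(table["L"], table["n_bp"])))
    nbp_non = _try(fit_linear_through_origin,
                   list(zip(table["L"], table["n_bp_non"])))

    deltas = table["asphericity"].to_numpy()
    frac = {t: float(np.mean(deltas < t)) for t in delta_thresholds}

    sequences = ([s.sequence() for s in structures] if structures is not None
                 else [])
    stack_bases = []
    if structures is not None:
        by_id = {s.id: s for s in structures}
        for r in reports:
            st = by_id.get(r.id)
            if st is None:
                continue
            res = st.residues
            stack_bases += [(res[s.i].base, res[s.j].base) for s in r.stacks]

    motifs = motif_histograms(
        (r.secondary for r in reports),
        pair_lists=[r.pairs for r in reports],
        stack_base_pairs=stack_bases,
        sequences=sequences)

    gauss = fit_pair_gaussians(geometry_records(reports))
    return DatasetSummary(
        n_structures=len(reports), table=table,
        power_law=power, power_law_short=power_short,
        nbp_slope=nbp, nbp_non_slope=nbp_non,
        fraction_delta_below=frac, motifs=motifs, pair_gaussians=gauss)
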