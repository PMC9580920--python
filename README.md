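# rnadesc

Statistical descriptors of RNA 3D structures, for people who build
knowledge-based potentials, coarse-grained force fields, or scoring
functions and need the underlying structural statistics: global
size/shape, base-pair and base-stacking geometry, secondary-structure
motif inventories, and atom-pair distance distributions, with
dataset-level aggregation and curve fitting.

## What it computes

**Size and shape.** Treating every heavy atom (C, N, O, P) as an equal
point mass, the radius of gyration is
`Rg² = (1/N) Σᵢ |rᵢ − r₀|²` about the geometric centre r₀, pooled over
all chains. From the gyration tensor
`T = (1/N) Σᵢ (rᵢ − r₀)(rᵢ − r₀)ᵀ` (normalised so tr T = Rg²) with
eigenvalues λ₁ ≥ λ₂ ≥ λ₃ and λ̄ = tr T / 3, the asphericity and shape
parameter are

    Δ = (3/2) Σᵢ (λᵢ − λ̄)² / (tr T)²   ∈ [0, 1]
    S = 27 Πᵢ (λᵢ − λ̄) / (tr T)³       ∈ [−1/4, 2]

Δ = 0 for a spherically symmetric cloud; S > 0 is prolate, S < 0 oblate;
a collinear rod attains (Δ, S) = (1, 2) and a flat symmetric disc
S = −1/4. Over a dataset, Rg–L points are fitted to the Flory-type
scaling law `Rg = a·Lᵇ` by least squares in log–log space (with a second
fit restricted to L < 100).

**Base-pair / stacking geometry.** Each nucleobase plus its glycosidic
C1' carries an orthonormal frame: origin at the group's heavy-atom
centre, Z normal to the base plane (from u = C8−N1 or C4−N1 and
v = N3−N1), X toward the Watson–Crick edge nitrogen. The position of
base j in the frame of base i is reported in cylindrical coordinates
(ρ, θ, z), and θ maps onto the three interacting edges: Watson–Crick
near 0°, Hoogsteen near 100°, sugar near 280°. Ideal WC pairs sit at
ρ ≈ 6.3 Å, θ ≈ 0°, z ≈ 0; stacked neighbours at ρ ≈ 3 Å, |z| ≈ 3 Å.
Per-class (base combination × Leontis–Westhof label or edge pair)
Gaussians summarise the geometry, with θ treated circularly.

**Base pairs and motifs.** Pairs come from a built-in geometric detector
(hydrogen-bond distance + base-plane criteria; thresholds configurable)
or from DSSR JSON annotations (LW labels preserved verbatim). C-G, A-U
and G-U pairs on Watson–Crick edges are canonical; everything else is
non-canonical. Canonical pairs are reduced to a maximum crossing-free
subset (exact dynamic programme; the rest are pseudoknots) and
decomposed into stems — runs of consecutively stacked pairs — and
hairpin / bulge / internal / junction loops, yielding length histograms,
nucleotide and pair frequency tables, and the linear growth of pair
counts with length (`Nbp = k·L` through the origin).

**Atom-pair distances.** Distances between heavy atoms of the 85-type
scheme (12 backbone/ribose names shared by all four bases, plus the
base-specific atoms: A = 22, C = 20, G = 23, U = 20) in different
nucleotides, excluding the bonded O3'–P link, binned per unordered type
pair (default 0.1 Å bins to 100 Å) — the raw material of
distance-dependent statistical potentials.

## Worked example

The package ships a fixture generator whose structures carry exact
ground truth, so the example needs no downloads:

```sh
rnadesc fixtures make --kind hairpin --stem-len 4 --loop-len 4 -o fx
rnadesc shape fx/hairpin_4_4.cif
```

```
id,L,n_atoms,rg,lambda1,lambda2,lambda3,asphericity,shape
hairpin_4_4,12,255,13.7313,133.792,41.2619,13.4943,0.334797,0.304464
```

A 12-nt hairpin (4-bp stem, 4-nt loop): Rg = 13.7 Å over its 255 heavy
atoms; λ₁ ≫ λ₂ > λ₃ gives Δ = 0.33 and S = +0.30 — moderately
anisotropic and prolate, as expected for a short helix with a wide
synthetic loop arc.

```sh
rnadesc pairs fx/hairpin_4_4.cif
```

```
i,j,base_i,base_j,canonical,edge_i,edge_j,lw,source,rho,theta,z
0,11,G,C,True,WC,WC,,builtin,6.23653,359.089,0.000493209
1,10,C,G,True,WC,WC,,builtin,6.23653,8.11945,0.000222222
2,9,A,U,True,WC,WC,,builtin,6.38496,2.44478,0.000111111
3,8,U,A,True,WC,WC,,builtin,6.38496,8.94279,-0.000111111
```

The four stem pairs, all canonical, each partner seen on the other's
Watson–Crick edge (θ within ±9° of 0) at ρ ≈ 6.3 Å and z ≈ 0.

```sh
rnadesc motifs fx/hairpin_4_4.cif
```

```
kind,length,detail
stem,4,"((0, 11), (1, 10), (2, 9), (3, 8))"
hairpin,4,"(4, 5, 6, 7)"
```

One 4-bp stem and one tetraloop — exactly the generator's ground truth.
`rnadesc batch DIR` runs the whole pipeline over a directory and writes
`summary.json` (scaling-law and slope fits, Δ/S statistics, motif
histograms, frequency tables, per-class geometry Gaussians) plus a
per-structure CSV. The same functionality is available as a library
(`rnadesc.analyze_structure`, `rnadesc.summarize`).

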