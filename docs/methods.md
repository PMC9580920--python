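# Methods

## Coordinate model

Structures are read with gemmi from mmCIF or legacy PDB. Only the four
standard ribonucleotides survive filtering; waters, ions, ligands,
protein/DNA chains and hydrogens are dropped and logged. Multi-model
(NMR) entries contribute model 1 only. Alternate locations keep the
highest-occupancy conformer (ties broken by altloc label order).
Modified nucleotides are dropped by default; an opt-in map renames the
common ones (PSU→U, 1MA→A, …) to their parent base, whose extra atoms
then simply carry no atom type. Backbone continuity is decided by the
O3'(i)–P(i+1) distance with a 2.5 Å cutoff; author residue numbering is
kept for display while every algorithm uses a 0-based sequential index.

The heavy-atom type scheme has exactly 85 entries: 12 sugar–phosphate
names shared by all bases (OP3 and hydrogens deliberately excluded)
plus 10/11/8/8 base atoms for A/G/C/U, i.e. per-base totals 22/23/20/20.
`atom_type_of` is total: anything outside the table maps to `None`
rather than raising, so terminal phosphates and exotic atoms flow
through parsing but never enter typed statistics.

## Size and shape

Rg uses the geometric centre of all heavy atoms with equal masses,
pooled over every chain of the entry. The gyration tensor is computed
in its centred single-sum form T = (1/N) Σ (rᵢ−r₀)(rᵢ−r₀)ᵀ, which equals
the pairwise double-sum form with a 1/(2N²) prefactor; the normalisation
is fixed by the contract tr T = Rg². (Δ and S are scale-free ratios of
eigenvalue deviations, so any overall prefactor cancels; the test suite
checks the single-sum implementation against a literal O(N²) double-sum
oracle to 1e-9 relative.) Eigenvalues come from `numpy.linalg.eigvalsh`,
sorted descending, with values above −1e-12·tr T clamped to zero.
Δ and S are reported unclamped; the mathematical bounds Δ ∈ [0,1],
S ∈ [−1/4, 2] are verified in tests up to 1e-12 float slack. A structure
whose atoms all coincide has tr T = 0 and raises a degenerate-geometry
error instead of returning NaNs.

## Base frames and cylindrical geometry

The rigid group is the nucleobase plus its glycosidic carbon C1', and
the frame origin is that group's heavy-atom centroid. Including C1' is
a deliberate package convention: with base-only centroids an ideal WC
pair sits at ρ ≈ 5.8–5.9 Å, whereas the C1'-inclusive origin puts it at
ρ ≈ 6.2–6.4 Å, consistent with the ρ ≈ 7 Å Watson–Crick locus reported
for experimental data and with the [6, 9] Å band the tests assert.
In-plane vectors are u = C8−N1 (purines) / C4−N1 (pyrimidines) and
v = N3−N1; Z = unit(u×v). X points from the origin toward the
Watson–Crick edge nitrogen — N1 in purines, N3 in pyrimidines —
Gram-Schmidt-projected into the base plane; Y = Z×X completes a
right-handed triad. Using N3 rather than N1 for pyrimidines is the
second deliberate convention: N1 is the pyrimidine glycosidic nitrogen,
and anchoring X there would rotate WC partners to θ ≈ 135°, destroying
the alignment of the three edge sectors across purines and pyrimidines.
With the WC-edge anchor, purine loci land near the reported sector
centres (WC ≈ 0°, Hoogsteen ≈ 100°–130°, sugar ≈ 280°).

θ is measured from X toward Y in degrees on [0°, 360°), defined as 0
when ρ = 0. Sector boundaries are WC = [0°, 60°) ∪ [300°, 360°),
Hoogsteen = [60°, 180°), Sugar = [180°, 300°): this centres the three
loci and places the sterically occluded arc (≈180°–260°) inside the
sugar sector. The boundaries are a configurable convention — the
original dotted-line positions were never published numerically — and
no claim is made of bit-for-bit agreement.

## Pair and stack detection

The built-in detector is intentionally simpler than a full annotation
program. A candidate pair must have (1) at least `hb_min = 2`
donor–acceptor heavy-atom contacts under `hb_dist = 3.4 Å` between base
atoms (per-base donor/acceptor tables are hard-coded), (2) an
inter-plane angle (base normals folded to ≤ 90°) under
`plane_max = 65°`, and (3) |z| < `z_pair_max = 2.5 Å` in *each*
partner's frame. Stacking requires |z| ∈ [2.5, 4.5] Å and ρ ≤ 5 Å in
both frames with planes within 30°. All thresholds are configurable and
are standard structural-biology heuristics, not fitted values. The
z-band split at 2.5 Å makes pairing and stacking mutually exclusive by
construction. Multiplets are allowed at detection time; motif
decomposition first reduces them to one partner per residue by
hydrogen-bond count. cis/trans glycosidic orientation is *not* inferred
geometrically — full Leontis–Westhof labels are available only through
DSSR JSON ingestion, which preserves them verbatim and recomputes the
canonical flag (bases ∈ {CG, AU, GU} and both edges WC). When both
sources are present the DSSR annotation wins and a reconciliation report
lists disagreements.

## Motif decomposition

Canonical pairs are split into a maximum-cardinality crossing-free
subset by an exact interval dynamic programme over compressed endpoint
coordinates (O(m³) in the pair count; verified against exhaustive
enumeration for m ≤ 12). Removed pairs are labelled pseudoknotted,
rendered in higher dot-bracket tiers, and excluded from loops. Stems
are maximal runs (i,j),(i+1,j−1),…; length-1 runs are reported as lone
pairs and kept out of the stem-length histogram by default. Loops are
classified by the number of bordering stems (hairpin 1; bulge/internal
2, distinguished by one side being empty; junction ≥ 3); loop length is
the total unpaired count without distinguishing 5′/3′ sides. Dangling
exterior residues belong to no loop, so stem-paired + loop + exterior
partitions the chain. Inter-chain pairs enter pair statistics and stem
runs but close no loop; loop decomposition is effectively per chain.

## Distances

Distance statistics cover typed heavy atoms in different residues,
excluding the single covalent O3'–P link between connected neighbours;
each unordered atom pair is emitted once. Default binning is 0.1 Å
half-open bins to d_max = 100 Å; overflow distances are dropped with a
logged count. Named extracts (nearest-neighbour, second-neighbour and
paired-nucleotide P–P) isolate the three features that dominate the
pooled P–P distribution.

## Dataset fits

The power law is an unweighted least-squares line in log–log space —
the regression scheme is a package choice, as is the through-origin
estimator k = Σ L·c / Σ L² for pair-count growth. Pair-geometry classes
(base combination × LW label or edge pair) are summarised as independent
per-coordinate Gaussians; θ uses circular mean/standard deviation
(scipy, period 360°) and full covariance is deliberately not modelled.
Classes with fewer than 2 records report their mean with NaN spread.
`summarize` sorts reports by id, making it permutation-invariant, and
skips fits (returning None) when fewer than two distinct lengths exist.

## Synthetic fixtures

The generators emulate *geometry*, not physics. Bases use standard
planar reference-frame coordinates; the sugar–phosphate positions are a
synthetic idealisation placing P at helix radius ≈ 9.3 Å so that an
assembled duplex (defaults: twist 32.7°/bp, rise 2.81 Å/bp, A-form
convention) reproduces A-form-like signatures: nearest-neighbour P–P
≈ 5.9 Å, second-neighbour ≈ 11.5 Å, cross-strand paired P–P ≈ 18.4 Å,
stacking at ρ ≈ 2.6–3.0 Å and |z| = rise. Strand II is the 180°
x-rotation of strand I; G·U wobbles are placed by solving the two-circle
intersection that puts both wobble hydrogen bonds at 2.85 Å, shifting
the base + C1' only. Hairpin loops fan their nucleotides along a wide
arc (≥ 9 Å spacing, bases pointing outward, ≥ 3.5 Å base–base
separation asserted at build time), which guarantees — independently of
detector thresholds — that loop bases can neither pair nor stack.

Consequently, passing fixture tests demonstrates correctness of the
geometric machinery (frames, detectors, decomposition, binning) under
ideal conditions; they say nothing about robustness to the distortions
of experimental structures — propeller twist, buckle, non-planar bases,
incomplete residues, modified nucleotides — beyond what the explicit
degraded-input tests (missing atoms, altlocs, multi-model files) cover.
Dataset-scale statistics over experimental structures (scaling-law
constants, Δ/S distributions, motif histograms, P–P peak positions)
require downloading a curated set, e.g. via the untested helper in
`scripts/curate_dataset.py`, and depend on annotation-source parity
(the built-in detector is not DSSR).

## Problem sizes and numerical choices

Test-suite problem sizes are chosen for exactness of the oracles rather
than realism: duplexes of 4–20 bp, hairpins with ≤ 8-nt loops, point
clouds of 50 points, 1,000-instance pseudoknot sweeps with ≤ 12 pairs
(the exhaustive reference enumerates 2^m subsets), and 100 structures of
≤ 200 atoms for the double-sum tensor oracle. Rigid-motion invariance
is asserted to 1e-9 (1e-7 for θ in degrees near the wrap-around).
Numeric CLI output is fixed at 6 significant digits so reruns are
byte-identical.
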