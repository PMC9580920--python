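"""Secondary-structure decomposition of a canonical base-pair list.

Pipeline: the canonical pairs of a structure are reduced to at most one
partner per residue (best hydrogen-bond count wins), a maximum-cardinality
crossing-free subset is selected by exact dynamic programming (the rest
are labelled pseudoknotted), and the nested set is decomposed into stems
(maximal runs of consecutively stacked pairs (i,j),(i+1,j−1),…) and
loops:

* hairpin — unpaired run closed by one stem; length = j − i − 1;
* bulge — between two stems, one side empty; length = unpaired count;
* internal — between two stems, both sides unpaired; length = total
  unpaired count over both sides (5′/3′ sides are not distinguished);
* junction — bordered by ≥ 3 stems; length = total unpaired count
  around the cycle.

Dangling exterior residues belong to no loop.  Length-1 stems are
reported separately as lone pairs and excluded from the stem-length
histogram by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .pair_annotation import BasePair

__all__ = [
    "Stem", "Loop", "SecondaryStructure",
    "best_partner_filter", "resolve_pseudoknots", "decompose",
    "motif_histograms", "MotifStatistics", "dot_bracket",
]


@dataclass(frozen=True)
class Stem:
    pairs: tuple[tuple[int, int], ...]  # (i,j),(i+1,j-1),...

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Loop:
    kind: str                     # hairpin | bulge | internal | junction
    positions: tuple[int, ...]    # unpaired residue indices
    branch_count: int

    @property
    def length(self) -> int:
        return len(self.positions)


@dataclass
class SecondaryStructure:
    length: int
    stems: list[Stem]
    loops: list[Loop]
    lone_pairs: list[tuple[int, int]]
    pseudoknot_pairs: list[tuple[int, int]]
    dotbracket: str

    @property
    def paired(self) -> set[int]:
        out = {k for st in self.stems for ij in st.pairs for k in ij}
        out |= {k for ij in self.lone_pairs for k in ij}
        return out

    @property
    def exterior(self) -> set[int]:
        in_loop = {p for lp in self.loops for p in lp.positions}
        return set(range(self.length)) - self.paired - in_loop


class MultipletError(ValueError):
    """A residue participates in more than one pair after pre-filtering."""


def best_partner_filter(pairs: Sequence[BasePair]) -> list[BasePair]:
    """Reduce multiplets to one partner per residue, keeping the pair with
    the most hydrogen bonds (ties: smaller span, then lexicographic)."""
    ranked = sorted(pairs, key=lambda p: (-p.n_hbonds, p.j - p.i, p.i, p.j))
    taken: set[int] = set()
    kept: list[BasePair] = []
    for p in ranked:
        if p.i in taken or p.j in taken:
            continue
        taken.update((p.i, p.j))
        kept.append(p)
    return sorted(kept, key=lambda p: (p.i, p.j))


def _as_tuples(pairs: Iterable) -> list[tuple[int, int]]:
    out = []
    for p in pairs:
        i, j = (p.i, p.j) if isinstance(p, BasePair) else (p[0], p[1])
        if i >= j:
            raise ValueError(f"pair ({i},{j}) must have i < j")
        out.append((i, j))
    return sorted(out)


def resolve_pseudoknots(pairs: Iterable) -> tuple[list[tuple[int, int]],
                                                  list[tuple[int, int]]]:
    """Split pairs into a maximum crossing-free subset and the rest.

    Exact interval dynamic programme over the compressed endpoint
    coordinates (Nussinov-style), O(m³) in the number of pairs m.
    Requires at most one partner per residue (apply
    :func:`best_partner_filter` first); violating input raises
    :class:`MultipletError`.
    """
    plist = _as_tuples(pairs)
    seen: Counter = Counter(k for ij in plist for k in ij)
    if seen and seen.most_common(1)[0][1] > 1:
        k, _ = seen.most_common(1)[0]
        raise MultipletError(f"residue {k} appears in more than one pair")
    if not plist:
        return [], []

    # compress endpoints to 0..2m-1
    coords = sorted(k for ij in plist for k in ij)
    pos = {c: n for n, c in enumerate(coords)}
    cpairs = [(pos[i], pos[j]) for i, j in plist]
    partner = {a: b for a, b in cpairs}
    m2 = len(coords)

    # dp[a][b] = (max pairs entirely within [a, b], chosen set)
    best: dict[tuple[int, int], tuple[int, frozenset]] = {}

    def solve(a: int, b: int) -> tuple[int, frozenset]:
        if a >= b:
            return 0, frozenset()
        key = (a, b)
        hit = best.get(key)
        if hit is not None:
            return hit
        # position a unpaired (or its partner outside [a,b])
        score, chosen = solve(a + 1, b)
        c = partner.get(a)
        if c is not None and a < c <= b:
            s1, k1 = solve(a + 1, c - 1)
            s2, k2 = solve(c + 1, b)
            if 1 + s1 + s2 > score:
                score, chosen = 1 + s1 + s2, k1 | k2 | {(a, c)}
        best[key] = (score, chosen)
        return best[key]

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * m2 + 100))
    try:
        _, chosen = solve(0, m2 - 1)
    finally:
        sys.setrecursionlimit(old)
    back = {pos[i]: (i, j) for i, j in plist}
    nested = sorted(back[a] for a, _ in chosen)
    removed = sorted(set(plist) - set(nested))
    return nested, removed


def _stems_of(nested: list[tuple[int, int]]) -> list[tuple[tuple[int, int], ...]]:
    pairs = sorted(nested)
    pairset = set(pairs)
    runs: list[tuple[tuple[int, int], ...]] = []
    used: set[tuple[int, int]] = set()
    for p in pairs:
        if p in used:
            continue
        run = [p]
        i, j = p
        while (i + 1, j - 1) in pairset:
            i, j = i + 1, j - 1
            run.append((i, j))
        used.update(run)
        runs.append(tuple(run))
    return runs


def decompose(structure_length: int, nested_pairs: Iterable,
              pseudoknot_pairs: Iterable = (),
              min_stem: int = 1,
              include_lone_in_stems: bool = False,
              chain_of: Optional[Sequence] = None) -> SecondaryStructure:
    """Decompose a crossing-free pair set into stems and loops.

    ``chain_of`` (optional, one label per residue) restricts loop
    decomposition to intra-chain pairs; inter-chain pairs are kept in the
    stem list but close no loop.  Pseudoknotted pairs are rendered in
    bracket tiers of the dot-bracket string but excluded from motifs.
    """
    L = int(structure_length)
    nested = _as_tuples(nested_pairs)
    pk = _as_tuples(pseudoknot_pairs) if pseudoknot_pairs else []
    for i, j in nested + pk:
        if not (0 <= i < j < L):
            raise ValueError(f"pair ({i},{j}) outside structure of length {L}")

    runs = _stems_of(nested)
    lone = [run[0] for run in runs if len(run) == 1]
    # length-1 runs are tracked as lone pairs and kept out of the stem list
    # (hence the stem-length histogram) unless include_lone_in_stems is set
    floor = 2 if not include_lone_in_stems else 1
    stems = [Stem(run) for run in runs if len(run) >= max(min_stem, floor)]

    paired = {k for i, j in nested for k in (i, j)}
    partner = {}
    for i, j in nested:
        partner[i] = j
        partner[j] = i

    same_chain = (lambda i, j: True) if chain_of is None else (
        lambda i, j: chain_of[i] == chain_of[j])

    loops: list[Loop] = []
    # loops are anchored at the innermost pair of each helix-closing run
    closing = [run[-1] for run in runs]
    for i, j in closing:
        if not same_chain(i, j):
            continue
        # walk the loop interior collecting unpaired runs and child stems
        unpaired: list[int] = []
        branches = 1
        k = i + 1
        ok = True
        while k < j:
            if k in partner:
                nxt = partner[k]
                if nxt < k or nxt > j or not same_chain(k, nxt):
                    ok = False  # pseudoknot remnant or inter-chain: skip loop
                    break
                branches += 1
                k = nxt + 1
            else:
                unpaired.append(k)
                k += 1
        if not ok:
            continue
        if branches == 1:
            loops.append(Loop("hairpin", tuple(unpaired), 1))
        elif branches == 2:
            # sides: before and after the single child stem
            child_start = next(k for k in range(i + 1, j) if k in partner)
            left = [p for p in unpaired if p < child_start]
            right = [p for p in unpaired if p > child_start]
            if not unpaired:
                continue  # flush coaxial stems, zero-length "loop": nothing to record
            kind = "bulge" if (not left or not right) else "internal"
            loops.append(Loop(kind, tuple(unpaired), 2))
        else:
            loops.append(Loop("junction", tuple(unpaired), branches))

    db = dot_bracket(L, nested, pk)
    return SecondaryStructure(length=L, stems=stems, loops=loops,
                              lone_pairs=lone, pseudoknot_pairs=pk,
                              dotbracket=db)


_TIERS = "([{<"
_CLOSE = ")]}>"


def dot_bracket(length: int, nested: list[tuple[int, int]],
                pseudoknots: list[tuple[int, int]] = []) -> str:
    """Dot-bracket string; pseudoknot pairs go to higher bracket tiers greedily."""
    out = ["."] * length
    tiers: list[list[tuple[int, int]]] = [list(nested)]
    for i, j in sorted(pseudoknots):
        for tier in tiers[1:]:
            if all(not (a < i < b < j or i < a < j < b) for a, b in tier):
                tier.append((i, j))
                break
        else:
            tiers.append([(i, j)])
    for level, tier in enumerate(tiers):
        o = _TIERS[min(level, len(_TIERS) - 1)]
        c = _CLOSE[min(level, len(_CLOSE) - 1)]
        for i, j in tier:
            out[i], out[j] = o, c
    return "".join(out)


@dataclass
class MotifStatistics:
    """Dataset-level motif histograms and normalised frequency tables."""
    stem_lengths: Counter = field(default_factory=Counter)
    hairpin_lengths: Counter = field(default_factory=Counter)
    bulge_lengths: Counter = field(default_factory=Counter)
    internal_lengths: Counter = field(default_factory=Counter)
    junction_lengths: Counter = field(default_factory=Counter)
    loop_lengths: Counter = field(default_factory=Counter)     # all kinds pooled
    pair_freq: dict = field(default_factory=dict)              # by base combination
    nucleotide_freq: dict = field(default_factory=dict)
    stack_freq: dict = field(default_factory=dict)             # by base combination
    n_lone_pairs: int = 0
    n_pseudoknot_pairs: int = 0


def _normalise(counter: Counter) -> dict:
    total = sum(counter.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counter.items())}


def motif_histograms(secondary_structures: Iterable[SecondaryStructure],
                     pair_lists: Iterable[Sequence[BasePair]] = (),
                     stack_base_pairs: Iterable[tuple[str, str]] = (),
                     sequences: Iterable[str] = ()) -> MotifStatistics:
    """Aggregate length histograms and frequency tables over a dataset.

    ``pair_lists`` feed the base-pair frequency table (canonical and
    non-canonical combinations alike), ``sequences`` the nucleotide
    table, ``stack_base_pairs`` the stack table.  All tables are
    normalised to sum to 1.
    """
    stats = MotifStatistics()
    kind_to = {"hairpin": stats.hairpin_lengths, "bulge": stats.bulge_lengths,
               "internal": stats.internal_lengths, "junction": stats.junction_lengths}
    for ss in secondary_structures:
        for st in ss.stems:
            stats.stem_lengths[st.length] += 1
        for lp in ss.loops:
            kind_to[lp.kind][lp.length] += 1
            stats.loop_lengths[lp.length] += 1
        stats.n_lone_pairs += len(ss.lone_pairs)
        stats.n_pseudoknot_pairs += len(ss.pseudoknot_pairs)

    pair_counter: Counter = Counter()
    for plist in pair_lists:
        for p in plist:
            pair_counter["-".join(sorted(p.bases))] += 1
    stats.pair_freq = _normalise(pair_counter)

    nt_counter: Counter = Counter()
    for seq in sequences:
        nt_counter.update(seq)
    stats.nucleotide_freq = _normalise(nt_counter)

    stack_counter: Counter = Counter()
    for bases in stack_base_pairs:
        stack_counter["-".join(sorted(bases))] += 1
    stats.stack_freq = _normalise(stack_counter)
    return stats
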