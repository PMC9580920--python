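import numpy as np
import pytest

from _oracles import max_noncrossing_bruteforce
from rnadesc.motif_decomposition import (MultipletError, best_partner_filter,
                                         decompose, dot_bracket,
                                         motif_histograms, resolve_pseudoknots)


def random_matching(rng, n_pairs, span=40):
    """Random set of pairs, each residue used at most once."""
    positions = rng.choice(span, size=2 * n_pairs, replace=False)
    rng.shuffle(positions)
    return sorted((min(a, b), max(a, b))
                  for a, b in positions.reshape(-1, 2))


class TestResolvePseudoknots:
    def test_crossing_blocks_keep_the_larger_side(self):
        pairs = [(1, 10), (2, 9), (5, 14), (6, 13)]
        nested, removed = resolve_pseudoknots(pairs)
        # brute force on this 4-pair instance: best crossing-free subset has 2
        assert len(nested) == max_noncrossing_bruteforce(pairs) == 2
        assert sorted(nested + removed) == pairs
        assert not any(a < c < b < d or c < a < d < b
                       for a, b in nested for c, d in nested)

    def test_nested_input_untouched(self):
        pairs = [(0, 11), (1, 10), (4, 8)]
        nested, removed = resolve_pseudoknots(pairs)
        assert nested == pairs and removed == []

    def test_empty_input(self):
        assert resolve_pseudoknots([]) == ([], [])

    def test_multiplet_raises(self):
        with pytest.raises(MultipletError):
            resolve_pseudoknots([(1, 5), (1, 9)])

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        pairs = random_matching(rng, int(rng.integers(1, 13)))
        nested, removed = resolve_pseudoknots(pairs)
        assert len(nested) == max_noncrossing_bruteforce(pairs)
        assert sorted(nested + removed) == sorted(pairs)


class TestBestPartnerFilter:
    def test_keeps_strongest_pair_per_residue(self):
        from rnadesc.pair_annotation import BasePair
        mk = lambda i, j, n: BasePair(i, j, ("G", "C"), True, ("WC", "WC"),
                                      "builtin", None, n_hbonds=n)
        kept = best_partner_filter([mk(1, 9, 3), mk(1, 12, 2), mk(3, 7, 2)])
        assert [(p.i, p.j) for p in kept] == [(1, 9), (3, 7)]


class TestDecompose:
    def test_simple_hairpin(self):
        ss = decompose(12, [(0, 11), (1, 10), (2, 9)])
        assert [s.length for s in ss.stems] == [3]
        assert [(l.kind, l.length) for l in ss.loops] == [("hairpin", 6)]
        assert ss.loops[0].positions == tuple(range(3, 9))
        assert ss.dotbracket == "(((......)))"

    def test_bulge_and_hairpin(self):
        # hand decomposition: stems (0,19),(1,18),(2,17) and (4,16),(5,15);
        # bulge at position 3; hairpin over 6..14
        ss = decompose(20, [(0, 19), (1, 18), (2, 17), (4, 16), (5, 15)])
        assert sorted(s.length for s in ss.stems) == [2, 3]
        loops = {l.kind: l for l in ss.loops}
        assert loops["bulge"].positions == (3,)
        assert loops["hairpin"].length == 9
        assert loops["hairpin"].positions == tuple(range(6, 15))

    def test_symmetric_internal_loop(self):
        ss = decompose(16, [(0, 15), (1, 14), (4, 11), (5, 10)])
        kinds = {l.kind: l for l in ss.loops}
        assert kinds["internal"].length == 4
        assert kinds["internal"].branch_count == 2

    def test_junction_loop(self):
        pairs = [(0, 23), (1, 22), (3, 9), (4, 8), (12, 19), (13, 18)]
        ss = decompose(24, pairs)
        kinds = [l.kind for l in ss.loops]
        assert kinds.count("junction") == 1
        j = next(l for l in ss.loops if l.kind == "junction")
        assert j.branch_count == 3
        assert j.positions == (2, 10, 11, 20, 21)

    def test_lone_pair_excluded_from_stems_by_default(self):
        ss = decompose(10, [(0, 9), (3, 7)])
        assert ss.lone_pairs == [(0, 9), (3, 7)]
        assert ss.stems == []
        ss2 = decompose(10, [(0, 9), (3, 7)], include_lone_in_stems=True)
        assert sorted(s.length for s in ss2.stems) == [1, 1]


class TestPartition:
    @pytest.mark.parametrize("seed", range(20))
    def test_every_residue_classified_once(self, seed):
        rng = np.random.default_rng(seed)
        span = 40
        pairs = random_matching(rng, int(rng.integers(1, 13)), span)
        nested, removed = resolve_pseudoknots(pairs)
        ss = decompose(span, nested, removed)
        paired = ss.paired
        in_loop = {p for l in ss.loops for p in l.positions}
        exterior = ss.exterior
        assert paired | in_loop | exterior == set(range(span))
        assert not (paired & in_loop) and not (paired & exterior)
        assert not (in_loop & exterior)


class TestDotBracket:
    def test_pseudoknots_get_bracket_tiers(self):
        s = dot_bracket(10, [(0, 5), (1, 4)], [(3, 7)])
        assert s == "((.[)).].."

    def test_plain_nested(self):
        assert dot_bracket(6, [(0, 5), (1, 4)]) == "((..))"


class TestMotifHistograms:
    def test_single_hairpin_histograms(self):
        ss = decompose(12, [(0, 11), (1, 10), (2, 9)])
        stats = motif_histograms([ss])
        assert dict(stats.stem_lengths) == {3: 1}
        assert dict(stats.hairpin_lengths) == {6: 1}

    def test_duplicating_structures_doubles_counts_not_frequencies(self):
        ss = decompose(12, [(0, 11), (1, 10), (2, 9)])
        one = motif_histograms([ss], sequences=["GGGAAAAAACCC"])
        two = motif_histograms([ss, ss],
                               sequences=["GGGAAAAAACCC", "GGGAAAAAACCC"])
        assert two.stem_lengths[3] == 2 * one.stem_lengths[3]
        assert two.nucleotide_freq == one.nucleotide_freq

    def test_frequency_tables_normalised(self):
        from rnadesc.pair_annotation import BasePair
        gc = BasePair(0, 11, ("G", "C"), True, ("WC", "WC"), "builtin", None)
        stats = motif_histograms([], pair_lists=[[gc, gc, gc]])
        assert stats.pair_freq == {"C-G": 1.0}
        assert abs(sum(stats.pair_freq.values()) - 1.0) < 1e-12
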