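import json

import pytest

from conftest import random_coil
from rnadesc import fixtures as fx
from rnadesc.pair_annotation import (DetectionParams, IngestionError,
                                     detect_base_pairs, detect_stacking,
                                     export_annotations, ingest_dssr_json,
                                     is_canonical, reconcile)


class TestDetector:
    def test_duplex_pairs_recovered_exactly(self, gc_duplex):
        st, truth = gc_duplex
        found = detect_base_pairs(st)
        assert sorted((p.i, p.j) for p in found) == truth.pairs
        assert all(p.canonical for p in found)
        assert all(p.edges == ("WC", "WC") for p in found)

    def test_wobble_reported_canonical(self, wobble_duplex):
        st, truth = wobble_duplex
        found = {(p.i, p.j): p for p in detect_base_pairs(st)}
        assert sorted(found) == truth.pairs
        gu = [p for p in found.values() if set(p.bases) == {"G", "U"}]
        assert len(gu) == 1 and gu[0].canonical

    def test_random_coil_has_no_pairs(self):
        st = random_coil(12, seed=5)
        assert detect_base_pairs(st) == []
        assert detect_stacking(st) == []

    def test_invariant_to_rigid_motion_and_atom_order(self, gc_duplex):
        st, truth = gc_duplex
        moved = fx.apply_rigid(st, *fx.random_rotation(77))
        assert sorted((p.i, p.j) for p in detect_base_pairs(moved)) == truth.pairs
        # reverse atom order within every residue
        import copy
        shuffled = copy.deepcopy(st)
        for res in shuffled.residues:
            res.atoms.reverse()
        assert sorted((p.i, p.j) for p in detect_base_pairs(shuffled)) == truth.pairs

    def test_geometry_invariance_to_1e9(self, gc_duplex):
        st, _ = gc_duplex
        moved = fx.apply_rigid(st, *fx.random_rotation(78))
        g0 = {(p.i, p.j): p.geometry for p in detect_base_pairs(st)}
        g1 = {(p.i, p.j): p.geometry for p in detect_base_pairs(moved)}
        for key in g0:
            assert g1[key].rho == pytest.approx(g0[key].rho, abs=1e-9)
            assert g1[key].z == pytest.approx(g0[key].z, abs=1e-9)


class TestStacking:
    def test_adjacent_intra_strand_neighbours_stacked(self, gc_duplex):
        st, truth = gc_duplex
        adjacent = {(s.i, s.j) for s in detect_stacking(st) if s.adjacent}
        assert set(truth.stacks) <= adjacent

    def test_coplanar_side_by_side_bases_not_stacked(self):
        # two residues of a flat duplex plane: z ≈ 0 in each other's frame
        st, truth = fx.make_duplex(fx.HelixSpec("G"))
        i, j = truth.pairs[0]
        stacks = detect_stacking(st)
        assert (i, j) not in {(s.i, s.j) for s in stacks}

    def test_isolated_base_has_no_stacks(self):
        st = random_coil(1, seed=2)
        assert detect_stacking(st) == []

    def test_stack_band_respected(self, gc_duplex):
        st, _ = gc_duplex
        p = DetectionParams()
        for s in detect_stacking(st):
            assert p.z_stack_min <= abs(s.geometry.z) <= p.z_stack_max
            assert s.geometry.rho <= p.rho_stack_max


class TestCanonicalRule:
    @pytest.mark.parametrize("bi,bj,ei,ej,expect", [
        ("G", "C", "WC", "WC", True),
        ("A", "U", "WC", "WC", True),
        ("G", "U", "WC", "WC", True),
        ("U", "G", "WC", "WC", True),
        ("A", "G", "WC", "WC", False),          # bases not canonical
        ("G", "C", "Hoogsteen", "WC", False),   # edge not WC
        ("A", "U", "WC", "Sugar", False),
    ])
    def test_pure_function_of_bases_and_edges(self, bi, bj, ei, ej, expect):
        assert is_canonical(bi, bj, ei, ej) is expect


class TestDssrIngestion:
    def test_minimal_pair_record(self, tmp_path):
        doc = {"pairs": [{"nt1": "A.G1", "nt2": "A.C12", "bp": "G-C", "LW": "cWW"}]}
        p = tmp_path / "one.json"
        p.write_text(json.dumps(doc))
        pairs, stacks, motifs = ingest_dssr_json(p)
        assert len(pairs) == 1 and stacks == [] and motifs == {}
        bp = pairs[0]
        assert bp.bases == ("G", "C") and bp.canonical and bp.lw_label == "cWW"
        assert bp.source == "dssr" and bp.i < bp.j

    def test_zero_pairs_allowed(self, tmp_path):
        p = tmp_path / "zero.json"
        p.write_text(json.dumps({"pairs": []}))
        pairs, stacks, motifs = ingest_dssr_json(p)
        assert pairs == [] and stacks == []

    def test_noncanonical_lw_class(self, tmp_path):
        doc = {"pairs": [{"nt1": "A.A3", "nt2": "A.G9", "bp": "A-G", "LW": "tSS"}]}
        p = tmp_path / "nc.json"
        p.write_text(json.dumps(doc))
        pairs, _, _ = ingest_dssr_json(p)
        assert pairs[0].canonical is False
        assert pairs[0].edges == ("Sugar", "Sugar")

    def test_malformed_json_and_missing_pairs_key(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(IngestionError):
            ingest_dssr_json(bad)
        nop = tmp_path / "nop.json"
        nop.write_text(json.dumps({"stems": []}))
        with pytest.raises(IngestionError, match="pairs"):
            ingest_dssr_json(nop)

    def test_roundtrip_export_then_ingest(self, tmp_path, wobble_duplex):
        st, _ = wobble_duplex
        pairs = detect_base_pairs(st)
        stacks = detect_stacking(st)
        out = tmp_path / "ann.json"
        export_annotations(st, pairs, stacks, out)
        pairs2, stacks2, _ = ingest_dssr_json(out, st)
        assert sorted((p.i, p.j) for p in pairs2) == sorted((p.i, p.j) for p in pairs)
        assert [p.canonical for p in sorted(pairs2, key=lambda q: q.i)] == \
               [p.canonical for p in sorted(pairs, key=lambda q: q.i)]
        assert sorted((s.i, s.j) for s in stacks2) == sorted((s.i, s.j) for s in stacks)

    def test_reconcile_reports_disagreements(self, tmp_path, gc_duplex):
        st, truth = gc_duplex
        builtin = detect_base_pairs(st)
        doc = {"pairs": [{"nt1": "A.G1",
                          "nt2": f"B.C{st.residues[truth.pairs[0][1]].seq_id}",
                          "bp": "G-C", "LW": "cWW"}]}
        p = tmp_path / "partial.json"
        p.write_text(json.dumps(doc))
        dssr, _, _ = ingest_dssr_json(p, st)
        rep = reconcile(dssr, builtin)
        assert rep["agree"] == [truth.pairs[0]]
        assert len(rep["builtin_only"]) == len(truth.pairs) - 1
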