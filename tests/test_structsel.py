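"""Structure candidates, residue maps, utility scoring and greedy selection."""

import csv

import numpy as np
import pytest

from vustruct.config import DEFAULT_CONFIG, load_config
from vustruct.structsel import (
    MapSegment,
    ResidueMap,
    StructureCandidate,
    candidate_utility,
    load_candidates,
    map_residue,
    overlap_fraction,
    select_structures,
)
from vustruct.validation import (
    brute_force_best,
    random_candidates,
    selection_oracle_trial,
    set_utility,
)


def mk_candidate(sid="S1", source="PDB", method="xray", quality=1.8, oligo=1,
                 start=1, length=100, chains=None):
    chains = chains or [chr(ord("A") + i) for i in range(oligo)]
    segs = [MapSegment(c, start, start, length) for c in chains]
    return StructureCandidate(sid, source, method, quality, oligo, "", ResidueMap(sid, segs))


class TestResidueMap:
    def test_segment_arithmetic(self):
        rm = ResidueMap("S", [MapSegment("A", 10, 110, 41)])  # 10..50 -> 110..150
        (addr,) = map_residue(25, rm)
        assert (addr.chain, addr.residue_number) == ("A", 125)

    def test_unmapped_position(self):
        rm = ResidueMap("S", [MapSegment("A", 10, 10, 41)])
        assert map_residue(5, rm) == []

    def test_homodimer_fan_out(self):
        rm = ResidueMap("S", [MapSegment("A", 1, 1, 50), MapSegment("B", 1, 1, 50)])
        addrs = map_residue(20, rm)
        assert [(a.chain, a.residue_number) for a in addrs] == [("A", 20), ("B", 20)]

    def test_double_mapping_within_chain_rejected(self):
        with pytest.raises(ValueError):
            ResidueMap("S", [MapSegment("A", 1, 1, 50), MapSegment("A", 25, 200, 50)])

    def test_inverse_round_trip(self):
        rm = ResidueMap("S", [MapSegment("A", 10, 110, 41), MapSegment("A", 60, 210, 20)])
        for pos in list(range(10, 51)) + list(range(60, 80)):
            (addr,) = map_residue(pos, rm)
            assert rm.to_transcript(addr.chain, addr.residue_number) == pos


class TestUtility:
    def test_lone_covering_xray_scores_six(self):
        """1.8 A X-ray covering the variant, empty selection: 4+1+1+0-0."""
        c = mk_candidate(quality=1.8)
        assert candidate_utility(c, 50, []) == pytest.approx(6.0)

    def test_duplicate_scores_strictly_lower(self):
        c1 = mk_candidate("S1")
        c2 = mk_candidate("S2")
        first = candidate_utility(c1, 50, [])
        dup = candidate_utility(c2, 50, [c1])
        assert dup < first

    def test_dimer_beats_identical_monomer_by_w_mult(self):
        mono = mk_candidate("S1", oligo=1)
        dim = mk_candidate("S2", oligo=2)
        diff = candidate_utility(dim, 50, []) - candidate_utility(mono, 50, [])
        assert diff == pytest.approx(DEFAULT_CONFIG.w_mult)

    def test_quality_normalization_bounds(self):
        assert mk_candidate(quality=1.5).normalized_quality() == 1.0
        assert mk_candidate(quality=4.5).normalized_quality() == 0.0
        assert mk_candidate(quality=3.0).normalized_quality() == pytest.approx(0.5)
        model = mk_candidate(source="ALPHAFOLD", method="model", quality=85.0)
        assert model.normalized_quality() == pytest.approx(0.85)

    def test_overlap_fraction_jaccard(self):
        big = mk_candidate("S1", start=1, length=80)
        small = mk_candidate("S2", start=11, length=20)
        assert overlap_fraction(small, [big]) == pytest.approx(20 / 80)
        assert overlap_fraction(big, [small]) == pytest.approx(20 / 80)
        assert overlap_fraction(small, []) == 0.0


class TestSelection:
    def test_single_covering_candidate_selected(self):
        c = mk_candidate()
        sel = select_structures([c], 50, max_k=3)
        assert [s.structure_id for s in sel.selected] == ["S1"]
        assert sel.rationale[0].covers_variant

    def test_byte_identical_duplicates_collapse_to_one(self):
        c1 = mk_candidate("S1")
        c2 = mk_candidate("S1b")
        sel = select_structures([c1, c2], 50, max_k=3)
        assert len(sel.selected) == 1

    def test_covering_structure_always_present(self):
        """Whenever any candidate covers the variant the selection contains a
        covering structure (500 random instances)."""
        rng = np.random.default_rng(0)
        for _ in range(500):
            cands = random_candidates(rng, int(rng.integers(1, 9)))
            pos = int(rng.integers(1, 101))
            sel = select_structures(cands, pos, max_k=int(rng.integers(1, 4)))
            if any(c.covers(pos) for c in cands):
                assert any(c.covers(pos) for c in sel.selected)

    def test_deterministic_for_identical_inputs(self):
        rng = np.random.default_rng(3)
        cands = random_candidates(rng, 8)
        a = select_structures(cands, 40, max_k=3)
        b = select_structures(list(cands), 40, max_k=3)
        assert [c.structure_id for c in a.selected] == [c.structure_id for c in b.selected]
        assert [(r.structure_id, r.marginal_utility, r.reasons) for r in a.rationale] == [
            (r.structure_id, r.marginal_utility, r.reasons) for r in b.rationale
        ]

    def test_empty_candidates_yield_no_coverage_note(self):
        sel = select_structures([], 10, max_k=3)
        assert sel.selected == [] and "no structural coverage" in sel.notes[0]

    def test_greedy_within_guarantee_of_brute_force(self):
        """Greedy set utility stays within (1-1/e) of the exhaustive optimum
        on random small instances scored identically."""
        r = selection_oracle_trial(n_instances=60, seed=1)
        assert r["coverage_violations"] == 0
        assert r["worst_ratio"] >= r["guarantee"]

    def test_weights_configurable(self):
        cfg = load_config(None, w_mult=10.0)
        mono = mk_candidate("S1", quality=1.5)
        dim = mk_candidate("S2", quality=4.5, oligo=2, method="cryoem")
        sel = select_structures([mono, dim], 50, max_k=1, cfg=cfg)
        assert sel.selected[0].structure_id == "S2"


class TestLoadCandidates:
    def _write_catalogs(self, tmp_path, rows):
        cat = tmp_path / "structure_catalog.csv"
        with open(cat, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["protein_id", "structure_id", "source",
                                               "method", "quality", "oligomeric_state", "coords_path"])
            w.writeheader()
            for r in rows:
                w.writerow(r)
        aln = tmp_path / "alignment_catalog.csv"
        with open(aln, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["structure_id", "chain", "seg_start_transcript",
                                               "seg_start_residue", "seg_length"])
            w.writeheader()
            for r in rows:
                w.writerow({"structure_id": r["structure_id"], "chain": "A",
                            "seg_start_transcript": 1, "seg_start_residue": 1, "seg_length": 50})
        return cat, aln

    def _rows(self, tmp_path):
        (tmp_path / "x.pdb").write_text("END\n")
        return [
            {"protein_id": "P1", "structure_id": "1ABC", "source": "PDB", "method": "xray",
             "quality": 2.0, "oligomeric_state": 1, "coords_path": "x.pdb"},
            {"protein_id": "P1", "structure_id": "AF_P1", "source": "ALPHAFOLD", "method": "model",
             "quality": 90.0, "oligomeric_state": 1, "coords_path": "x.pdb"},
        ]

    def test_alphafold_attached_to_canonical_only(self, tmp_path):
        cat, aln = self._write_catalogs(tmp_path, self._rows(tmp_path))
        cands, _ = load_candidates("P1", cat, aln)
        assert {c.structure_id for c in cands} == {"1ABC", "AF_P1"}
        cands2, _ = load_candidates("P1-2", cat, aln)
        assert {c.structure_id for c in cands2} == {"1ABC"}

    def test_missing_coordinates_dropped_with_warning(self, tmp_path):
        rows = self._rows(tmp_path)
        rows[0]["coords_path"] = "gone.pdb"
        cat, aln = self._write_catalogs(tmp_path, rows)
        cands, warns = load_candidates("P1", cat, aln)
        assert {c.structure_id for c in cands} == {"AF_P1"}
        assert any("gone.pdb" in w for w in warns)

    def test_empty_catalog(self, tmp_path):
        cat, aln = self._write_catalogs(tmp_path, [])
        cands, warns = load_candidates("P1", cat, aln)
        assert cands == []
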