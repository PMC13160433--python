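"""Cross-reference classification, curated filtering, isoform expansion."""

import json

import pytest

from vustruct.ingest import CaseInput, ProteinVariant
from vustruct.validation import xref_census_trial
from vustruct.xref import (
    Isoform,
    IsoformSet,
    classify_xref,
    expand_isoforms,
    filter_curated,
    halt_on_disconnect,
    load_isoform_fasta,
    load_xref_catalog,
    map_position,
    validate_reference_residue,
)


@pytest.mark.parametrize(
    "tpep,cpep,status",
    [
        ("MACK", "MACK", "PERFECT"),
        ("MACK", "MARK", "LEN_MATCH_SEQ_MISMATCH"),
        ("MACK", "MAC", "LEN_MISMATCH"),
        ("MACK", None, "NO_XREF"),
    ],
)
def test_classify_xref_four_way(tpep, cpep, status):
    assert classify_xref(tpep, cpep) == status


from hypothesis import given, settings
from hypothesis import strategies as st

_peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


@settings(max_examples=200, derandomize=True)
@given(tpep=_peptides, cpep=st.none() | _peptides)
def test_classify_is_total_and_consistent(tpep, cpep):
    """Every sequence pair maps to exactly one of the four statuses, and the
    status agrees with the defining length/equality relations."""
    status = classify_xref(tpep, cpep)
    if cpep is None:
        assert status == "NO_XREF"
    elif tpep == cpep:
        assert status == "PERFECT"
    elif len(tpep) == len(cpep):
        assert status == "LEN_MATCH_SEQ_MISMATCH"
    else:
        assert status == "LEN_MISMATCH"


def test_classify_is_total_and_census_conserved():
    """On a planted fixture census the four class counts are recovered
    exactly and sum to the record total."""
    r = xref_census_trial(n_records=40, seed=9)
    assert r["exact"] and r["total_conserved"]
    assert sum(r["recovered"].values()) == r["n_records"]


def _mkcase(statuses):
    xrefs = {}
    variants = []
    catalog_rows = {
        "PERFECT": ("MACK", "MACK"),
        "NO_XREF": ("MACK", None),
        "LEN_MISMATCH": ("MACK", "MAC"),
        "LEN_MATCH_SEQ_MISMATCH": ("MACK", "MARK"),
    }
    from vustruct.xref import XrefRecord

    for i, s in enumerate(statuses):
        tid = f"T{i}"
        tpep, cpep = catalog_rows[s]
        xrefs[tid] = XrefRecord(tid, f"P{i}", tpep, cpep)
        variants.append(ProteinVariant("G", "", tid, 2, "A", "V"))
    return CaseInput("c", variants, ["genomic"] * len(variants)), xrefs


class TestFilterCurated:
    def test_mixed_statuses(self):
        case, xrefs = _mkcase(["PERFECT", "NO_XREF", "LEN_MISMATCH"])
        retained, rejected = filter_curated(case, xrefs)
        assert len(retained) == 1 and len(rejected) == 2
        assert retained[0].protein_id == "P0"  # curated id assigned
        assert {r.reason for r in rejected} == {"NO_XREF", "LEN_MISMATCH"}

    def test_conservation(self):
        case, xrefs = _mkcase(
            ["PERFECT", "PERFECT", "NO_XREF", "LEN_MATCH_SEQ_MISMATCH", "LEN_MISMATCH"]
        )
        retained, rejected = filter_curated(case, xrefs)
        assert len(retained) + len(rejected) == len(case.variants)

    def test_all_perfect_empty_rejections(self):
        case, xrefs = _mkcase(["PERFECT", "PERFECT"])
        retained, rejected = filter_curated(case, xrefs)
        assert len(retained) == 2 and rejected == []

    def test_unknown_transcript_rejected_as_no_xref(self):
        case, _ = _mkcase(["PERFECT"])
        retained, rejected = filter_curated(case, {})
        assert retained == [] and rejected[0].reason == "NO_XREF"


class TestHalt:
    def test_single_rejection_stops(self):
        case, xrefs = _mkcase(["NO_XREF"])
        _, rejected = filter_curated(case, xrefs)
        report = halt_on_disconnect(case, rejected, n_retained=0)
        assert report is not None and report.stopped
        data = json.loads(report.to_json())
        assert data["rejections"]["NO_XREF"][0]["transcript_id"] == "T0"

    def test_no_rejections_no_report(self):
        case, xrefs = _mkcase(["PERFECT"])
        _, rejected = filter_curated(case, xrefs)
        assert halt_on_disconnect(case, rejected, n_retained=1) is None

    def test_mixed_reasons_grouped_and_force_proceeds(self):
        case, xrefs = _mkcase(["NO_XREF", "LEN_MISMATCH", "NO_XREF", "PERFECT"])
        _, rejected = filter_curated(case, xrefs)
        report = halt_on_disconnect(case, rejected, n_retained=1, force=True)
        assert not report.stopped
        assert len(report.rejections_by_reason["NO_XREF"]) == 2
        assert len(report.rejections_by_reason["LEN_MISMATCH"]) == 1


CANON = "MACKWLDERFGHISTV"


class TestExpandIsoforms:
    def test_canonical_only_singleton_identity(self):
        isoset = IsoformSet("P1", [Isoform("P1", CANON, True)])
        v = ProteinVariant("G", "P1", "T1", 3, "C", "Y")
        exp = expand_isoforms(v, isoset)
        assert [x.protein_id for x in exp.variants] == ["P1"]
        assert exp.variants[0].position == 3

    def test_cterminal_extension_keeps_position(self):
        isoset = IsoformSet(
            "P1",
            [Isoform("P1", CANON, True), Isoform("P1-2", CANON + "GGGGS", False)],
        )
        v = ProteinVariant("G", "P1", "T1", 5, "W", "R")
        exp = expand_isoforms(v, isoset)
        assert {(x.protein_id, x.position) for x in exp.variants} == {("P1", 5), ("P1-2", 5)}

    def test_internal_deletion_removing_variant_is_skipped(self):
        # isoform lacks residues 4..8 (the exon carrying W5)
        iso_pep = CANON[:3] + CANON[8:]
        isoset = IsoformSet(
            "P1", [Isoform("P1", CANON, True), Isoform("P1-2", iso_pep, False)]
        )
        v = ProteinVariant("G", "P1", "T1", 5, "W", "R")
        exp = expand_isoforms(v, isoset)
        assert [x.protein_id for x in exp.variants] == ["P1"]
        assert exp.skipped and exp.skipped[0][0] == "P1-2"

    def test_internal_deletion_downstream_position_shifts(self):
        iso_pep = CANON[:3] + CANON[8:]  # delete 5 residues
        isoset = IsoformSet(
            "P1", [Isoform("P1", CANON, True), Isoform("P1-2", iso_pep, False)]
        )
        v = ProteinVariant("G", "P1", "T1", 10, CANON[9], "A" if CANON[9] != "A" else "G")
        exp = expand_isoforms(v, isoset)
        by_id = {x.protein_id: x.position for x in exp.variants}
        assert by_id == {"P1": 10, "P1-2": 5}

    def test_identical_peptides_identical_positions(self):
        isoset = IsoformSet(
            "P1",
            [Isoform("P1", CANON, True), Isoform("P1-2", CANON, False),
             Isoform("P1-3", CANON, False)],
        )
        v = ProteinVariant("G", "P1", "T1", 7, CANON[6], "A")
        exp = expand_isoforms(v, isoset)
        assert len(exp.variants) == 3
        assert {x.position for x in exp.variants} == {7}

    def test_variant_not_matching_canonical_raises(self):
        isoset = IsoformSet("P1", [Isoform("P1", CANON, True)])
        v = ProteinVariant("G", "P1", "T1", 3, "W", "Y")  # canonical has C at 3
        with pytest.raises(ValueError):
            expand_isoforms(v, isoset)


def test_map_position_prefix_fast_path_and_alignment():
    assert map_position("MACK", "MACK", 3) == 3
    assert map_position("MACKW", "MAKW", 5) == 4  # C deleted
    assert map_position("MACK", "MAK", 3) is None or map_position("MACK", "MAK", 3) == 3


class TestValidateReferenceResidue:
    def test_ok(self):
        assert validate_reference_residue(ProteinVariant("G", "P", "T", 2, "A", "V"), "MACK").ok

    def test_mismatch_names_expected(self):
        r = validate_reference_residue(ProteinVariant("G", "P", "T", 2, "R", "V"), "MACK")
        assert not r.ok and "A" in r.detail

    def test_out_of_range(self):
        r = validate_reference_residue(ProteinVariant("G", "P", "T", 9, "K", "E"), "MACK")
        assert not r.ok and "beyond" in r.detail


def test_catalog_and_fasta_loaders(bundle):
    xrefs = load_xref_catalog(bundle["dir"] / "xref_catalog.csv")
    isosets = load_isoform_fasta(bundle["dir"] / "isoforms.fasta")
    assert len(xrefs) == 6
    for s in isosets.values():
        assert sum(i.is_canonical for i in s.isoforms) == 1
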