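"""Ingest: VCF parsing, consequence calling, and the case-CSV dialect."""

import numpy as np
import pytest

from vustruct.ingest import (
    CaseInput,
    GenomicVariant,
    ProteinVariant,
    ReferenceMismatchError,
    TranscriptModel,
    annotate_consequence,
    load_annotated_table,
    parse_aa_change,
    parse_vcf,
    parse_vustruct_csv,
    write_vustruct_csv,
)
from vustruct.validation import consequence_oracle_trial

from conftest import write_vcf

# hand-checkable toy CDS: ATG GCT TAA -> peptide "MA", genomic 101..109, + strand
TOY = TranscriptModel(
    transcript_id="T1", gene="G1", chrom="1", strand="+",
    cds_intervals=((101, 109),), cds_sequence="ATGGCTTAA", peptide="MA",
)
# the same coding sequence laid on the minus strand at 201..209
TOY_MINUS = TranscriptModel(
    transcript_id="T1m", gene="G1", chrom="1", strand="-",
    cds_intervals=((201, 209),), cds_sequence="ATGGCTTAA", peptide="MA",
)


class TestParseVcf:
    def test_snv_and_multiallelic_split(self, tmp_path):
        p = write_vcf(
            tmp_path / "a.vcf",
            [("1", 1000, ".", "A", "G", ".", ".", "INH=maternal"),
             ("1", 1001, ".", "A", "G,T", ".", ".", ".")],
        )
        variants, skipped = parse_vcf(p)
        assert [(v.pos, v.ref, v.alt) for v in variants] == [
            (1000, "A", "G"), (1001, "A", "G"), (1001, "A", "T"),
        ]
        assert variants[0].inheritance == "maternal"
        assert variants[1].inheritance == "unknown"
        assert skipped == []

    def test_non_snv_records_skipped_with_reason(self, tmp_path):
        p = write_vcf(tmp_path / "b.vcf", [("1", 1000, ".", "AT", "A", ".", ".", ".")])
        variants, skipped = parse_vcf(p)
        assert variants == []
        assert len(skipped) == 1 and skipped[0][2] == "indel"

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_vcf(tmp_path / "nope.vcf")


class TestAnnotateConsequence:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected_class,change",
        [
            (105, "C", "T", "missense", (2, "A", "V")),  # GCT -> GTT
            (106, "T", "C", "synonymous", None),  # GCT -> GCC
            (100, "A", "G", "non_coding", None),  # upstream of the CDS
            (104, "G", "T", "missense", (2, "A", "S")),  # GCT -> TCT
        ],
    )
    def test_plus_strand_classes(self, pos, ref, alt, expected_class, change):
        c = annotate_consequence(GenomicVariant("1", pos, ref, alt), TOY)
        assert c.consequence_class == expected_class
        if change:
            pv = c.protein_variant
            assert (pv.position, pv.ref_aa, pv.alt_aa) == change
        else:
            assert c.protein_variant is None

    def test_stop_codon_classes(self):
        # pos 107 is T of the TAA stop: T->C makes CAA (Q): stop_lost
        c = annotate_consequence(GenomicVariant("1", 107, "T", "C"), TOY)
        assert c.consequence_class == "stop_lost"
        # pos 106 T->A makes GCT -> GAT? no: 106 is codon2 base3; test nonsense at 103 G->T: TAA? GCT codon2... use 102 T->A: ATG->AAG (M->K missense at pos1)
        c = annotate_consequence(GenomicVariant("1", 102, "T", "A"), TOY)
        assert c.consequence_class == "missense"
        assert c.protein_variant.position == 1

    def test_reference_mismatch_raises_with_both_bases(self):
        with pytest.raises(ReferenceMismatchError) as ei:
            annotate_consequence(GenomicVariant("1", 105, "G", "T"), TOY)
        assert ei.value.observed == "G" and ei.value.expected == "C"

    def test_strand_symmetry(self):
        """A minus-strand transcript carrying the same coding sequence yields
        identical protein consequences for the complemented variants."""
        # plus: pos 105 (offset 4, base C); minus: offset 4 -> pos 209-4=205, base complement
        for off, alt_cds in [(4, "T"), (5, "C"), (1, "A")]:
            ref_cds = TOY.cds_sequence[off]
            plus = annotate_consequence(
                GenomicVariant("1", 101 + off, ref_cds, alt_cds), TOY
            )
            comp = str.maketrans("ACGT", "TGCA")
            minus = annotate_consequence(
                GenomicVariant("1", 209 - off, ref_cds.translate(comp), alt_cds.translate(comp)),
                TOY_MINUS,
            )
            assert plus.consequence_class == minus.consequence_class
            if plus.protein_variant:
                assert (
                    plus.protein_variant.position,
                    plus.protein_variant.ref_aa,
                    plus.protein_variant.alt_aa,
                ) == (
                    minus.protein_variant.position,
                    minus.protein_variant.ref_aa,
                    minus.protein_variant.alt_aa,
                )

    def test_split_cds_across_two_exons(self):
        t = TranscriptModel(
            transcript_id="T2", gene="G2", chrom="2", strand="+",
            cds_intervals=((101, 104), (201, 205)), cds_sequence="ATGGCTTAA", peptide="MA",
        )
        # offset 4 (the C of GCT) sits at genomic 201 in the second exon
        c = annotate_consequence(GenomicVariant("2", 201, "C", "T"), t)
        assert c.consequence_class == "missense"
        assert (c.protein_variant.position, c.protein_variant.alt_aa) == (2, "V")
        # intronic gap position is non-coding
        assert annotate_consequence(GenomicVariant("2", 150, "A", "G"), t).consequence_class == "non_coding"

    def test_codon_caller_agrees_with_full_translation_oracle(self):
        r = consequence_oracle_trial(n_snvs=300, seed=2)
        assert r["n_agree"] == r["n"]


class TestCaseCsv:
    def test_compact_change_row(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "gene,transcript_id,protein_id,aa_change,inheritance\n"
            "HFE,T1,P1,C282Y,maternal\n"
            "HFE,T1,P1,H63D,\n"
        )
        case, errors = parse_vustruct_csv(p, case_id="c1")
        assert errors == []
        assert case.variants[0] == ProteinVariant("HFE", "P1", "T1", 282, "C", "Y", "maternal")
        assert case.variants[1].inheritance == "unknown"

    def test_malformed_change_excluded_row_level(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "gene,transcript_id,protein_id,aa_change,inheritance\n"
            "HFE,T1,P1,282CY,\nHFE,T1,P1,C282Y,\n"
        )
        case, errors = parse_vustruct_csv(p)
        assert len(case.variants) == 1 and len(errors) == 1
        assert errors[0][0] == 1

    def test_split_column_form(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "gene,transcript_id,protein_id,ref_aa,position,alt_aa,inheritance\n"
            "HFE,T1,P1,C,282,Y,paternal\n"
        )
        case, errors = parse_vustruct_csv(p)
        assert errors == [] and case.variants[0].label == "C282Y"

    def test_round_trip_identity_randomized(self, tmp_path):
        """parse(write(c)) == c exactly, over randomized cases."""
        rng = np.random.default_rng(42)
        aas = sorted("ACDEFGHIKLMNPQRSTVWY")
        inh = ["maternal", "paternal", "de_novo", "unknown"]
        for trial in range(100):
            n = int(rng.integers(0, 8))
            variants, prov = [], []
            for j in range(n):
                ref, alt = rng.choice(aas, size=2, replace=False)
                variants.append(
                    ProteinVariant(
                        gene=f"G{rng.integers(1, 5)}",
                        protein_id=f"P{j}" + ("-2" if rng.random() < 0.3 else ""),
                        transcript_id=f"T{j}",
                        position=int(rng.integers(1, 500)),
                        ref_aa=str(ref), alt_aa=str(alt),
                        inheritance=inh[int(rng.integers(0, 4))],
                    )
                )
                prov.append("genomic" if rng.random() < 0.5 else "proteomic")
            case = CaseInput(f"case{trial}", variants, prov)
            path = tmp_path / f"rt{trial}.csv"
            write_vustruct_csv(case, path)
            reparsed, errors = parse_vustruct_csv(path, case_id=case.case_id)
            assert errors == []
            assert reparsed == case

    def test_empty_case_round_trips(self, tmp_path):
        case = CaseInput("empty", [], [])
        path = tmp_path / "e.csv"
        write_vustruct_csv(case, path)
        reparsed, _ = parse_vustruct_csv(path, case_id="empty")
        assert reparsed == case and reparsed.variants == []

    def test_deduplication_keeps_first_and_logs(self):
        v = ProteinVariant("G", "P1", "T1", 10, "A", "V", "maternal")
        dup = ProteinVariant("G", "P1", "T1", 10, "A", "V", "paternal")
        case = CaseInput("c", [v, dup], ["proteomic", "proteomic"])
        assert case.variants == [v]
        assert case.duplicates == [dup]

    def test_annotated_table_import(self, tmp_path):
        p = tmp_path / "vep.csv"
        p.write_text("transcript_id,position,ref_aa,alt_aa,gene\nT9,44,R,W,GENE9\n")
        case = load_annotated_table(p, "c")
        assert case.variants[0].label == "R44W"
        assert case.provenance == ["annotated"]


@pytest.mark.parametrize(
    "text,expected",
    [("C282Y", ("C", 282, "Y")), ("a2v", ("A", 2, "V"))],
)
def test_parse_aa_change_accepts_compact_forms(text, expected):
    assert parse_aa_change(text) == expected


@pytest.mark.parametrize("text", ["282CY", "C282", "CY", "C282B"])
def test_parse_aa_change_rejects_malformed(text):
    with pytest.raises(ValueError):
        parse_aa_change(text)


from hypothesis import given, settings
from hypothesis import strategies as st

_aa = st.sampled_from(sorted("ACDEFGHIKLMNPQRSTVWY"))


@settings(max_examples=200, derandomize=True)
@given(ref=_aa, pos=st.integers(1, 99999), alt=_aa)
def test_aa_change_label_round_trips(ref, pos, alt):
    assert parse_aa_change(f"{ref}{pos}{alt}") == (ref, pos, alt)
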