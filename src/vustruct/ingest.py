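"""Case ingestion: VCF / case-CSV parsing and missense consequence calling.

Variants enter the pipeline either as genomic SNVs (VCF) or directly as
protein-level substitutions in the comma-delimited "vustruct.csv" dialect.
Genomic variants are located inside toy transcript CDS models, the affected
codon is re-translated, and missense changes become :class:`ProteinVariant`
records — the pipeline's atom of work.

Coordinate conventions: VCF and CDS intervals are 1-based (intervals closed);
protein positions are 1-based, matching standard mutation nomenclature
(e.g. ``C282Y``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from cyvcf2 import VCF

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = set("ACGT")
INHERITANCE_VALUES = ("maternal", "paternal", "de_novo", "unknown")
CONSEQUENCE_CLASSES = ("missense", "synonymous", "nonsense", "stop_lost", "non_coding")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: fixed column order of the vustruct.csv dialect (the trailing provenance
#: column is optional on input and always written on output)
VUSTRUCT_CSV_COLUMNS = (
    "gene",
    "transcript_id",
    "protein_id",
    "aa_change",
    "inheritance",
    "provenance",
)


class IngestError(Exception):
    """Base class for ingest failures."""


class VcfParseError(IngestError):
    """Malformed VCF content; carries the 1-based record index where known."""


class ReferenceMismatchError(IngestError):
    """VCF reference base disagrees with the transcript CDS sequence."""

    def __init__(self, expected: str, observed: str, pos: int):
        self.expected, self.observed, self.pos = expected, observed, pos
        super().__init__(
            f"reference mismatch at genomic position {pos}: "
            f"CDS has {expected}, VCF claims {observed}"
        )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide substitution in genomic coordinates (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    inheritance: str = "unknown"

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("genomic position must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - NUCLEOTIDES or set(self.alt) - NUCLEOTIDES:
            raise ValueError(f"alleles must be over ACGT: {self.ref}>{self.alt}")
        if self.inheritance not in INHERITANCE_VALUES:
            raise ValueError(f"bad inheritance {self.inheritance!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class TranscriptModel:
    """A toy coding transcript: CDS intervals on a chromosome plus sequence.

    ``cds_intervals`` are 1-based closed genomic intervals listed in
    transcription (5'→3') order — ascending genomic coordinates on the plus
    strand, descending on the minus strand.  ``cds_sequence`` is the coding
    sequence in reading-frame order, including the stop codon;
    ``peptide`` is its translation with the trailing stop removed.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_sequence: str
    peptide: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        object.__setattr__(
            self, "cds_intervals", tuple(tuple(iv) for iv in self.cds_intervals)
        )
        total = sum(e - s + 1 for s, e in self.cds_intervals)
        if total != len(self.cds_sequence):
            raise ValueError("CDS interval lengths do not sum to sequence length")
        if len(self.cds_sequence) % 3:
            raise ValueError("CDS length not divisible by 3")
        translated = translate_cds(self.cds_sequence)
        if translated != self.peptide:
            raise ValueError("peptide does not match translated CDS")

    def cds_offset(self, chrom: str, pos: int) -> int | None:
        """0-based offset of a genomic position into the coding sequence.

        Returns None when the position lies outside every CDS interval.
        """
        if chrom != self.chrom:
            return None
        offset = 0
        for start, end in self.cds_intervals:
            if start <= pos <= end:
                if self.strand == "+":
                    return offset + (pos - start)
                return offset + (end - pos)
            offset += end - start + 1
        return None


@dataclass(frozen=True)
class ProteinVariant:
    """An amino-acid substitution on a specific protein isoform."""

    gene: str
    protein_id: str
    transcript_id: str
    position: int
    ref_aa: str
    alt_aa: str
    inheritance: str = "unknown"
    #: label of the canonical-isoform variant this one was expanded from
    #: ("" when the variant itself is the original input)
    canonical_label: str = ""

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")
        if self.position < 1:
            raise ValueError("protein position must be >= 1")
        if self.ref_aa not in AA_ALPHABET or self.alt_aa not in AA_ALPHABET:
            raise ValueError(f"amino acids must be one of the 20: {self.ref_aa}>{self.alt_aa}")
        if self.inheritance not in INHERITANCE_VALUES:
            raise ValueError(f"bad inheritance {self.inheritance!r}")

    @property
    def label(self) -> str:
        """Compact HGVS-like label, e.g. ``C282Y``."""
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def group_label(self) -> str:
        """Identity of the underlying case variant across isoform expansion."""
        return self.canonical_label or self.label

    @property
    def base_protein_id(self) -> str:
        """Protein identifier with any '-N' isoform suffix stripped."""
        return strip_isoform_suffix(self.protein_id)


def strip_isoform_suffix(protein_id: str) -> str:
    m = re.fullmatch(r"(.+)-(\d+)", protein_id)
    return m.group(1) if m else protein_id


def isoform_number(protein_id: str) -> int:
    """Isoform index: unsuffixed and '-1' are canonical (1)."""
    m = re.fullmatch(r".+-(\d+)", protein_id)
    return int(m.group(1)) if m else 1


@dataclass
class CaseInput:
    """A case: a label plus a de-duplicated list of protein variants.

    ``provenance`` records, per variant, whether it arrived from genomic
    (VCF) or proteomic (CSV) input.
    """

    case_id: str
    variants: list[ProteinVariant] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.provenance:
            self.provenance = ["proteomic"] * len(self.variants)
        if len(self.provenance) != len(self.variants):
            raise ValueError("provenance must parallel variants")
        self.variants, self.provenance, self.duplicates = _dedupe(
            self.variants, self.provenance
        )

    def __eq__(self, other):
        if not isinstance(other, CaseInput):
            return NotImplemented
        return (
            self.case_id == other.case_id
            and self.variants == other.variants
            and self.provenance == other.provenance
        )


def _dedupe(variants, provenance):
    """Drop repeats of (protein_id, position, ref, alt), keeping the first.

    Variants without an assigned protein_id (pre-xref genomic input) are
    keyed on their transcript instead, so different genes never collapse.
    """
    seen, kept_v, kept_p, dups = set(), [], [], []
    for v, p in zip(variants, provenance):
        key = (v.protein_id or v.transcript_id, v.position, v.ref_aa, v.alt_aa)
        if key in seen:
            dups.append(v)
            continue
        seen.add(key)
        kept_v.append(v)
        kept_p.append(p)
    return kept_v, kept_p, dups


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------


def parse_vcf(path: str | Path) -> tuple[list[GenomicVariant], list[tuple[int, str, str]]]:
    """Read SNVs from a VCF file.

    Multi-allelic records are split into one variant per alternate allele.
    Non-SNV alleles (indels, MNVs, symbolic) are not errors: they come back
    in the ``skipped`` list as ``(record_index, description, reason)``.
    Parental inheritance is read from an ``INH`` INFO tag when present.

    Raises VcfParseError on malformed content, naming the 1-based record
    index (the underlying htslib reader does not expose raw line numbers).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    variants: list[GenomicVariant] = []
    skipped: list[tuple[int, str, str]] = []
    try:
        reader = VCF(str(path))
    except Exception as exc:  # htslib raises bare Exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    idx = 0
    try:
        for rec in reader:
            idx += 1
            inh = rec.INFO.get("INH") or "unknown"
            if inh not in INHERITANCE_VALUES:
                inh = "unknown"
            ref = rec.REF
            for alt in rec.ALT:
                desc = f"{rec.CHROM}:{rec.POS} {ref}>{alt}"
                if len(ref) != 1 or len(alt) != 1 or set(alt) - NUCLEOTIDES:
                    reason = "indel" if len(ref) != len(alt) else "not a SNV"
                    skipped.append((idx, desc, reason))
                    continue
                if alt == ref:
                    skipped.append((idx, desc, "ref == alt"))
                    continue
                variants.append(
                    GenomicVariant(
                        chrom=str(rec.CHROM), pos=rec.POS, ref=ref, alt=alt,
                        inheritance=inh,
                    )
                )
    except Exception as exc:
        if isinstance(exc, (VcfParseError, ValueError)):
            raise VcfParseError(f"malformed VCF record {idx + 1}: {exc}") from exc
        raise VcfParseError(f"VCF parse failure at record {idx + 1}: {exc}") from exc
    finally:
        reader.close()
    return variants, skipped


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, trailing stop removed."""
    pep = str(Seq(cds).translate())
    return pep[:-1] if pep.endswith("*") else pep


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class Consequence:
    """Outcome of locating one genomic SNV inside one transcript model."""

    consequence_class: str  # missense | synonymous | nonsense | stop_lost | non_coding
    protein_variant: ProteinVariant | None = None
    codon_index: int | None = None  # 0-based
    ref_aa: str | None = None
    alt_aa: str | None = None


def annotate_consequence(
    v: GenomicVariant, t: TranscriptModel, protein_id: str = ""
) -> Consequence:
    """Classify a genomic SNV against one transcript's CDS.

    The variant is located strand-aware within the CDS intervals (minus-strand
    alleles are complemented), the containing codon is re-translated and the
    class read off the amino-acid change.  Positions outside every CDS
    interval — UTRs, introns, intergenic — are uniformly ``non_coding``.
    """
    if not v.is_snv:
        raise ValueError("consequence calling is defined for SNVs only")
    offset = t.cds_offset(v.chrom, v.pos)
    if offset is None:
        return Consequence("non_coding")
    ref_cds = v.ref if t.strand == "+" else complement(v.ref)
    alt_cds = v.alt if t.strand == "+" else complement(v.alt)
    if t.cds_sequence[offset] != ref_cds:
        raise ReferenceMismatchError(
            expected=t.cds_sequence[offset] if t.strand == "+" else complement(t.cds_sequence[offset]),
            observed=v.ref,
            pos=v.pos,
        )
    ci = offset // 3
    codon = t.cds_sequence[3 * ci : 3 * ci + 3]
    within = offset - 3 * ci
    mutated = codon[:within] + alt_cds + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    if ref_aa == alt_aa:
        return Consequence("synonymous", codon_index=ci, ref_aa=ref_aa, alt_aa=alt_aa)
    if alt_aa == "*":
        return Consequence("nonsense", codon_index=ci, ref_aa=ref_aa, alt_aa=alt_aa)
    if ref_aa == "*":
        return Consequence("stop_lost", codon_index=ci, ref_aa=ref_aa, alt_aa=alt_aa)
    pv = ProteinVariant(
        gene=t.gene,
        protein_id=protein_id,
        transcript_id=t.transcript_id,
        position=ci + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        inheritance=v.inheritance,
    )
    return Consequence("missense", protein_variant=pv, codon_index=ci, ref_aa=ref_aa, alt_aa=alt_aa)


def call_missense(
    genomic: Iterable[GenomicVariant],
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[ProteinVariant], list[tuple[GenomicVariant, str]]]:
    """Run consequence calling for each variant against every transcript.

    Only missense consequences are retained for structural analysis; each
    dropped (variant, transcript-or-reason) pair is reported.  A variant may
    legitimately yield several missense calls when transcripts overlap.
    """
    kept: list[ProteinVariant] = []
    dropped: list[tuple[GenomicVariant, str]] = []
    for gv in genomic:
        hit = False
        for t in transcripts:
            if t.cds_offset(gv.chrom, gv.pos) is None:
                continue
            c = annotate_consequence(gv, t)
            if c.consequence_class == "missense":
                kept.append(c.protein_variant)
                hit = True
            else:
                dropped.append((gv, f"{t.transcript_id}:{c.consequence_class}"))
                hit = True
        if not hit:
            dropped.append((gv, "non_coding"))
    return kept, dropped


# ---------------------------------------------------------------------------
# vustruct.csv dialect
# ---------------------------------------------------------------------------

_AA_CHANGE_RE = re.compile(r"([A-Za-z])(\d+)([A-Za-z])")


def parse_aa_change(text: str) -> tuple[str, int, str]:
    """Parse a compact substitution like ``C282Y`` into (ref, pos, alt)."""
    m = _AA_CHANGE_RE.fullmatch(text.strip())
    if not m:
        raise ValueError(f"cannot parse amino-acid change {text!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if ref not in AA_ALPHABET or alt not in AA_ALPHABET:
        raise ValueError(f"non-standard amino acid in change {text!r}")
    return ref, pos, alt


def parse_vustruct_csv(path: str | Path, case_id: str | None = None):
    """Load a case from the vustruct.csv dialect.

    Column order is fixed (see VUSTRUCT_CSV_COLUMNS); the amino-acid change is
    accepted either compact in ``aa_change`` (``C282Y``) or split across
    ``ref_aa``/``position``/``alt_aa`` columns.  Rows that fail to parse are
    excluded and reported — a bad row never aborts the whole case.

    Returns (CaseInput, row_errors) where row_errors is a list of
    (1-based data row number, message).
    """
    path = Path(path)
    variants: list[ProteinVariant] = []
    provenance: list[str] = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise IngestError(f"{path}: missing header row")
        fieldset = set(reader.fieldnames)
        split_form = {"ref_aa", "position", "alt_aa"} <= fieldset
        if "aa_change" not in fieldset and not split_form:
            raise IngestError(f"{path}: no aa_change (or ref_aa/position/alt_aa) columns")
        for i, row in enumerate(reader, start=1):
            try:
                if split_form and not row.get("aa_change"):
                    ref, pos, alt = row["ref_aa"].strip().upper(), int(row["position"]), row["alt_aa"].strip().upper()
                else:
                    ref, pos, alt = parse_aa_change(row["aa_change"])
                inh = (row.get("inheritance") or "").strip() or "unknown"
                if inh not in INHERITANCE_VALUES:
                    raise ValueError(f"bad inheritance {inh!r}")
                variants.append(
                    ProteinVariant(
                        gene=(row.get("gene") or "").strip(),
                        protein_id=(row.get("protein_id") or "").strip(),
                        transcript_id=(row.get("transcript_id") or "").strip(),
                        position=pos,
                        ref_aa=ref,
                        alt_aa=alt,
                        inheritance=inh,
                    )
                )
                provenance.append((row.get("provenance") or "").strip() or "proteomic")
            except (ValueError, KeyError) as exc:
                errors.append((i, str(exc)))
    case = CaseInput(case_id=case_id or path.stem, variants=variants, provenance=provenance)
    return case, errors


def write_vustruct_csv(case: CaseInput, path: str | Path) -> None:
    """Write a case in the vustruct.csv dialect (round-trip exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(VUSTRUCT_CSV_COLUMNS)
        for v, prov in zip(case.variants, case.provenance):
            w.writerow([v.gene, v.transcript_id, v.protein_id, v.label, v.inheritance, prov])


def load_annotated_table(path: str | Path, case_id: str) -> CaseInput:
    """Import pre-annotated consequences (e.g. real VEP output reduced to a
    4+ column CSV: ``transcript_id,position,ref_aa,alt_aa`` plus optional
    ``gene``, ``protein_id``, ``inheritance``)."""
    variants, provenance = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            variants.append(
                ProteinVariant(
                    gene=(row.get("gene") or "").strip(),
                    protein_id=(row.get("protein_id") or "").strip(),
                    transcript_id=row["transcript_id"].strip(),
                    position=int(row["position"]),
                    ref_aa=row["ref_aa"].strip().upper(),
                    alt_aa=row["alt_aa"].strip().upper(),
                    inheritance=(row.get("inheritance") or "unknown").strip() or "unknown",
                )
            )
            provenance.append("annotated")
    return CaseInput(case_id=case_id, variants=variants, provenance=provenance)


def case_from_vcf(
    path: str | Path,
    transcripts: Sequence[TranscriptModel],
    case_id: str,
) -> tuple[CaseInput, dict]:
    """VCF → missense-only CaseInput, with a log of skipped/dropped records."""
    genomic, skipped = parse_vcf(path)
    kept, dropped = call_missense(genomic, transcripts)
    case = CaseInput(
        case_id=case_id,
        variants=kept,
        provenance=["genomic"] * len(kept),
    )
    return case, {"skipped_vcf_records": skipped, "non_missense": dropped}
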