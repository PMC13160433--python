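"""Transcript ↔ curated-protein reconciliation and isoform expansion.

Transcript records and curated protein sequences drift apart over time; this
module classifies each cross-reference into one of four discrepancy classes,
restricts the case to variants on perfectly cross-referenced transcripts,
fans each retained variant out across the protein's curated "-N" splice
isoforms, and validates the claimed reference residue against the actual
peptide.  Unprocessable variants stop the pipeline with a machine-readable
halt report (a ``force`` flag proceeds with the retained subset instead).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO

from .ingest import AA_ALPHABET, CaseInput, ProteinVariant, isoform_number, strip_isoform_suffix

XREF_STATUSES = ("PERFECT", "LEN_MATCH_SEQ_MISMATCH", "LEN_MISMATCH", "NO_XREF")


@dataclass(frozen=True)
class XrefRecord:
    transcript_id: str
    protein_id: str
    transcript_peptide: str
    curated_peptide: str | None  # None when no cross-reference exists

    @property
    def status(self) -> str:
        return classify_xref(self.transcript_peptide, self.curated_peptide)


@dataclass
class Isoform:
    isoform_id: str
    peptide: str
    is_canonical: bool


@dataclass
class IsoformSet:
    """All curated splice isoforms of one protein, exactly one canonical."""

    protein_id: str
    isoforms: list[Isoform]

    def __post_init__(self):
        ids = [i.isoform_id for i in self.isoforms]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate isoform ids for {self.protein_id}")
        n_canon = sum(i.is_canonical for i in self.isoforms)
        if n_canon != 1:
            raise ValueError(f"{self.protein_id}: need exactly one canonical isoform, got {n_canon}")

    @property
    def canonical(self) -> Isoform:
        return next(i for i in self.isoforms if i.is_canonical)


def classify_xref(transcript_peptide: str, curated_peptide: str | None) -> str:
    """Four-way discrepancy class between transcript and curated sequences."""
    if curated_peptide is None:
        return "NO_XREF"
    if transcript_peptide == curated_peptide:
        return "PERFECT"
    if len(transcript_peptide) == len(curated_peptide):
        return "LEN_MATCH_SEQ_MISMATCH"
    return "LEN_MISMATCH"


def load_xref_catalog(path: str | Path) -> dict[str, XrefRecord]:
    """Read the xref catalog CSV keyed by transcript_id.

    Columns: transcript_id,protein_id,transcript_peptide,curated_peptide
    (empty curated_peptide means no cross-reference).
    """
    records: dict[str, XrefRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            tid = row["transcript_id"].strip()
            if tid in records:
                raise ValueError(f"duplicate transcript {tid} in xref catalog")
            curated = row.get("curated_peptide") or None
            records[tid] = XrefRecord(
                transcript_id=tid,
                protein_id=(row.get("protein_id") or "").strip(),
                transcript_peptide=row["transcript_peptide"].strip(),
                curated_peptide=curated.strip() if curated else None,
            )
    return records


def load_isoform_fasta(path: str | Path) -> dict[str, IsoformSet]:
    """Read "-N"-suffixed isoform FASTA into IsoformSets keyed by base id.

    The unsuffixed identifier (or "-1", a conventional synonym) is canonical.
    """
    groups: dict[str, list[Isoform]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        iso_id = rec.id
        base = strip_isoform_suffix(iso_id)
        canonical = isoform_number(iso_id) == 1
        groups.setdefault(base, []).append(Isoform(iso_id, str(rec.seq), canonical))
    sets = {}
    for base, isoforms in groups.items():
        isoforms.sort(key=lambda i: (not i.is_canonical, isoform_number(i.isoform_id)))
        sets[base] = IsoformSet(protein_id=base, isoforms=isoforms)
    return sets


# ---------------------------------------------------------------------------
# curated-transcript filter and halt protocol
# ---------------------------------------------------------------------------


@dataclass
class Rejection:
    variant: ProteinVariant
    reason: str


def filter_curated(
    case: CaseInput, xrefs: dict[str, XrefRecord]
) -> tuple[list[ProteinVariant], list[Rejection]]:
    """Retain variants whose transcript cross-references perfectly.

    Every other status (sequence mismatch, length mismatch, missing
    cross-reference, transcript absent from the catalog) rejects the variant
    with that status as the reason.  Retained variants get their curated
    protein_id assigned from the catalog.  |retained| + |rejected| == |input|.
    """
    retained, rejected = [], []
    for v in case.variants:
        rec = xrefs.get(v.transcript_id)
        if rec is None:
            rejected.append(Rejection(v, "NO_XREF"))
            continue
        status = rec.status
        if status != "PERFECT":
            rejected.append(Rejection(v, status))
            continue
        if not v.protein_id:
            v = ProteinVariant(
                gene=v.gene or rec.protein_id,
                protein_id=rec.protein_id,
                transcript_id=v.transcript_id,
                position=v.position,
                ref_aa=v.ref_aa,
                alt_aa=v.alt_aa,
                inheritance=v.inheritance,
            )
        retained.append(v)
    return retained, rejected


@dataclass
class HaltReport:
    """Machine-readable record of why (part of) a case cannot proceed."""

    case_id: str
    n_input: int
    n_retained: int
    rejections_by_reason: dict[str, list[dict]]
    stopped: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "case_id": self.case_id,
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "stopped": self.stopped,
                "rejections": self.rejections_by_reason,
            },
            indent=2,
            sort_keys=True,
        )


def halt_on_disconnect(
    case: CaseInput,
    rejections: list[Rejection],
    n_retained: int,
    force: bool = False,
) -> HaltReport | None:
    """Build the stop report when any variant is unprocessable.

    Default behaviour mirrors the stop-and-let-the-user-patch flow: any
    rejection halts the run (``stopped=True`` ⇒ non-zero CLI exit) so the
    user can rework coordinates or patch the vustruct.csv.  With ``force``
    the report is still produced but the pipeline proceeds on the retained
    subset.  No rejections → None.
    """
    if not rejections:
        return None
    grouped: dict[str, list[dict]] = {}
    for r in rejections:
        grouped.setdefault(r.reason, []).append(
            {
                "gene": r.variant.gene,
                "transcript_id": r.variant.transcript_id,
                "protein_id": r.variant.protein_id,
                "variant": r.variant.label,
            }
        )
    return HaltReport(
        case_id=case.case_id,
        n_input=len(case.variants),
        n_retained=n_retained,
        rejections_by_reason=grouped,
        stopped=not force,
    )


# ---------------------------------------------------------------------------
# isoform expansion
# ---------------------------------------------------------------------------

# Global (Needleman-Wunsch) alignment with fixed, documented parameters:
# match +1, mismatch -1, gap open -5, gap extend -0.5.  Splice isoforms are
# near-identical outside spliced-out exons, so heavy gap-open with light
# extension recovers exon-sized indels as single gaps.
_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -5.0
_aligner.extend_gap_score = -0.5


def map_position(src_peptide: str, dst_peptide: str, position: int) -> int | None:
    """Map a 1-based residue position from one isoform peptide onto another.

    Fast path: when both peptides agree through ``position`` (gap-free
    prefix), the position maps to itself.  Otherwise a global pairwise
    alignment is used and the position maps only if its column pairs two
    residues (no gap).  Returns the 1-based destination position or None.
    """
    if position > len(src_peptide):
        return None
    if (
        position <= len(dst_peptide)
        and src_peptide[:position] == dst_peptide[:position]
    ):
        return position
    aln = _aligner.align(src_peptide, dst_peptide)[0]
    src_idx = position - 1
    for (s0, s1), (d0, d1) in zip(*aln.aligned):
        if s0 <= src_idx < s1:
            return d0 + (src_idx - s0) + 1
    return None


@dataclass
class IsoformExpansion:
    variants: list[ProteinVariant]
    skipped: list[tuple[str, str]]  # (isoform_id, reason)


def expand_isoforms(variant: ProteinVariant, isoset: IsoformSet) -> IsoformExpansion:
    """Fan a canonical-coordinate variant out across all curated isoforms.

    The reference residue must land, ungapped, on an identical residue of the
    target isoform; isoforms lacking it (e.g. the exon is spliced out) are
    skipped with a reason.  Raises ValueError if the variant maps to no
    isoform at all (feeds the halt protocol).
    """
    canonical = isoset.canonical
    out: list[ProteinVariant] = []
    skipped: list[tuple[str, str]] = []
    if (
        variant.position > len(canonical.peptide)
        or canonical.peptide[variant.position - 1] != variant.ref_aa
    ):
        raise ValueError(
            f"{variant.label} does not match canonical peptide of {isoset.protein_id}"
        )
    for iso in isoset.isoforms:
        pos = map_position(canonical.peptide, iso.peptide, variant.position)
        if pos is None:
            skipped.append((iso.isoform_id, "position falls in an alignment gap"))
            continue
        if iso.peptide[pos - 1] != variant.ref_aa:
            skipped.append(
                (iso.isoform_id, f"reference residue absent (has {iso.peptide[pos - 1]})")
            )
            continue
        out.append(
            ProteinVariant(
                gene=variant.gene,
                protein_id=iso.isoform_id,
                transcript_id=variant.transcript_id,
                position=pos,
                ref_aa=variant.ref_aa,
                alt_aa=variant.alt_aa,
                inheritance=variant.inheritance,
                canonical_label=variant.label,
            )
        )
    if not out:
        raise ValueError(
            f"{variant.label} maps to no isoform of {isoset.protein_id}: {skipped}"
        )
    return IsoformExpansion(variants=out, skipped=skipped)


# ---------------------------------------------------------------------------
# reference-residue guard
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueCheck:
    ok: bool
    detail: str = ""


def validate_reference_residue(v: ProteinVariant, peptide: str) -> ResidueCheck:
    """Check that the peptide really carries ref_aa at the claimed position."""
    if v.position > len(peptide):
        return ResidueCheck(False, f"position {v.position} beyond peptide length {len(peptide)}")
    actual = peptide[v.position - 1]
    if actual != v.ref_aa:
        return ResidueCheck(False, f"expected {v.ref_aa} at {v.position}, peptide has {actual}")
    return ResidueCheck(True)
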