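"""Structure gathering, residue mapping, and minimal-redundancy selection.

For each protein the catalog offers a mixed bag of experimental structures
(PDB; X-ray/cryo-EM/NMR with a resolution) and computed models (AlphaFold /
SwissModel / ModBase with a 0–100 confidence), each covering part of the
sequence with one or more chains.  Residue-level alignment between transcript
positions and structure residue numbers is carried as explicit segment
tables, in the style of SIFTS mappings — never inferred from the residue
numbering in the coordinate file.

Selection scores each candidate with an additive utility —

    u = w_cov·covers(variant) + w_div·[method unseen] + w_qual·quality
        + w_mult·[oligomer > 1] − w_red·overlap(candidate, selected)

— and greedily retains the best positive-marginal candidates, so the final
set minimises redundancy while maximising technique diversity, variant
coverage, quality, and multimeric context.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .config import Config, DEFAULT_CONFIG

SOURCES = ("PDB", "SWISSMODEL", "MODBASE", "ALPHAFOLD")
METHODS = ("xray", "cryoem", "nmr", "model")
EXPERIMENTAL_SOURCES = {"PDB"}
#: tie-break preference between sources of otherwise equal utility/quality
SOURCE_RANK = {"PDB": 0, "ALPHAFOLD": 1, "SWISSMODEL": 2, "MODBASE": 3}


@dataclass(frozen=True)
class MapSegment:
    """A gap-free alignment run: ``seg_length`` consecutive residues starting
    at transcript position ``transcript_start`` map to structure residues
    starting at ``residue_start`` on ``chain``."""

    chain: str
    transcript_start: int
    residue_start: int
    seg_length: int
    insertion_code: str = ""

    def contains(self, position: int) -> bool:
        return self.transcript_start <= position < self.transcript_start + self.seg_length

    def residue_for(self, position: int) -> int:
        return self.residue_start + (position - self.transcript_start)


@dataclass
class ResidueMap:
    """Transcript-position ↔ structure-residue alignment for one structure."""

    structure_id: str
    segments: list[MapSegment]

    def __post_init__(self):
        # no transcript position may map twice within one chain
        per_chain: dict[str, set[int]] = {}
        for seg in self.segments:
            cov = per_chain.setdefault(seg.chain, set())
            rng = set(range(seg.transcript_start, seg.transcript_start + seg.seg_length))
            if cov & rng:
                raise ValueError(
                    f"{self.structure_id}: chain {seg.chain} maps transcript "
                    f"positions {sorted(cov & rng)[:3]}... twice"
                )
            cov |= rng

    @property
    def chains(self) -> list[str]:
        return sorted({s.chain for s in self.segments})

    def covered_positions(self, chain: str | None = None) -> set[int]:
        out: set[int] = set()
        for seg in self.segments:
            if chain is None or seg.chain == chain:
                out |= set(range(seg.transcript_start, seg.transcript_start + seg.seg_length))
        return out

    def to_transcript(self, chain: str, residue_number: int) -> int | None:
        """Inverse lookup: structure residue → transcript position."""
        for seg in self.segments:
            if seg.chain == chain and seg.residue_start <= residue_number < seg.residue_start + seg.seg_length:
                return seg.transcript_start + (residue_number - seg.residue_start)
        return None


@dataclass(frozen=True)
class ResidueAddress:
    chain: str
    residue_number: int
    insertion_code: str = ""


def map_residue(variant_position: int, rm: ResidueMap) -> list[ResidueAddress]:
    """Resolve a transcript position to structure residue address(es).

    Returns one address per protomer chain carrying the position — a
    homodimer yields two — or an empty list when unmapped.
    """
    out = []
    for seg in rm.segments:
        if seg.contains(variant_position):
            out.append(
                ResidueAddress(seg.chain, seg.residue_for(variant_position), seg.insertion_code)
            )
    out.sort(key=lambda a: (a.chain, a.residue_number))
    return out


@dataclass
class StructureCandidate:
    """One catalog structure: provenance, quality metric, and residue map."""

    structure_id: str
    source: str  # PDB | SWISSMODEL | MODBASE | ALPHAFOLD
    method: str  # xray | cryoem | nmr | model
    quality: float  # resolution (A) for experimental; confidence 0-100 for models
    oligomeric_state: int
    coordinates_path: str
    residue_map: ResidueMap

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method}")
        if self.is_experimental:
            if self.quality <= 0:
                raise ValueError(f"{self.structure_id}: experimental resolution must be > 0")
        elif not 0 <= self.quality <= 100:
            raise ValueError(f"{self.structure_id}: model confidence must be in [0,100]")
        if self.oligomeric_state < 1:
            raise ValueError("oligomeric_state must be >= 1")

    @property
    def is_experimental(self) -> bool:
        return self.source in EXPERIMENTAL_SOURCES

    def covers(self, position: int) -> bool:
        return bool(map_residue(position, self.residue_map))

    def covered_positions(self) -> set[int]:
        return self.residue_map.covered_positions()

    def normalized_quality(self, cfg: Config = DEFAULT_CONFIG) -> float:
        """Quality on [0,1]: resolution <=res_best→1 linearly to >=res_worst→0
        for experimental structures; confidence/100 for models."""
        if self.is_experimental:
            span = cfg.res_worst - cfg.res_best
            return min(1.0, max(0.0, (cfg.res_worst - self.quality) / span))
        return self.quality / 100.0


# ---------------------------------------------------------------------------
# catalog I/O
# ---------------------------------------------------------------------------


def load_alignment_catalog(path: str | Path) -> dict[str, ResidueMap]:
    """Read per-structure alignment segments.

    CSV columns: structure_id,chain,seg_start_transcript,seg_start_residue,seg_length
    """
    segs: dict[str, list[MapSegment]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            segs.setdefault(row["structure_id"], []).append(
                MapSegment(
                    chain=row["chain"],
                    transcript_start=int(row["seg_start_transcript"]),
                    residue_start=int(row["seg_start_residue"]),
                    seg_length=int(row["seg_length"]),
                )
            )
    return {sid: ResidueMap(sid, s) for sid, s in segs.items()}


def load_candidates(
    protein_id: str,
    catalog_path: str | Path,
    alignment_path: str | Path,
    structures_root: str | Path | None = None,
) -> tuple[list[StructureCandidate], list[str]]:
    """Gather structure candidates for one protein (isoform-aware).

    Catalog CSV columns:
    protein_id,structure_id,source,method,quality,oligomeric_state,coords_path

    AlphaFold models cover canonical sequences only, so they are attached
    only when ``protein_id`` names the canonical isoform (unsuffixed or
    "-1").  Candidates whose coordinate file is missing are dropped with a
    warning rather than failing the case.
    """
    from .ingest import isoform_number  # local import to avoid cycle at import time

    maps = load_alignment_catalog(alignment_path)
    root = Path(structures_root) if structures_root else Path(catalog_path).parent
    canonical = isoform_number(protein_id) == 1
    base_id = protein_id.rsplit("-", 1)[0] if not canonical else protein_id
    candidates: list[StructureCandidate] = []
    warnings: list[str] = []
    with open(catalog_path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["protein_id"] not in (protein_id, base_id):
                continue
            source = row["source"].strip().upper()
            if source == "ALPHAFOLD" and not canonical:
                continue
            sid = row["structure_id"]
            coords = root / row["coords_path"]
            if not coords.exists():
                warnings.append(f"{sid}: coordinate file missing ({coords}); dropped")
                continue
            if sid not in maps:
                warnings.append(f"{sid}: no alignment segments in catalog; dropped")
                continue
            candidates.append(
                StructureCandidate(
                    structure_id=sid,
                    source=source,
                    method=row["method"].strip().lower(),
                    quality=float(row["quality"]),
                    oligomeric_state=int(row["oligomeric_state"]),
                    coordinates_path=str(coords),
                    residue_map=maps[sid],
                )
            )
    candidates.sort(key=lambda c: c.structure_id)
    return candidates, warnings


# ---------------------------------------------------------------------------
# utility and greedy selection
# ---------------------------------------------------------------------------


def overlap_fraction(c: StructureCandidate, selected: list[StructureCandidate]) -> float:
    """Jaccard overlap between the candidate's covered positions and the
    union of the selected set's.

    The symmetric (Jaccard) form, rather than the fraction of the
    candidate's own positions, keeps the redundancy penalty nearly
    independent of the order structures are added in — a small structure
    nested in a large one is penalised the same whichever was picked first.
    """
    mine = c.covered_positions()
    if not mine:
        return 0.0
    covered: set[int] = set()
    for s in selected:
        covered |= s.covered_positions()
    if not covered:
        return 0.0
    return len(mine & covered) / len(mine | covered)


def candidate_utility(
    c: StructureCandidate,
    variant_position: int,
    already_selected: list[StructureCandidate],
    cfg: Config = DEFAULT_CONFIG,
) -> float:
    """Marginal utility of adding ``c`` to the current selection.

    The coverage and technique-diversity terms are marginal: they pay out
    only while the selection does not yet cover the variant / include the
    method, so duplicates of an already-selected structure score strictly
    lower and pure copies go negative.
    """
    seen_methods = {s.method for s in already_selected}
    already_covered = any(s.covers(variant_position) for s in already_selected)
    u = 0.0
    if c.covers(variant_position) and not already_covered:
        u += cfg.w_cov
    if c.method not in seen_methods:
        u += cfg.w_div
    u += cfg.w_qual * c.normalized_quality(cfg)
    if c.oligomeric_state > 1:
        u += cfg.w_mult
    u -= cfg.w_red * overlap_fraction(c, already_selected)
    return u


@dataclass
class SelectionRationale:
    structure_id: str
    covers_variant: bool
    marginal_utility: float
    reasons: list[str]


@dataclass
class SelectionResult:
    selected: list[StructureCandidate]
    rationale: list[SelectionRationale]
    notes: list[str] = field(default_factory=list)


def _tiebreak_key(c: StructureCandidate, cfg: Config):
    return (
        -c.normalized_quality(cfg),
        SOURCE_RANK[c.source],
        c.structure_id,
    )


def _reasons(c: StructureCandidate, covers: bool, new_method: bool, cfg: Config) -> list[str]:
    r = []
    if covers:
        r.append("coverage")
    if new_method:
        r.append("technique_diversity")
    if c.normalized_quality(cfg) >= 0.5:
        r.append("quality")
    if c.oligomeric_state > 1:
        r.append("multimer")
    if c.source == "ALPHAFOLD":
        r.append("alphafold_canonical")
    return r


def select_structures(
    candidates: list[StructureCandidate],
    variant_position: int,
    max_k: int | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> SelectionResult:
    """Greedy maximal-marginal-utility selection of at most ``max_k``
    structures.

    Each round adds the candidate with the highest positive marginal utility
    (ties broken by quality, then source preference PDB > AlphaFold >
    SwissModel > ModBase, then structure id) and stops when the budget is
    exhausted or nothing positive remains.  Whenever any candidate covers the
    variant, the final selection is guaranteed to contain a covering
    structure — if the greedy loop never picked one, the best covering
    candidate is forced in (replacing the weakest pick if the budget is
    full).
    """
    max_k = max_k if max_k is not None else cfg.max_structures
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if not candidates:
        return SelectionResult([], [], notes=["no structural coverage: empty candidate list"])
    remaining = sorted(candidates, key=lambda c: _tiebreak_key(c, cfg))
    selected: list[StructureCandidate] = []
    rationale: list[SelectionRationale] = []
    notes: list[str] = []
    while remaining and len(selected) < max_k:
        scored = [
            (candidate_utility(c, variant_position, selected, cfg), c) for c in remaining
        ]
        best_u, best = min(scored, key=lambda t: (-t[0], _tiebreak_key(t[1], cfg)))
        if best_u <= 0:
            break
        selected.append(best)
        remaining.remove(best)
        rationale.append(
            SelectionRationale(
                best.structure_id,
                best.covers(variant_position),
                best_u,
                _reasons(
                    best,
                    best.covers(variant_position),
                    best.method not in {s.method for s in selected[:-1]},
                    cfg,
                ),
            )
        )
    covering = [c for c in candidates if c.covers(variant_position)]
    if covering and not any(c.covers(variant_position) for c in selected):
        forced = min(
            (c for c in covering if c not in selected), key=lambda c: _tiebreak_key(c, cfg)
        )
        if len(selected) >= max_k:
            dropped_idx = min(
                range(len(selected)), key=lambda i: rationale[i].marginal_utility
            )
            notes.append(
                f"dropped {selected[dropped_idx].structure_id} to honour variant coverage"
            )
            del selected[dropped_idx]
            del rationale[dropped_idx]
        base = [s for s in selected]
        u = candidate_utility(forced, variant_position, base, cfg)
        selected.append(forced)
        rationale.append(
            SelectionRationale(
                forced.structure_id, True, u,
                _reasons(forced, True, forced.method not in {s.method for s in base}, cfg),
            )
        )
        notes.append(f"forced covering structure {forced.structure_id}")
    if not covering:
        notes.append("no candidate covers the variant position")
    return SelectionResult(selected, rationale, notes=notes)
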