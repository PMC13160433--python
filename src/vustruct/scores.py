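"""Precomputed per-residue / per-substitution score tables.

Transcriptome-wide precomputations (AlphaMissense-style substitution scores,
ConSurf/Rate4Site- and COSMIS-style per-position constraint scores) are
ingested from flat tables and resolved per variant by exact key lookup — no
cluster jobs, no imputation.  Substitution scores key on
(protein_id, position, alt_aa); constraint scores on (protein_id, position).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .ingest import ProteinVariant, strip_isoform_suffix

KEYINGS = ("substitution", "position")


class ScoreTableError(Exception):
    pass


@dataclass
class ScoreTable:
    score_name: str
    keying: str  # "substitution" (alt-specific) or "position"
    values: dict[tuple, float] = field(default_factory=dict)
    provenance: str = ""
    n_rejected_rows: int = 0

    def __post_init__(self):
        if self.keying not in KEYINGS:
            raise ValueError(f"keying must be one of {KEYINGS}")

    def key_for(self, variant: ProteinVariant, protein_id: str | None = None) -> tuple:
        pid = protein_id if protein_id is not None else variant.protein_id
        if self.keying == "substitution":
            return (pid, variant.position, variant.alt_aa)
        return (pid, variant.position)

    def get(self, variant: ProteinVariant, protein_id: str | None = None) -> float | None:
        return self.values.get(self.key_for(variant, protein_id))


def load_score_table(
    path: str | Path, keying: str, score_name: str | None = None
) -> ScoreTable:
    """Load a TSV/CSV score table with declared keying.

    Columns: ``protein_id,position[,alt_aa],value`` (tab- or comma-
    delimited; the alt_aa column is required for substitution keying and
    ignored for position keying).  Rows failing key validation are counted
    and skipped; a duplicate key is a hard error naming the key.
    """
    path = Path(path)
    name = score_name or path.stem
    table = ScoreTable(score_name=name, keying=keying, provenance=path.name)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        for row in csv.DictReader(fh, delimiter=delim):
            try:
                pid = row["protein_id"].strip()
                pos = int(row["position"])
                value = float(row["value"])
                if not pid or pos < 1:
                    raise ValueError
                if keying == "substitution":
                    alt = row["alt_aa"].strip().upper()
                    if len(alt) != 1:
                        raise ValueError
                    key = (pid, pos, alt)
                else:
                    key = (pid, pos)
            except (KeyError, ValueError, AttributeError, TypeError):
                table.n_rejected_rows += 1
                continue
            if key in table.values:
                raise ScoreTableError(f"{path.name}: duplicate key {key}")
            table.values[key] = value
    return table


def load_score_dir(path: str | Path) -> dict[str, ScoreTable]:
    """Load every ``*.tsv`` table under a directory.

    Keying is inferred from the header: a file with an ``alt_aa`` column is
    substitution-keyed, otherwise position-keyed.
    """
    tables: dict[str, ScoreTable] = {}
    for f in sorted(Path(path).glob("*.tsv")):
        with open(f) as fh:
            header = fh.readline()
        keying = "substitution" if "alt_aa" in header else "position"
        t = load_score_table(f, keying)
        tables[t.score_name] = t
    return tables


def lookup(
    variant: ProteinVariant,
    tables: dict[str, ScoreTable],
    canonical_fallback: bool = False,
) -> dict[str, float | None]:
    """Resolve one variant against all tables: exact keys only.

    Missing entries come back as None — absent, never imputed.  With
    ``canonical_fallback`` an isoform-suffixed protein falls back to its
    canonical (unsuffixed) entry when its own key is absent; the default is
    no fallback, since precomputations cover canonical sequences only.
    """
    out: dict[str, float | None] = {}
    for name, table in tables.items():
        value = table.get(variant)
        if value is None and canonical_fallback:
            base = strip_isoform_suffix(variant.protein_id)
            if base != variant.protein_id:
                value = table.get(variant, protein_id=base)
        out[name] = value
    return out
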