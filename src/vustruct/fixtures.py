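"""Synthetic inputs: toy transcriptomes, helix structures, planted clusters.

Everything the pipeline consumes — transcript models with CDS intervals on
both strands, transcript↔curated-protein catalogs realizing the four
discrepancy classes, "-N" isoform FASTA, structure/alignment catalogs with
PDB coordinate files of controlled coverage, quality and multimericity,
spatially clustered labeled variant sites with ground truth, VCF cases and
precomputed score tables — can be generated offline from a seed.  Identical
spec + seed yields byte-identical files.

Structures are ideal α-helix Cα traces (rise 1.5 Å, 100°/residue, radius
2.3 Å): not folded proteins, but geometry enough for distance statistics,
coverage arithmetic and multimer fan-out, with trivially controllable
inter-residue distances.

The module also hosts the brute-force consequence oracle
(:func:`oracle_consequence`): it mutates the full CDS string and translates
both sequences end to end, sharing no code path with the codon-level caller
it is used to check.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio.Seq import Seq

from .ingest import (
    AA_ALPHABET,
    GenomicVariant,
    ProteinVariant,
    TranscriptModel,
    complement,
    translate_cds,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)

# ideal helix parameters (documented; see module docstring)
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
HELIX_RADIUS = 2.3
#: translation between protomer copies along x, in Å
PROTOMER_SPACING = 40.0


@dataclass
class ClusterGeometry:
    n_pathogenic: int = 8
    n_benign: int = 8
    cluster_radius: float = 8.0
    separation: float = 20.0


@dataclass
class FixtureSpec:
    """Knobs of the synthetic world; defaults are the study conditions used
    throughout the test-suite."""

    seed: int = 0
    n_genes: int = 6
    isoforms_per_gene: int = 2
    peptide_length: tuple[int, int] = (60, 120)
    xref_class_mix: dict = field(
        default_factory=lambda: {
            "PERFECT": 0.7,
            "LEN_MATCH_SEQ_MISMATCH": 0.1,
            "LEN_MISMATCH": 0.1,
            "NO_XREF": 0.1,
        }
    )
    structures_per_protein: tuple[int, int] = (2, 4)
    source_weights: dict = field(
        default_factory=lambda: {
            "PDB": 0.4,
            "ALPHAFOLD": 0.25,
            "SWISSMODEL": 0.2,
            "MODBASE": 0.15,
        }
    )
    p_multimer: float = 0.3
    cluster: ClusterGeometry = field(default_factory=ClusterGeometry)
    n_missense: int = 5
    n_extra_records: int = 3

    def __post_init__(self):
        total = sum(self.xref_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("xref_class_mix proportions must sum to 1")
        if isinstance(self.cluster, dict):
            self.cluster = ClusterGeometry(**self.cluster)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def planted_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n records to classes."""
    names = sorted(mix)
    raw = {k: mix[k] * n for k in names}
    counts = {k: int(raw[k]) for k in names}
    short = n - sum(counts.values())
    for k in sorted(names, key=lambda k: (counts[k] - raw[k], k))[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# brute-force consequence oracle
# ---------------------------------------------------------------------------


def genomic_offset_pairs(t: TranscriptModel) -> list[tuple[int, int]]:
    """(genomic position, CDS offset) for every coding base, fixture-side."""
    pairs = []
    offset = 0
    for start, end in t.cds_intervals:
        positions = range(start, end + 1) if t.strand == "+" else range(end, start - 1, -1)
        for pos in positions:
            pairs.append((pos, offset))
            offset += 1
    return pairs


def oracle_consequence(t: TranscriptModel, gv: GenomicVariant) -> tuple[str, tuple | None]:
    """Full-CDS mutate-and-translate oracle.

    Rebuilds the coding sequence with the variant applied, translates the
    whole original and mutated sequences, and diffs the peptides.  Returns
    (class, (position, ref_aa, alt_aa) or None).
    """
    if gv.chrom != t.chrom:
        return "non_coding", None
    offset = next((o for p, o in genomic_offset_pairs(t) if p == gv.pos), None)
    if offset is None:
        return "non_coding", None
    ref_cds = gv.ref if t.strand == "+" else complement(gv.ref)
    alt_cds = gv.alt if t.strand == "+" else complement(gv.alt)
    if t.cds_sequence[offset] != ref_cds:
        raise ValueError("oracle: reference base mismatch")
    mutated = t.cds_sequence[:offset] + alt_cds + t.cds_sequence[offset + 1 :]
    ref_pep = str(Seq(t.cds_sequence).translate())
    alt_pep = str(Seq(mutated).translate())
    if ref_pep == alt_pep:
        return "synonymous", None
    diffs = [i for i, (a, b) in enumerate(zip(ref_pep, alt_pep)) if a != b]
    i = diffs[0]
    ref_aa, alt_aa = ref_pep[i], alt_pep[i]
    if alt_aa == "*":
        return "nonsense", None
    if ref_aa == "*":
        return "stop_lost", None
    return "missense", (i + 1, ref_aa, alt_aa)


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


@dataclass
class Transcriptome:
    transcripts: list[TranscriptModel]
    xref_rows: list[dict]  # transcript_id,protein_id,transcript_peptide,curated_peptide,planted_class
    isoform_records: list[tuple[str, str]]  # (isoform_id, peptide)

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.transcript_id == tid)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = ["ATG"] + [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 1)]
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "".join(body) + stop


def make_transcriptome(spec: FixtureSpec, out_dir: str | Path | None = None) -> Transcriptome:
    """Generate toy transcripts + xref catalog + isoform FASTA.

    The planted xref class mix is realized exactly (largest-remainder
    apportionment over n_genes); single- and two-exon CDS layouts on both
    strands exercise the interval arithmetic.
    """
    rng = np.random.default_rng(spec.seed)
    counts = planted_counts(spec.xref_class_mix, spec.n_genes)
    classes = [k for k in sorted(counts) for _ in range(counts[k])]
    rng.shuffle(classes)

    transcripts: list[TranscriptModel] = []
    xref_rows: list[dict] = []
    iso_records: list[tuple[str, str]] = []
    for i in range(spec.n_genes):
        gene = f"G{i + 1:04d}"
        tid = f"T{i + 1:04d}"
        pid = f"P{i + 1:04d}"
        n_aa = int(rng.integers(*spec.peptide_length))
        cds = _random_cds(rng, n_aa)  # n_aa sense codons (ATG first) + stop
        peptide = translate_cds(cds)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{i % 4 + 1}"
        # non-overlapping windows per chromosome (one gene every 50 kb)
        start = 1_000 + (i // 4) * 50_000 + int(rng.integers(0, 10_000))
        total = len(cds)
        if rng.random() < 0.5:
            genomic_ivs = [(start, start + total - 1)]
        else:
            cut = int(rng.integers(3, total - 3))
            gap = int(rng.integers(50, 500))
            genomic_ivs = [
                (start, start + cut - 1),
                (start + cut + gap, start + cut + gap + (total - cut) - 1),
            ]
        ivs = genomic_ivs if strand == "+" else list(reversed(genomic_ivs))
        t = TranscriptModel(
            transcript_id=tid, gene=gene, chrom=chrom, strand=strand,
            cds_intervals=tuple(ivs), cds_sequence=cds, peptide=peptide,
        )
        transcripts.append(t)

        cls = classes[i]
        curated: str | None
        if cls == "PERFECT":
            curated = peptide
        elif cls == "LEN_MATCH_SEQ_MISMATCH":
            j = int(rng.integers(1, len(peptide)))
            alt = rng.choice(sorted(AA_ALPHABET - {peptide[j]}))
            curated = peptide[:j] + str(alt) + peptide[j + 1 :]
        elif cls == "LEN_MISMATCH":
            curated = peptide[: len(peptide) - int(rng.integers(1, 6))]
        else:
            curated = None
        xref_rows.append(
            {
                "transcript_id": tid,
                "protein_id": pid,
                "transcript_peptide": peptide,
                "curated_peptide": curated or "",
                "planted_class": cls,
            }
        )

        # curated isoforms: canonical (unsuffixed) + "-N" splice variants
        canonical_pep = curated if curated else peptide
        iso_records.append((pid, canonical_pep))
        for n in range(2, spec.isoforms_per_gene + 1):
            mode = rng.integers(0, 3)
            if mode == 0 and len(canonical_pep) > 25:  # internal exon-like deletion
                a = int(rng.integers(5, len(canonical_pep) - 20))
                w = int(rng.integers(8, 16))
                iso_pep = canonical_pep[:a] + canonical_pep[a + w :]
            elif mode == 1 and len(canonical_pep) > 20:  # C-terminal truncation
                iso_pep = canonical_pep[: len(canonical_pep) - int(rng.integers(5, 15))]
            else:  # C-terminal extension
                ext = "".join(rng.choice(sorted(AA_ALPHABET), size=int(rng.integers(5, 12))))
                iso_pep = canonical_pep + ext
            iso_records.append((f"{pid}-{n}", iso_pep))

    tr = Transcriptome(transcripts, xref_rows, iso_records)
    if out_dir is not None:
        write_transcriptome(tr, out_dir)
    return tr


def write_transcriptome(tr: Transcriptome, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "transcripts.json", "w") as fh:
        json.dump(
            [
                {
                    "transcript_id": t.transcript_id, "gene": t.gene, "chrom": t.chrom,
                    "strand": t.strand, "cds_intervals": [list(iv) for iv in t.cds_intervals],
                    "cds_sequence": t.cds_sequence, "peptide": t.peptide,
                }
                for t in tr.transcripts
            ],
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    with open(out / "xref_catalog.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["transcript_id", "protein_id", "transcript_peptide", "curated_peptide"])
        for r in tr.xref_rows:
            w.writerow([r["transcript_id"], r["protein_id"], r["transcript_peptide"], r["curated_peptide"]])
    with open(out / "planted_classes.json", "w") as fh:  # ground-truth sidecar
        json.dump({r["transcript_id"]: r["planted_class"] for r in tr.xref_rows}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "isoforms.fasta", "w") as fh:
        for iso_id, pep in tr.isoform_records:
            fh.write(f">{iso_id}\n")
            for k in range(0, len(pep), 60):
                fh.write(pep[k : k + 60] + "\n")


def load_transcript_models(path: str | Path) -> list[TranscriptModel]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        TranscriptModel(
            transcript_id=d["transcript_id"], gene=d["gene"], chrom=d["chrom"],
            strand=d["strand"], cds_intervals=tuple(tuple(iv) for iv in d["cds_intervals"]),
            cds_sequence=d["cds_sequence"], peptide=d["peptide"],
        )
        for d in data
    ]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def helix_ca(n: int, start_index: int = 0, offset=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Cα positions of an ideal helix for residues start_index..start_index+n-1."""
    i = np.arange(start_index, start_index + n)
    theta = np.deg2rad(HELIX_TURN_DEG) * i
    xyz = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i], axis=1
    )
    return xyz + np.asarray(offset)


def write_helix_pdb(
    path: str | Path,
    peptide: str,
    segments: list[tuple[int, int, int]],  # (transcript_start, residue_start, length)
    n_chains: int = 1,
) -> None:
    """Emit a Cα-only PDB: one ideal helix per chain, residues numbered per
    the alignment segments (identical numbering replicated across chains)."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model("1")
    chain_names = [chr(ord("A") + c) for c in range(n_chains)]
    for c, cname in enumerate(chain_names):
        chain = gemmi.Chain(cname)
        for t_start, r_start, length in segments:
            coords = helix_ca(length, start_index=t_start, offset=(PROTOMER_SPACING * c, 0.0, 0.0))
            for j in range(length):
                aa = peptide[t_start - 1 + j]
                res = gemmi.Residue()
                res.name = three[aa]
                res.seqid = gemmi.SeqId(r_start + j, " ")
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*coords[j])
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
                chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))


@dataclass
class StructureFixture:
    structure_id: str
    catalog_row: dict
    alignment_rows: list[dict]
    pdb_path: Path


def make_structures(
    spec: FixtureSpec,
    protein_id: str,
    peptide: str,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> list[StructureFixture]:
    """Generate candidate structures of mixed provenance for one protein.

    Experimental entries get partial coverage and a resolution; models get
    broader coverage and a 0–100 confidence (AlphaFold always full-length).
    Roughly ``p_multimer`` of entries are homodimers.  Residue numbering is
    shifted by a small per-structure offset so maps are exercised, never
    assumed identical to transcript numbering.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    n = int(rng.integers(*spec.structures_per_protein)) if spec.structures_per_protein[1] > spec.structures_per_protein[0] else spec.structures_per_protein[0]
    names = sorted(spec.source_weights)
    probs = np.array([spec.source_weights[k] for k in names], float)
    probs /= probs.sum()
    fixtures = []
    L = len(peptide)
    for s in range(n):
        source = str(rng.choice(names, p=probs))
        sid = f"{protein_id}_S{s + 1}"
        if source == "ALPHAFOLD":
            method, quality = "model", float(np.round(rng.uniform(60, 95), 1))
            t_start, length = 1, L
        elif source == "PDB":
            method = str(rng.choice(["xray", "cryoem", "nmr"], p=[0.7, 0.2, 0.1]))
            quality = float(np.round(rng.uniform(1.2, 4.2), 2))
            length = int(rng.integers(max(10, L // 3), L + 1))
            t_start = int(rng.integers(1, L - length + 2))
        else:
            method, quality = "model", float(np.round(rng.uniform(40, 90), 1))
            length = int(rng.integers(max(10, L // 2), L + 1))
            t_start = int(rng.integers(1, L - length + 2))
        n_chains = 2 if rng.random() < spec.p_multimer else 1
        shift = int(rng.integers(-4, 5))
        r_start = t_start + shift
        pdb_path = out / "structures" / f"{sid}.pdb"
        write_helix_pdb(pdb_path, peptide, [(t_start, r_start, length)], n_chains=n_chains)
        catalog_row = {
            "protein_id": protein_id,
            "structure_id": sid,
            "source": source,
            "method": method,
            "quality": quality,
            "oligomeric_state": n_chains,
            "coords_path": f"structures/{sid}.pdb",
        }
        alignment_rows = [
            {
                "structure_id": sid, "chain": chr(ord("A") + c),
                "seg_start_transcript": t_start, "seg_start_residue": r_start,
                "seg_length": length,
            }
            for c in range(n_chains)
        ]
        fixtures.append(StructureFixture(sid, catalog_row, alignment_rows, pdb_path))
    return fixtures


def write_structure_catalogs(fixtures: list[StructureFixture], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "structure_catalog.csv", "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=["protein_id", "structure_id", "source", "method", "quality",
                        "oligomeric_state", "coords_path"],
        )
        w.writeheader()
        for f in fixtures:
            w.writerow(f.catalog_row)
    with open(out / "alignment_catalog.csv", "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=["structure_id", "chain", "seg_start_transcript",
                        "seg_start_residue", "seg_length"],
        )
        w.writeheader()
        for f in fixtures:
            for row in f.alignment_rows:
                w.writerow(row)


# ---------------------------------------------------------------------------
# planted clusters
# ---------------------------------------------------------------------------


class GeometryError(ValueError):
    pass


def plant_clusters(
    structure_id: str,
    ca_coords: dict[tuple[str, int], np.ndarray],
    geometry: ClusterGeometry,
    seed: int,
) -> tuple[list[dict], dict]:
    """Place labeled sites with known geometry on one structure.

    Pathogenic sites fall within ``cluster_radius`` of a randomly picked
    centre residue; benign sites at least ``separation`` away from it.  A
    degenerate ``separation == 0`` places both labels uniformly (the null
    geometry used for calibration).  Site residue numbers are chosen on the
    first chain and replicated across protomer chains.  Returns (rows for
    the sites CSV, ground-truth dict).
    """
    rng = np.random.default_rng(seed)
    chains = sorted({c for c, _ in ca_coords})
    first = chains[0]
    residues = sorted(r for c, r in ca_coords if c == first)
    coords = {r: ca_coords[(first, r)] for r in residues}
    if len(residues) < geometry.n_pathogenic + geometry.n_benign + 1:
        raise GeometryError("not enough mapped residues for the requested site counts")
    if geometry.separation == 0:
        picks = rng.choice(residues, size=geometry.n_pathogenic + geometry.n_benign, replace=False)
        path_res = sorted(int(r) for r in picks[: geometry.n_pathogenic])
        ben_res = sorted(int(r) for r in picks[geometry.n_pathogenic :])
        center = None
    else:
        order = rng.permutation(residues)
        center = None
        for cand in order:
            d = {r: float(np.linalg.norm(coords[r] - coords[cand])) for r in residues}
            near = [r for r in residues if r != cand and d[r] <= geometry.cluster_radius]
            far = [r for r in residues if d[r] >= geometry.separation]
            if len(near) >= geometry.n_pathogenic and len(far) >= geometry.n_benign:
                center = int(cand)
                break
        if center is None:
            dists = [
                float(np.linalg.norm(coords[a] - coords[b]))
                for a in residues for b in residues if a < b
            ]
            raise GeometryError(
                "cluster geometry unsatisfiable on this structure; "
                f"achievable separations span [0, {max(dists):.1f}] Å"
            )
        d = {r: float(np.linalg.norm(coords[r] - coords[center])) for r in residues}
        near = [r for r in residues if r != center and d[r] <= geometry.cluster_radius]
        far = [r for r in residues if d[r] >= geometry.separation]
        path_res = sorted(int(r) for r in rng.choice(near, size=geometry.n_pathogenic, replace=False))
        far_pool = [r for r in far if r not in set(path_res)]
        if len(far_pool) < geometry.n_benign:
            raise GeometryError("benign pool exhausted at the requested separation")
        ben_res = sorted(int(r) for r in rng.choice(far_pool, size=geometry.n_benign, replace=False))
    rows = []
    for chain in chains:
        for r in path_res:
            rows.append({"structure_id": structure_id, "chain": chain, "residue": r, "label": "pathogenic"})
        for r in ben_res:
            rows.append({"structure_id": structure_id, "chain": chain, "residue": r, "label": "benign"})
    truth = {
        "structure_id": structure_id,
        "center_residue": center,
        "pathogenic": path_res,
        "benign": ben_res,
        "geometry": vars(geometry).copy(),
        "seed": seed,
    }
    return rows, truth


def write_sites_csv(rows: list[dict], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["structure_id", "chain", "residue", "label"])
        w.writeheader()
        for r in rows:
            w.writerow(r)


# ---------------------------------------------------------------------------
# case generation (VCF + expected vustruct.csv + score tables)
# ---------------------------------------------------------------------------


def make_case(
    spec: FixtureSpec,
    tr: Transcriptome,
    out_dir: str | Path,
    case_id: str = "case1",
) -> dict:
    """Sample SNVs to hit the requested missense count; write VCF, expected
    vustruct.csv (computed by the brute-force oracle, independent of the
    ingest module), and planted score tables."""
    rng = np.random.default_rng(spec.seed + 101)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    perfect = [
        r["transcript_id"] for r in tr.xref_rows if r["planted_class"] == "PERFECT"
    ]
    pid_of = {r["transcript_id"]: r["protein_id"] for r in tr.xref_rows}
    records: list[tuple[str, int, str, str, str]] = []  # chrom,pos,ref,alt,inh
    expected: list[dict] = []
    seen = set()
    inh_values = ["maternal", "paternal", "de_novo", "unknown"]
    guard = 0
    while len(expected) < spec.n_missense and guard < 100_000:
        guard += 1
        tid = perfect[int(rng.integers(0, len(perfect)))]
        t = tr.transcript(tid)
        pairs = genomic_offset_pairs(t)
        gpos, offset = pairs[int(rng.integers(0, len(pairs)))]
        ref_cds = t.cds_sequence[offset]
        ref = ref_cds if t.strand == "+" else complement(ref_cds)
        alt = str(rng.choice(sorted(set(_BASES) - {ref})))
        if (t.chrom, gpos, alt) in seen:
            continue
        gv = GenomicVariant(chrom=t.chrom, pos=gpos, ref=ref, alt=alt,
                            inheritance=inh_values[int(rng.integers(0, 4))])
        cls, change = oracle_consequence(t, gv)
        if cls != "missense":
            continue
        seen.add((t.chrom, gpos, alt))
        pos_aa, ref_aa, alt_aa = change
        if (pid_of[tid], pos_aa, ref_aa, alt_aa) in {
            (e["protein_id"], e["position"], e["ref_aa"], e["alt_aa"]) for e in expected
        }:
            continue
        records.append((t.chrom, gpos, ref, alt, gv.inheritance))
        expected.append(
            {
                "gene": t.gene, "transcript_id": tid, "protein_id": pid_of[tid],
                "position": pos_aa, "ref_aa": ref_aa, "alt_aa": alt_aa,
                "inheritance": gv.inheritance,
            }
        )
    # extra non-missense records: synonymous/nonsense SNVs and one indel
    extras = 0
    while extras < spec.n_extra_records and guard < 200_000:
        guard += 1
        tid = perfect[int(rng.integers(0, len(perfect)))]
        t = tr.transcript(tid)
        pairs = genomic_offset_pairs(t)
        gpos, offset = pairs[int(rng.integers(0, len(pairs)))]
        ref_cds = t.cds_sequence[offset]
        ref = ref_cds if t.strand == "+" else complement(ref_cds)
        alt = str(rng.choice(sorted(set(_BASES) - {ref})))
        if (t.chrom, gpos, alt) in seen:
            continue
        gv = GenomicVariant(chrom=t.chrom, pos=gpos, ref=ref, alt=alt)
        cls, _ = oracle_consequence(t, gv)
        if cls == "missense":
            continue
        seen.add((t.chrom, gpos, alt))
        records.append((t.chrom, gpos, ref, alt, "unknown"))
        extras += 1
    # one indel to exercise the skip path
    t0 = tr.transcript(perfect[0])
    g0 = t0.cds_intervals[0][0]
    b0 = t0.cds_sequence[0] if t0.strand == "+" else complement(t0.cds_sequence[-1])
    records.append((t0.chrom, g0, b0 + "A", b0, "unknown"))

    vcf_path = out / "case.vcf"
    _write_vcf(records, sorted({t.chrom for t in tr.transcripts}), vcf_path)

    expected.sort(key=lambda e: (e["gene"], e["position"], e["alt_aa"]))
    exp_path = out / "expected_vustruct.csv"
    with open(exp_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene", "transcript_id", "protein_id", "aa_change", "inheritance", "provenance"])
        for e in expected:
            w.writerow(
                [e["gene"], e["transcript_id"], e["protein_id"],
                 f"{e['ref_aa']}{e['position']}{e['alt_aa']}", e["inheritance"], "genomic"]
            )

    scores_dir = out / "scores"
    _write_score_tables(expected, tr, scores_dir, rng)
    return {"vcf": vcf_path, "expected_csv": exp_path, "scores_dir": scores_dir,
            "expected": expected}


def _write_vcf(records, contigs, path: Path) -> None:
    rows = sorted(records, key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=INH,Number=1,Type=String,Description="Parental inheritance">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, inh in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tINH={inh}\n")


def _write_score_tables(expected, tr: Transcriptome, scores_dir: Path, rng) -> None:
    scores_dir.mkdir(parents=True, exist_ok=True)
    sub_rows, pos_rows = {}, {}
    for e in expected:
        sub_rows[(e["protein_id"], e["position"], e["alt_aa"])] = float(
            np.round(rng.uniform(0, 1), 4)
        )
        pos_rows[(e["protein_id"], e["position"])] = float(np.round(rng.uniform(-2, 2), 4))
    # decoy rows on other positions
    for r in tr.xref_rows[:3]:
        pid = r["protein_id"]
        sub_rows.setdefault((pid, 1, "W"), float(np.round(rng.uniform(0, 1), 4)))
        pos_rows.setdefault((pid, 1), float(np.round(rng.uniform(-2, 2), 4)))
    with open(scores_dir / "alphamissense_like.tsv", "w") as fh:
        fh.write("protein_id\tposition\talt_aa\tvalue\n")
        for (pid, pos, alt), v in sorted(sub_rows.items()):
            fh.write(f"{pid}\t{pos}\t{alt}\t{v}\n")
    for name in ("consurf_like", "cosmis_like"):
        with open(scores_dir / f"{name}.tsv", "w") as fh:
            fh.write("protein_id\tposition\tvalue\n")
            for (pid, pos), v in sorted(pos_rows.items()):
                fh.write(f"{pid}\t{pos}\t{v + (0.1 if name == 'cosmis_like' else 0.0)}\n")


def _write_domains(tr: Transcriptome, path: Path, rng) -> None:
    """BED-like domain-architecture table (stand-in for a PFAM track)."""
    names = ["KINASE_like", "ZnF_like", "IG_like", "EGF_like", "SH3_like"]
    with open(path, "w") as fh:
        fh.write("# protein_id\tdomain\tstart\tend\n")
        for row in tr.xref_rows:
            pep = row["curated_peptide"] or row["transcript_peptide"]
            L = len(pep)
            pos = 3
            for _ in range(int(rng.integers(1, 3))):
                width = int(rng.integers(10, max(12, L // 3)))
                start = pos + int(rng.integers(0, 8))
                end = min(start + width, L)
                if end - start < 5 or start >= L:
                    break
                fh.write(f"{row['protein_id']}\t{names[int(rng.integers(0, len(names)))]}\t{start}\t{end}\n")
                pos = end + 5


def make_bundle(spec: FixtureSpec, out_dir: str | Path, case_id: str = "case1") -> dict:
    """Generate the full offline world for one case: transcriptome, structure
    and alignment catalogs with PDB files, labeled sites, score tables, VCF
    and the oracle-derived expected vustruct.csv."""
    out = Path(out_dir)
    tr = make_transcriptome(spec, out)
    rng = np.random.default_rng(spec.seed + 7)
    all_fixtures: list[StructureFixture] = []
    site_rows: list[dict] = []
    truths = []
    for row in tr.xref_rows:
        pep = row["curated_peptide"] or row["transcript_peptide"]
        fixtures = make_structures(spec, row["protein_id"], pep, out, rng)
        all_fixtures.extend(fixtures)
        for f in fixtures:
            from .pathprox import ca_coordinates

            ca = ca_coordinates(f.pdb_path)
            try:
                rows, truth = plant_clusters(
                    f.structure_id, ca, spec.cluster, seed=int(rng.integers(0, 2**31 - 1))
                )
            except GeometryError:
                continue
            site_rows.extend(rows)
            truths.append(truth)
    write_structure_catalogs(all_fixtures, out)
    write_sites_csv(site_rows, out / "sites.csv")
    _write_domains(tr, out / "domains.tsv", np.random.default_rng(spec.seed + 13))
    with open(out / "sites_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
        fh.write("\n")
    case = make_case(spec, tr, out, case_id=case_id)
    return {"transcriptome": tr, "structures": all_fixtures, "dir": out, **case}
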