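"""End-to-end case orchestration over a local (offline) catalog bundle.

Wires the stages together: VCF/CSV ingest → curated-transcript filtering and
isoform expansion → per-variant structure selection → workplan under the
``<case>_<guid>`` directory tree → local execution of every planned job →
landing report, transcript reports and the case summary spreadsheet.
"""

from __future__ import annotations

import json
import uuid
from dataclasses import dataclass, field
from pathlib import Path

from .config import Config, DEFAULT_CONFIG
from .executors import default_registry
from .ingest import CaseInput, case_from_vcf, parse_vustruct_csv, write_vustruct_csv
from .planner import (
    CasePaths,
    DdgCache,
    ExecutorContext,
    plan_case,
    run_local,
    write_workplans,
)
from .report import draft_case_summary, render_case_report, render_transcript_reports
from .scores import load_score_dir
from .structsel import load_candidates, select_structures
from .xref import (
    expand_isoforms,
    filter_curated,
    halt_on_disconnect,
    load_isoform_fasta,
    load_xref_catalog,
    validate_reference_residue,
)

DEFAULT_CALCS = (
    "ddg_monomer",
    "ddg_cartesian",
    "pathprox",
    "ppi_surface",
    "ptm_site",
    "score_lookup",
    "digenic_pair",
)


@dataclass
class RunResult:
    stopped: bool
    case_root: Path | None
    halt_report_path: Path | None = None
    n_input: int = 0
    n_retained: int = 0
    n_expanded: int = 0
    n_jobs: int = 0
    statuses: dict = field(default_factory=dict)
    report_paths: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)


def run_case(
    bundle_dir: str | Path,
    out_base: str | Path,
    case_id: str = "case1",
    vcf: str | Path | None = None,
    case_csv: str | Path | None = None,
    seed: int = 0,
    guid: str | None = None,
    force: bool = False,
    enabled_calcs=DEFAULT_CALCS,
    cfg: Config = DEFAULT_CONFIG,
    clock=None,
) -> RunResult:
    """Run one case against a catalog bundle directory.

    The bundle supplies ``transcripts.json``, ``xref_catalog.csv``,
    ``isoforms.fasta``, ``structure_catalog.csv``, ``alignment_catalog.csv``,
    coordinate files, ``sites.csv`` and a ``scores/`` table directory (all of
    which the fixtures module can generate).  Exactly one of ``vcf`` /
    ``case_csv`` selects the input route.  On an unprocessable variant the
    run stops with a halt report unless ``force``.
    """
    bundle = Path(bundle_dir)
    if (vcf is None) == (case_csv is None):
        raise ValueError("provide exactly one of vcf / case_csv")

    # --- phase 1: ingest ---------------------------------------------------
    from .fixtures import load_transcript_models

    log: dict = {}
    if vcf is not None:
        transcripts = load_transcript_models(bundle / "transcripts.json")
        case, ingest_log = case_from_vcf(vcf, transcripts, case_id)
        log["ingest"] = {
            "skipped_vcf_records": len(ingest_log["skipped_vcf_records"]),
            "non_missense": len(ingest_log["non_missense"]),
        }
    else:
        case, row_errors = parse_vustruct_csv(case_csv, case_id=case_id)
        log["ingest"] = {"row_errors": row_errors}

    # --- phase 1b: xref filter + isoform expansion -------------------------
    xrefs = load_xref_catalog(bundle / "xref_catalog.csv")
    retained, rejections = filter_curated(case, xrefs)
    isosets = load_isoform_fasta(bundle / "isoforms.fasta")
    expanded = []
    skipped_isoforms = []
    for v in retained:
        isoset = isosets.get(v.base_protein_id)
        if isoset is None:
            expanded.append(v)
            continue
        try:
            exp = expand_isoforms(v, isoset)
        except ValueError as exc:
            from .xref import Rejection

            rejections.append(Rejection(v, f"isoform mapping failed: {exc}"))
            continue
        for ev in exp.variants:
            iso = next(i for i in isoset.isoforms if i.isoform_id == ev.protein_id)
            check = validate_reference_residue(ev, iso.peptide)
            if check.ok:
                expanded.append(ev)
            else:
                skipped_isoforms.append((ev.protein_id, check.detail))
        skipped_isoforms.extend(exp.skipped)
    log["isoforms_skipped"] = skipped_isoforms

    halt = halt_on_disconnect(case, rejections, n_retained=len(retained), force=force)
    paths = CasePaths(case_id=case_id, guid=guid or str(uuid.uuid4()), base=Path(out_base))
    root = paths.root
    root.mkdir(parents=True, exist_ok=True)
    halt_path = None
    if halt is not None:
        halt_path = root / "halt_report.json"
        halt_path.write_text(halt.to_json() + "\n")
        if halt.stopped:
            return RunResult(
                stopped=True, case_root=root, halt_report_path=halt_path,
                n_input=len(case.variants), n_retained=len(retained), log=log,
            )

    write_vustruct_csv(
        CaseInput(case_id, expanded, ["expanded"] * len(expanded)), root / "vustruct.csv"
    )

    # --- phase 2: structure selection --------------------------------------
    items = []
    peptide_lengths = {}
    for iso_id, pep in _isoform_peptides(isosets).items():
        peptide_lengths[iso_id] = len(pep)
    for v in expanded:
        candidates, warns = load_candidates(
            v.protein_id, bundle / "structure_catalog.csv",
            bundle / "alignment_catalog.csv", structures_root=bundle,
        )
        log.setdefault("structure_warnings", []).extend(warns)
        sel = select_structures(candidates, v.position, cfg.max_structures, cfg)
        items.append((v, sel))

    # --- phase 3: planning ---------------------------------------------------
    params = {
        "pathprox": {
            "alignment_path": str(bundle / "alignment_catalog.csv"),
            "sites_path": str(bundle / "sites.csv"),
            "n_perm": cfg.n_permutations,
        }
    }
    rows = plan_case(case_id, items, enabled_calcs, parameters=params)
    coords_of = {}
    for _, sel in items:
        for c in sel.selected:
            coords_of[c.structure_id] = c.coordinates_path
    for r in rows:
        if r.calc_type == "pathprox":
            r.parameters["coords_path"] = coords_of[r.structure_id]
    write_workplans(rows, root)
    with open(root / "selection_rationale.json", "w") as fh:
        json.dump(
            {
                f"{v.protein_id}:{v.label}": [
                    {"structure_id": r.structure_id, "covers": r.covers_variant,
                     "marginal_utility": r.marginal_utility, "reasons": r.reasons}
                    for r in sel.rationale
                ]
                for v, sel in items
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")

    # --- phase 4: execution --------------------------------------------------
    scores_dir = bundle / "scores"
    context = ExecutorContext(
        case_root=root,
        seed=seed,
        clock=clock,
        config=cfg,
        score_tables=load_score_dir(scores_dir) if scores_dir.is_dir() else {},
        sites_path=bundle / "sites.csv",
        ddg_cache=DdgCache(root / "ddg_repository"),
    )
    statuses = run_local(rows, default_registry(), context)

    # --- phase 5: reporting --------------------------------------------------
    report_paths = render_case_report(root, case_id=case_id, cfg=cfg)
    render_transcript_reports(
        root,
        domains_path=bundle / "domains.tsv",
        peptide_lengths=peptide_lengths,
        cfg=cfg,
    )
    report_paths["case_summary"] = draft_case_summary(root, cfg=cfg)

    return RunResult(
        stopped=False,
        case_root=root,
        halt_report_path=halt_path,
        n_input=len(case.variants),
        n_retained=len(retained),
        n_expanded=len(expanded),
        n_jobs=len(rows),
        statuses={j: s.state for j, s in statuses.items()},
        report_paths=report_paths,
        log=log,
    )


def _isoform_peptides(isosets) -> dict[str, str]:
    out = {}
    for s in isosets.values():
        for iso in s.isoforms:
            out[iso.isoform_id] = iso.peptide
    return out
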