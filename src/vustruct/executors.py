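"""Executors: the native spatial-clustering job plus deterministic stubs.

Every executor shares one contract: it receives a workplan row, its work
directory and an :class:`~vustruct.planner.ExecutorContext`, and writes a
``result.csv`` (columns ``metric,value,qualifier``) into the work directory.
The clustering analysis and precomputed-score lookup run natively.  The
licensed / ML calculators (Rosetta-style ΔΔG, interface surface, PTM site,
digenic pair) are stubs: they emit pseudo-scores derived from a seeded hash
of the job identity, so end-to-end runs are fully reproducible and exercise
the same result plumbing as real calculators would.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path

from .pathprox import (
    attach_coordinates,
    ca_coordinates,
    load_sites_csv,
    multimer_test,
    per_residue_scores,
    write_score_track,
)
from .planner import DdgCacheKey, ExecutorContext, WorkPlanRow
from .structsel import load_alignment_catalog

RESULT_FILE = "result.csv"

#: documented output ranges of the stub calculators
STUB_RANGES = {
    "ddg_monomer": (-1.0, 7.0),  # R.E.U.-like; positive destabilizes
    "ddg_cartesian": (-1.0, 7.0),
    "ppi_surface": (0.0, 1.0),  # interface-disruption probability
    "ptm_site": (0.0, 1.0),  # PTM-site probability
    "digenic_pair": (0.0, 1.0),  # digenic-interaction probability
}
STUB_METRICS = {
    "ddg_monomer": "ddg",
    "ddg_cartesian": "ddg",
    "ppi_surface": "ppi_disruption",
    "ptm_site": "ptm_probability",
    "digenic_pair": "digenic_score",
}


def write_result(workdir: Path, rows: list[tuple[str, object, str]]) -> Path:
    path = Path(workdir) / RESULT_FILE
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "value", "qualifier"])
        for metric, value, qualifier in rows:
            w.writerow([metric, value, qualifier])
    return path


def read_result(workdir: Path) -> list[dict]:
    path = Path(workdir) / RESULT_FILE
    if not path.exists():
        return []
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def _stub_unit(token: str, seed: int) -> float:
    """Deterministic pseudo-uniform in [0,1) from a hash of the job identity."""
    h = hashlib.sha256(f"{token}|{seed}".encode()).digest()
    return int.from_bytes(h[:8], "big") / 2**64


def stub_executor(row: WorkPlanRow, workdir: Path, ctx: ExecutorContext) -> None:
    """Shared stub: emits one hash-derived score in the documented range."""
    lo, hi = STUB_RANGES[row.calc_type]
    v = row.variant
    token = "|".join(
        [
            row.calc_type,
            row.gene,
            v.protein_id if v else "",
            f"{v.position}{v.ref_aa}{v.alt_aa}" if v else "",
            row.structure_id,
        ]
    )
    value = lo + (hi - lo) * _stub_unit(token, ctx.seed)
    extra: list[tuple[str, object, str]] = []
    if row.calc_type.startswith("ddg") and ctx.ddg_cache is not None:
        # exercise the relax-repository contract: one relax per structure/chain
        key = DdgCacheKey(
            structure_id=row.structure_id,
            chain=row.parameters.get("chain", "A"),
            relax_protocol_tag=row.calc_type,
            parameters_hash="default",
        )
        entry = ctx.ddg_cache.get_or_create(
            key, lambda d: (d / "relaxed.txt").write_text(f"relaxed {key.slug()}\n")
        )
        extra.append(("relax_cache_entry", entry.name, "cached"))
    write_result(workdir, [(STUB_METRICS[row.calc_type], f"{value:.6f}", "stub")] + extra)


def pathprox_executor(row: WorkPlanRow, workdir: Path, ctx: ExecutorContext) -> None:
    """Native clustering job: loads the structure's Cα trace, the labeled
    pathogenic/benign sites and the residue map, runs the permutation test on
    every protomer chain, and writes the minimum-p result plus a per-residue
    score track."""
    coords_path = Path(row.parameters["coords_path"])
    sites_path = Path(row.parameters.get("sites_path") or ctx.sites_path)
    alignment_path = Path(row.parameters["alignment_path"])
    n_perm = int(row.parameters.get("n_perm", 199))
    ca = ca_coordinates(coords_path)
    sites = attach_coordinates(load_sites_csv(sites_path, row.structure_id), ca)
    rmap = load_alignment_catalog(alignment_path)[row.structure_id]
    from .config import DEFAULT_CONFIG

    best, per_chain = multimer_test(
        row.variant.position, rmap, sites, ca, n_perm=n_perm, seed=ctx.seed,
        cfg=ctx.config or DEFAULT_CONFIG,
    )
    import math

    rows: list[tuple[str, object, str]] = []
    if best is None:
        rows.append(("pathprox_score", "", "variant unmapped on structure"))
    else:
        qual = best.skipped_reason or f"n_perm={best.n_permutations}"
        score_text = "" if math.isnan(best.score) else f"{best.score:.6f}"
        rows.append(("pathprox_score", score_text, f"chain {best.chain}" + (f"; {best.skipped_reason}" if best.skipped_reason else "")))
        if best.p_value is not None:
            rows.append(("pathprox_pvalue", f"{best.p_value:.6f}", qual))
        else:
            rows.append(("pathprox_pvalue", "", qual))
        for r in per_chain:
            rows.append(
                (
                    f"pathprox_pvalue_chain_{r.chain}",
                    "" if r.p_value is None else f"{r.p_value:.6f}",
                    r.skipped_reason or "",
                )
            )
    write_result(workdir, rows)
    try:
        track = per_residue_scores(sites, ca)
        write_score_track(track, workdir / "residue_scores.csv")
    except Exception:
        pass  # track is best-effort; the result file is the contract


def score_lookup_executor(row: WorkPlanRow, workdir: Path, ctx: ExecutorContext) -> None:
    """Resolve the variant against the loaded precomputed score tables."""
    from .scores import lookup

    tables = ctx.score_tables or {}
    values = lookup(row.variant, tables)
    rows = []
    for name in sorted(tables):
        v = values.get(name)
        if v is None:
            rows.append((name, "", "absent"))
        else:
            rows.append((name, f"{v:.6f}", "precomputed"))
    write_result(workdir, rows)


def default_registry() -> dict:
    """Executor registry covering every registered calc type."""
    return {
        "ddg_monomer": stub_executor,
        "ddg_cartesian": stub_executor,
        "ppi_surface": stub_executor,
        "ptm_site": stub_executor,
        "digenic_pair": stub_executor,
        "pathprox": pathprox_executor,
        "score_lookup": score_lookup_executor,
    }
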