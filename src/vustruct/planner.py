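"""Work planning, the case directory hierarchy, and the job status protocol.

Planning turns (variant, selected-structure) pairs into an architecture-
independent table of calculations — the workplan — with one row per job and
no scheduler concepts anywhere in it.  Each case lives under an isolating
``<case_id>_<guid>`` root, and every job owns a work directory plus a
sibling status directory at

    <root>/<transcript id>/<structure type and id>/<calc type>/{work,status}

Progress is communicated uniformly through the status directory as
append-only, timestamped transition files (planned → submitted → running →
complete | failed); a monitor reconstructs state by listing the directory,
so partially written files degrade to warnings, never crashes.  Execution
is delegated to registered executors — the spatial-clustering analysis runs
natively, while licensed / ML calculators (ΔΔG, interface, PTM, digenic)
ship as deterministic stubs with the same contract.
"""

from __future__ import annotations

import csv
import json
import re
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .ingest import ProteinVariant
from .structsel import SelectionResult, StructureCandidate

CALC_TYPES = (
    "ddg_monomer",
    "ddg_cartesian",
    "pathprox",
    "ppi_surface",
    "ptm_site",
    "digenic_pair",
    "score_lookup",
)
#: calculations that need a structure (one job per variant × structure)
STRUCTURAL_CALCS = ("ddg_monomer", "ddg_cartesian", "pathprox", "ppi_surface")
#: calculations on the protein sequence alone (one job per variant)
SEQUENCE_CALCS = ("ptm_site", "score_lookup")
PAIR_CALCS = ("digenic_pair",)

STATES = ("planned", "submitted", "running", "complete", "failed")
_STATE_ORDER = {s: i for i, s in enumerate(STATES)}
_TERMINAL = {"complete", "failed"}

WORKPLAN_COLUMNS = (
    "job_id", "calc_type", "gene", "protein_id", "position", "ref_aa",
    "alt_aa", "structure_id", "parameters_json", "workdir", "status_dir",
)

_SAFE_RE = re.compile(r"[^A-Za-z0-9._+-]")


def sanitize(component: str) -> str:
    """Restrict a path component to [A-Za-z0-9._+-]; others become '_'."""
    if not component:
        raise ValueError("empty path component")
    return _SAFE_RE.sub("_", component)


@dataclass
class WorkPlanRow:
    job_id: str
    calc_type: str
    variant: ProteinVariant | None
    structure_id: str  # "" for sequence-level and pair jobs
    parameters: dict
    workdir: str  # relative to the case root
    status_dir: str
    gene: str = ""  # pair jobs carry "G1+G2" here

    def __post_init__(self):
        if self.calc_type not in CALC_TYPES:
            raise ValueError(f"unknown calc_type {self.calc_type}")
        if not self.gene and self.variant is not None:
            self.gene = self.variant.gene


@dataclass
class CasePaths:
    """Isolated directory tree for one case run."""

    case_id: str
    guid: str
    base: Path  # parent under which VUStruct/<case>_<guid> is created

    def __post_init__(self):
        uuid.UUID(self.guid)  # validate
        self.base = Path(self.base)

    @property
    def root(self) -> Path:
        return self.base / "VUStruct" / f"{sanitize(self.case_id)}_{self.guid}"


def job_paths(transcript_id: str, structure_label: str, calc_type: str) -> tuple[str, str]:
    """Relative work/status directory pair for one job (injective)."""
    stem = f"{sanitize(transcript_id)}/{sanitize(structure_label)}/{sanitize(calc_type)}"
    return f"{stem}/work", f"{stem}/status"


def plan_case(
    case_id: str,
    items: list[tuple[ProteinVariant, SelectionResult]],
    enabled_calcs: Iterable[str],
    parameters: dict | None = None,
) -> list[WorkPlanRow]:
    """Build the workplan: one row per planned calculation.

    * per variant × selected structure × enabled structural calc → one row
    * per variant → one row per enabled sequence-level calc
    * per unordered pair of distinct genes in the case → one digenic row

    Rows carry only calculation identity, parameters and relative paths —
    planning is independent of any particular execution architecture.
    """
    enabled = list(enabled_calcs)
    unknown = set(enabled) - set(CALC_TYPES)
    if unknown:
        raise ValueError(f"unknown calc types: {sorted(unknown)}")
    if not enabled:
        raise ValueError("enabled_calcs must be non-empty")
    params = parameters or {}
    rows: list[WorkPlanRow] = []
    used_paths: dict[str, str] = {}
    counter = 0

    def add(calc_type, variant, structure_label, structure_id, gene=""):
        nonlocal counter
        counter += 1
        job_id = f"{sanitize(case_id)}_{counter:04d}"
        row_params = dict(params.get(calc_type, {}))
        if variant is not None:
            # persists the canonical-variant identity through the CSV round trip
            row_params["variant_group"] = variant.group_label
        workdir, status_dir = job_paths(
            variant.transcript_id if variant else "_case", structure_label, calc_type
        )
        claim = f"{workdir}"
        prior = used_paths.get(claim)
        if prior is not None:
            raise ValueError(f"path collision after sanitization: {claim} ({prior})")
        used_paths[claim] = job_id
        rows.append(
            WorkPlanRow(
                job_id=job_id,
                calc_type=calc_type,
                variant=variant,
                structure_id=structure_id,
                parameters=row_params,
                workdir=workdir,
                status_dir=status_dir,
                gene=gene,
            )
        )

    for variant, selection in items:
        vtag = variant.label
        for calc in STRUCTURAL_CALCS:
            if calc not in enabled:
                continue
            for cand in selection.selected:
                add(
                    calc,
                    variant,
                    f"{cand.source}_{cand.structure_id}__{sanitize(variant.protein_id or 'NA')}_{vtag}",
                    cand.structure_id,
                )
        for calc in SEQUENCE_CALCS:
            if calc in enabled:
                add(calc, variant, f"SEQ__{sanitize(variant.protein_id or 'NA')}__{vtag}", "")
    if "digenic_pair" in enabled:
        genes = sorted({v.gene for v, _ in items if v.gene})
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1 :]:
                add("digenic_pair", None, f"digenic__{sanitize(g1)}__{sanitize(g2)}", "", gene=f"{g1}+{g2}")
    return rows


def write_workplan(rows: list[WorkPlanRow], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(WORKPLAN_COLUMNS)
        for r in rows:
            v = r.variant
            w.writerow(
                [
                    r.job_id, r.calc_type, r.gene,
                    v.protein_id if v else "", v.position if v else "",
                    v.ref_aa if v else "", v.alt_aa if v else "",
                    r.structure_id, json.dumps(r.parameters, sort_keys=True),
                    r.workdir, r.status_dir,
                ]
            )


def read_workplan(path: str | Path) -> list[WorkPlanRow]:
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            variant = None
            parameters = json.loads(rec["parameters_json"])
            if rec["position"]:
                variant = ProteinVariant(
                    gene=rec["gene"],
                    protein_id=rec["protein_id"],
                    transcript_id=rec["workdir"].split("/")[0],
                    position=int(rec["position"]),
                    ref_aa=rec["ref_aa"],
                    alt_aa=rec["alt_aa"],
                    canonical_label=parameters.get("variant_group", ""),
                )
            rows.append(
                WorkPlanRow(
                    job_id=rec["job_id"],
                    calc_type=rec["calc_type"],
                    variant=variant,
                    structure_id=rec["structure_id"],
                    parameters=parameters,
                    workdir=rec["workdir"],
                    status_dir=rec["status_dir"],
                    gene=rec["gene"],
                )
            )
    return rows


def write_workplans(rows: list[WorkPlanRow], root: Path) -> list[Path]:
    """Write the master workplan.csv plus one per transcript subdirectory."""
    root = Path(root)
    written = [root / "workplan.csv"]
    write_workplan(rows, written[0])
    by_dir: dict[str, list[WorkPlanRow]] = {}
    for r in rows:
        by_dir.setdefault(r.workdir.split("/")[0], []).append(r)
    for sub, subrows in sorted(by_dir.items()):
        p = root / sub / "workplan.csv"
        write_workplan(subrows, p)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# status protocol
# ---------------------------------------------------------------------------


@dataclass
class StatusEvent:
    state: str
    timestamp: str  # ISO-8601
    detail: str = ""
    exit_info: str | None = None


@dataclass
class JobStatus:
    state: str
    history: list[StatusEvent] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return self.state in _TERMINAL


def _iso_now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()) + "Z"


class LogicalClock:
    """Deterministic stand-in clock: monotone ISO timestamps from a counter.

    Useful when a run must be byte-reproducible (status files embed their
    timestamps); the wall clock remains the default.
    """

    def __init__(self):
        self.tick = 0

    def __call__(self) -> str:
        self.tick += 1
        return f"1970-01-01T00:00:{min(self.tick, 59):02d}Z#{self.tick:06d}"


def write_status(
    status_dir: str | Path,
    state: str,
    detail: str = "",
    exit_info: str | None = None,
    clock: Callable[[], str] | None = None,
) -> Path:
    """Append one transition file; rejects backward transitions."""
    if state not in STATES:
        raise ValueError(f"unknown state {state}")
    status_dir = Path(status_dir)
    status_dir.mkdir(parents=True, exist_ok=True)
    current = read_status(status_dir)
    if _STATE_ORDER[state] < _STATE_ORDER[current.state]:
        raise ValueError(f"backward transition {current.state} -> {state}")
    if current.is_terminal and state != current.state:
        raise ValueError(f"job already terminal ({current.state})")
    seq = len(current.history) + 1
    path = status_dir / f"{seq:04d}_{state}.json"
    payload = {
        "state": state,
        "timestamp": (clock or _iso_now)(),
        "detail": detail,
        "exit_info": exit_info,
    }
    path.write_text(json.dumps(payload, sort_keys=True) + "\n")
    return path


def read_status(status_dir: str | Path) -> JobStatus:
    """Reconstruct the latest state and history from a status directory.

    An empty or missing directory reads as implicit ``planned``; unreadable
    or partially written files are skipped (the monitor warns, never dies).
    """
    status_dir = Path(status_dir)
    history: list[StatusEvent] = []
    if status_dir.is_dir():
        for f in sorted(status_dir.iterdir()):
            if not f.name.endswith(".json"):
                continue
            try:
                data = json.loads(f.read_text())
                history.append(
                    StatusEvent(
                        state=data["state"],
                        timestamp=data.get("timestamp", ""),
                        detail=data.get("detail", ""),
                        exit_info=data.get("exit_info"),
                    )
                )
            except (json.JSONDecodeError, KeyError, OSError):
                continue  # torn write; ignore with implicit warning semantics
    state = history[-1].state if history else "planned"
    return JobStatus(state=state, history=history)


# ---------------------------------------------------------------------------
# relaxed-structure cache (two-part ΔΔG protocols)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DdgCacheKey:
    structure_id: str
    chain: str
    relax_protocol_tag: str
    parameters_hash: str

    def slug(self) -> str:
        return sanitize(
            f"{self.structure_id}_{self.chain}_{self.relax_protocol_tag}_{self.parameters_hash}"
        )


class DdgCache:
    """Keyed repository of relaxed-structure artifacts.

    The expensive "relax" half of a two-part stability protocol is computed
    once per (structure, chain, protocol, parameters) and reused; corrupt
    entries are recomputed and overwritten with a warning.
    """

    def __init__(self, cache_dir: str | Path):
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.produce_calls = 0
        self.warnings: list[str] = []

    def _entry(self, key: DdgCacheKey) -> Path:
        return self.cache_dir / key.slug()

    def get_or_create(self, key: DdgCacheKey, produce: Callable[[Path], None]) -> Path:
        entry = self._entry(key)
        marker = entry / ".complete"
        if entry.exists():
            if marker.exists():
                return entry
            self.warnings.append(f"corrupt cache entry {entry.name}; recomputing")
            for f in sorted(entry.rglob("*"), reverse=True):
                f.unlink() if f.is_file() else f.rmdir()
        entry.mkdir(parents=True, exist_ok=True)
        self.produce_calls += 1
        produce(entry)
        marker.write_text("ok\n")
        return entry

    def clear(self) -> None:
        import shutil

        shutil.rmtree(self.cache_dir)
        self.cache_dir.mkdir(parents=True)


# ---------------------------------------------------------------------------
# local runner
# ---------------------------------------------------------------------------


@dataclass
class ExecutorContext:
    """Everything an executor may need, bundled once per run."""

    case_root: Path
    seed: int
    clock: Callable[[], str] | None = None
    config: object = None
    score_tables: dict | None = None
    sites_path: Path | None = None
    ddg_cache: DdgCache | None = None
    extras: dict = field(default_factory=dict)


Executor = Callable[[WorkPlanRow, Path, ExecutorContext], None]


def run_local(
    rows: list[WorkPlanRow],
    registry: dict[str, Executor],
    context: ExecutorContext,
    max_parallel: int = 1,
) -> dict[str, JobStatus]:
    """Execute every planned job through its registered executor.

    Jobs run in workplan order (``max_parallel`` is accepted for interface
    compatibility but execution is serialized for determinism).  An executor
    exception marks only its own job failed, with the error captured in the
    status detail; every job ends in exactly one terminal state.
    """
    missing = {r.calc_type for r in rows} - set(registry)
    if missing:
        raise ValueError(f"no executor registered for: {sorted(missing)}")
    statuses: dict[str, JobStatus] = {}
    for row in rows:
        workdir = context.case_root / row.workdir
        status_dir = context.case_root / row.status_dir
        workdir.mkdir(parents=True, exist_ok=True)
        write_status(status_dir, "planned", clock=context.clock)
        write_status(status_dir, "submitted", detail=f"local:{row.job_id}", clock=context.clock)
        write_status(status_dir, "running", clock=context.clock)
        try:
            registry[row.calc_type](row, workdir, context)
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            write_status(
                status_dir, "failed",
                detail=f"{type(exc).__name__}: {exc}", exit_info="1",
                clock=context.clock,
            )
        else:
            write_status(status_dir, "complete", exit_info="0", clock=context.clock)
        statuses[row.job_id] = read_status(status_dir)
    return statuses
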