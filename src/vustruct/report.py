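"""Case-wide reporting: range aggregation, landing page, summary spreadsheet.

Because several structures (and, for genomic input, several transcript
isoforms) are analysed per variant, each calculated metric is presented as a
[min, max] range with the number of contributing results; absent results are
counted, never coerced to zero.  The landing page is an HTML table — one
summary row per variant, expandable into per-isoform child rows, canonical
isoform first — with a digenic section and a per-job status block.  A CSV
twin carries the same ranges machine-readably, and a clinician-facing case
summary spreadsheet condenses everything to one flagged line per variant.

Rendering is a pure function of the files on disk: re-rendering while jobs
are still completing updates cell content only, and rendering twice from
unchanged results is byte-identical.
"""

from __future__ import annotations

import csv
import html as _html
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .config import Config, DEFAULT_CONFIG
from .executors import read_result
from .ingest import isoform_number
from .planner import WorkPlanRow, read_status, read_workplan

#: metric(s) each calculation is expected to deliver (for missing-count
#: accounting when a job fails outright)
EXPECTED_METRICS = {
    "ddg_monomer": ["ddg"],
    "ddg_cartesian": ["ddg"],
    "ppi_surface": ["ppi_disruption"],
    "ptm_site": ["ptm_probability"],
    "pathprox": ["pathprox_score", "pathprox_pvalue"],
}

plt.rcParams["svg.hashsalt"] = "vustruct"  # deterministic SVG ids


@dataclass
class MetricRange:
    min: float
    max: float
    n_structures: int
    n_missing: int = 0

    def merge_value(self, v: float) -> None:
        self.min = min(self.min, v)
        self.max = max(self.max, v)
        self.n_structures += 1


@dataclass
class ChildRow:
    protein_id: str
    transcript_id: str
    variant_label: str
    ranges: dict[str, MetricRange] = field(default_factory=dict)

    @property
    def is_canonical(self) -> bool:
        return isoform_number(self.protein_id) == 1


@dataclass
class VariantSummaryRow:
    gene: str
    variant_label: str  # canonical-isoform label
    ranges: dict[str, MetricRange] = field(default_factory=dict)
    children: list[ChildRow] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _accumulate(ranges: dict[str, MetricRange], metric: str, value) -> None:
    try:
        v = float(value)
        if math.isnan(v):
            raise ValueError
    except (TypeError, ValueError):
        r = ranges.setdefault(metric, MetricRange(math.inf, -math.inf, 0, 0))
        r.n_missing += 1
        return
    r = ranges.get(metric)
    if r is None:
        ranges[metric] = MetricRange(v, v, 1, 0)
    else:
        r.merge_value(v)


def aggregate_ranges(results: list[tuple[WorkPlanRow, list[dict], str]]) -> dict[str, MetricRange]:
    """Fold job results into per-metric [min, max] ranges.

    ``results`` pairs each workplan row with its parsed result rows and its
    terminal state.  Failed or silent jobs count toward ``n_missing`` for
    the metrics their calculation was expected to deliver.
    """
    ranges: dict[str, MetricRange] = {}
    for row, res_rows, state in results:
        if not res_rows:
            for metric in EXPECTED_METRICS.get(row.calc_type, []):
                r = ranges.setdefault(metric, MetricRange(math.inf, -math.inf, 0, 0))
                r.n_missing += 1
            continue
        for rr in res_rows:
            if rr["metric"].startswith("pathprox_pvalue_chain_") or rr["metric"] == "relax_cache_entry":
                continue  # per-chain detail / cache bookkeeping, not summary metrics
            _accumulate(ranges, rr["metric"], rr["value"])
    return ranges


def expand_isoform_rows(children: list[ChildRow]) -> list[ChildRow]:
    """Order child rows: canonical isoform first, then '-N' numerically."""
    return sorted(children, key=lambda c: (not c.is_canonical, isoform_number(c.protein_id), c.protein_id))


# ---------------------------------------------------------------------------
# collection from a case directory
# ---------------------------------------------------------------------------


@dataclass
class CaseResults:
    rows: list[WorkPlanRow]
    per_job: dict[str, tuple[list[dict], str]]  # job_id -> (result rows, state)
    summary_rows: list[VariantSummaryRow]
    digenic: list[dict]

    @property
    def statuses(self) -> dict[str, str]:
        return {jid: state for jid, (_, state) in self.per_job.items()}


def collect_case(case_root: str | Path, cfg: Config = DEFAULT_CONFIG) -> CaseResults:
    """Read the workplan, every result file and every status directory, and
    aggregate variant-level ranges plus digenic outputs."""
    case_root = Path(case_root)
    rows = read_workplan(case_root / "workplan.csv")
    per_job: dict[str, tuple[list[dict], str]] = {}
    for row in rows:
        state = read_status(case_root / row.status_dir).state
        per_job[row.job_id] = (read_result(case_root / row.workdir), state)

    groups: dict[tuple, list[WorkPlanRow]] = {}
    for row in rows:
        if row.variant is None:
            continue
        v = row.variant
        key = (v.gene, v.base_protein_id, v.group_label)
        groups.setdefault(key, []).append(row)

    summary_rows = []
    for key in sorted(groups):
        gene, base_pid, group_label = key
        grows = groups[key]
        triplets = [(r, *per_job[r.job_id]) for r in grows]
        child_keys = sorted({(r.variant.protein_id, r.variant.transcript_id) for r in grows})
        children = []
        for pid, tid in child_keys:
            crows = [t for t in triplets if t[0].variant.protein_id == pid]
            label = crows[0][0].variant.label
            children.append(
                ChildRow(pid, tid, label, ranges=aggregate_ranges(crows))
            )
        children = expand_isoform_rows(children)
        canonical = next((c for c in children if c.is_canonical), children[0])
        summary_rows.append(
            VariantSummaryRow(
                gene=gene,
                variant_label=canonical.variant_label,
                ranges=aggregate_ranges(triplets),
                children=children,
            )
        )
    digenic = []
    for row in rows:
        if row.calc_type != "digenic_pair":
            continue
        res, state = per_job[row.job_id]
        score = next((r["value"] for r in res if r["metric"] == "digenic_score"), "")
        digenic.append({"pair": row.gene, "score": score, "state": state})
    digenic.sort(key=lambda d: d["pair"])
    out = CaseResults(rows, per_job, summary_rows, digenic)
    _apply_flags(out, cfg)
    return out


def _apply_flags(case: CaseResults, cfg: Config) -> None:
    digenic_partners: dict[str, list[str]] = {}
    for d in case.digenic:
        try:
            strong = float(d["score"]) >= cfg.digenic_flag
        except ValueError:
            strong = False
        if strong:
            g1, g2 = d["pair"].split("+")
            digenic_partners.setdefault(g1, []).append(g2)
            digenic_partners.setdefault(g2, []).append(g1)
    for row in case.summary_rows:
        flags = []
        r = row.ranges
        if "ddg" in r and r["ddg"].n_structures and r["ddg"].max >= cfg.ddg_flag:
            flags.append("destabilizing_ddg")
        if (
            "pathprox_pvalue" in r
            and r["pathprox_pvalue"].n_structures
            and r["pathprox_pvalue"].min <= cfg.pathprox_p_flag
        ):
            flags.append("pathogenic_clustering")
        if "ppi_disruption" in r and r["ppi_disruption"].n_structures and r["ppi_disruption"].max >= cfg.ppi_flag:
            flags.append("interface_hit")
        if "ptm_probability" in r and r["ptm_probability"].n_structures and r["ptm_probability"].max >= cfg.ptm_flag:
            flags.append("ptm_hit")
        partners = sorted(set(digenic_partners.get(row.gene, [])))
        if partners:
            flags.append("digenic:" + "|".join(partners))
        row.flags = flags


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _fmt_range(r: MetricRange) -> str:
    if r.n_structures == 0:
        return f"pending ({r.n_missing} missing)" if r.n_missing else "pending"
    s = f"{r.min:.3g}" if r.min == r.max else f"{r.min:.3g} … {r.max:.3g}"
    s += f" (n={r.n_structures}"
    if r.n_missing:
        s += f", missing={r.n_missing}"
    return s + ")"


def _metrics_union(case: CaseResults) -> list[str]:
    metrics: set[str] = set()
    for row in case.summary_rows:
        metrics |= set(row.ranges)
    return sorted(metrics)


def render_case_report(
    case_root: str | Path,
    out_dir: str | Path | None = None,
    case_id: str = "",
    cfg: Config = DEFAULT_CONFIG,
) -> dict[str, Path]:
    """Render the landing page (HTML) and its machine-readable CSV twin.

    Both are derived purely from the current result/status files, so the
    report can be refreshed at any point of a run; completed jobs replace
    "pending" cells without changing the table schema.
    """
    case_root = Path(case_root)
    out = Path(out_dir) if out_dir else case_root / "report"
    out.mkdir(parents=True, exist_ok=True)
    case = collect_case(case_root, cfg)
    metrics = _metrics_union(case)

    esc = _html.escape
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Case report {esc(case_id)}</title>",
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:3px 8px;font:13px sans-serif}tr.iso td{background:#f4f6fa}</style>",
        "</head><body>",
        f"<h1>Case report {esc(case_id)}</h1>",
        "<h2>Variant summary</h2>",
        "<p>Each row summarises the range of calculated values for one variant; "
        "ranges arise because multiple structures (and isoforms) are considered.</p>",
        "<table><tr><th>gene</th><th>variant</th><th>isoform</th>"
        + "".join(f"<th>{esc(m)}</th>" for m in metrics)
        + "<th>flags</th></tr>",
    ]
    for row in case.summary_rows:
        cells = "".join(
            f"<td>{esc(_fmt_range(row.ranges[m])) if m in row.ranges else ''}</td>" for m in metrics
        )
        parts.append(
            f"<tr><td>{esc(row.gene)}</td><td>{esc(row.variant_label)}</td>"
            f"<td>all ({len(row.children)})</td>{cells}<td>{esc(', '.join(row.flags))}</td></tr>"
        )
        for c in row.children:
            ccells = "".join(
                f"<td>{esc(_fmt_range(c.ranges[m])) if m in c.ranges else ''}</td>" for m in metrics
            )
            parts.append(
                f"<tr class='iso'><td></td><td>{esc(c.variant_label)}</td>"
                f"<td><a href='transcript_{esc(c.protein_id)}.html'>{esc(c.protein_id)}</a></td>"
                f"{ccells}<td></td></tr>"
            )
    parts.append("</table>")

    parts.append("<h2>Digenic analysis</h2>")
    if case.digenic:
        parts.append("<table><tr><th>gene pair</th><th>score</th><th>status</th></tr>")
        for d in case.digenic:
            parts.append(
                f"<tr><td>{esc(d['pair'])}</td><td>{esc(d['score'] or 'pending')}</td>"
                f"<td>{esc(d['state'])}</td></tr>"
            )
        parts.append("</table>")
    else:
        parts.append("<p>No digenic pairs (fewer than two genes in the case).</p>")

    parts.append("<h2>Job status</h2><table><tr><th>job</th><th>calculation</th><th>state</th></tr>")
    for row in case.rows:
        parts.append(
            f"<tr><td>{esc(row.job_id)}</td><td>{esc(row.calc_type)}</td>"
            f"<td>{esc(case.statuses[row.job_id])}</td></tr>"
        )
    parts.append("</table></body></html>")
    html_path = out / "index.html"
    html_path.write_text("\n".join(parts) + "\n")

    csv_path = out / "case_report.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene", "variant", "protein_id", "metric", "min", "max",
                    "n_structures", "n_missing", "flags"])
        for row in case.summary_rows:
            for m in sorted(row.ranges):
                r = row.ranges[m]
                w.writerow([row.gene, row.variant_label, "ALL", m,
                            "" if r.n_structures == 0 else repr(r.min),
                            "" if r.n_structures == 0 else repr(r.max),
                            r.n_structures, r.n_missing, ";".join(row.flags)])
            for c in row.children:
                for m in sorted(c.ranges):
                    r = c.ranges[m]
                    w.writerow([row.gene, c.variant_label, c.protein_id, m,
                                "" if r.n_structures == 0 else repr(r.min),
                                "" if r.n_structures == 0 else repr(r.max),
                                r.n_structures, r.n_missing, ""])
    return {"html": html_path, "csv": csv_path, "out_dir": out}


def parse_report_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def draft_case_summary(
    case_root: str | Path,
    out_path: str | Path | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> Path:
    """One flagged line per variant for the clinical audience; the free-text
    recommendation column is deliberately left blank for the analyst."""
    case_root = Path(case_root)
    case = collect_case(case_root, cfg)
    out_path = Path(out_path) if out_path else case_root / "report" / "case_summary.csv"
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["gene", "variant", "n_isoforms", "destabilizing_ddg",
             "pathogenic_clustering", "interface_hit", "ptm_hit",
             "digenic_partners", "recommendation"]
        )
        for row in case.summary_rows:
            partners = ""
            for f in row.flags:
                if f.startswith("digenic:"):
                    partners = f.split(":", 1)[1].replace("|", ";")
            w.writerow(
                [
                    row.gene, row.variant_label, len(row.children),
                    "X" if "destabilizing_ddg" in row.flags else "",
                    "X" if "pathogenic_clustering" in row.flags else "",
                    "X" if "interface_hit" in row.flags else "",
                    "X" if "ptm_hit" in row.flags else "",
                    partners, "",
                ]
            )
    return out_path


# ---------------------------------------------------------------------------
# transcript reports with domain track
# ---------------------------------------------------------------------------


def load_domains(path: str | Path) -> dict[str, list[dict]]:
    """BED-like domain table: protein_id<TAB>domain<TAB>start<TAB>end."""
    out: dict[str, list[dict]] = {}
    p = Path(path)
    if not p.exists():
        return out
    with open(p) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            pid, name, start, end = line.rstrip("\n").split("\t")[:4]
            out.setdefault(pid, []).append({"domain": name, "start": int(start), "end": int(end)})
    return out


def domain_track_svg(
    protein_id: str,
    length: int,
    domains: list[dict],
    variant_positions: list[int],
    out_path: str | Path,
) -> Path:
    """Static domain-architecture graphic with the variant site(s) marked
    (diamond above the backbone)."""
    fig, ax = plt.subplots(figsize=(7, 1.6))
    ax.hlines(0.5, 1, length, colors="#888", lw=3, zorder=1)
    palette = ["#4878d0", "#ee854a", "#6acc64", "#d65f5f", "#956cb4"]
    for i, d in enumerate(sorted(domains, key=lambda d: d["start"])):
        ax.barh(0.5, d["end"] - d["start"] + 1, left=d["start"], height=0.45,
                color=palette[i % len(palette)], zorder=2)
        ax.text((d["start"] + d["end"]) / 2, 0.5, d["domain"], ha="center",
                va="center", fontsize=7, zorder=3)
    for pos in variant_positions:
        ax.scatter([pos], [0.92], marker="D", s=45, color="#e75480", zorder=4)
    ax.set_xlim(0, length + 1)
    ax.set_ylim(0, 1.15)
    ax.set_yticks([])
    ax.set_xlabel(f"{protein_id} residue")
    ax.spines[["left", "top", "right"]].set_visible(False)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, format="svg", metadata={"Date": None})
    plt.close(fig)
    return out_path


def render_transcript_reports(
    case_root: str | Path,
    out_dir: str | Path | None = None,
    domains_path: str | Path | None = None,
    peptide_lengths: dict[str, int] | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> list[Path]:
    """Per-isoform report pages: domain graphic, structure summary table
    (each selected structure exactly once) and per-structure result blocks."""
    case_root = Path(case_root)
    out = Path(out_dir) if out_dir else case_root / "report"
    out.mkdir(parents=True, exist_ok=True)
    case = collect_case(case_root, cfg)
    domains = load_domains(domains_path) if domains_path else {}
    lengths = peptide_lengths or {}
    esc = _html.escape
    written = []
    for srow in case.summary_rows:
        for child in srow.children:
            jobs = [
                r for r in case.rows
                if r.variant is not None and r.variant.protein_id == child.protein_id
            ]
            structures = sorted({r.structure_id for r in jobs if r.structure_id})
            pos = int(child.variant_label[1:-1])
            length = lengths.get(child.protein_id, max([pos + 10] + [d["end"] for d in domains.get(child.protein_id, [])]))
            svg_name = f"domains_{child.protein_id}.svg"
            domain_track_svg(child.protein_id, length, domains.get(child.protein_id, []), [pos], out / svg_name)
            parts = [
                "<!DOCTYPE html><html><head><meta charset='utf-8'>",
                f"<title>{esc(child.protein_id)} {esc(child.variant_label)}</title></head><body>",
                f"<h1>{esc(srow.gene)} {esc(child.variant_label)} on {esc(child.protein_id)} "
                f"({esc(child.transcript_id)})</h1>",
                f"<img src='{svg_name}' alt='domain track'>",
                "<h2>Structure summary</h2>",
                "<table border='1'><tr><th>structure</th><th>calculations</th></tr>",
            ]
            for sid in structures:
                calcs = sorted({r.calc_type for r in jobs if r.structure_id == sid})
                parts.append(f"<tr><td>{esc(sid)}</td><td>{esc(', '.join(calcs))}</td></tr>")
            parts.append("</table><h2>Per-structure results</h2>")
            for sid in structures:
                parts.append(f"<h3>{esc(sid)}</h3><table border='1'><tr><th>metric</th><th>value</th><th>qualifier</th></tr>")
                for r in jobs:
                    if r.structure_id != sid:
                        continue
                    res, state = case.per_job[r.job_id]
                    if not res:
                        parts.append(f"<tr><td colspan='3'>{esc(r.calc_type)}: {esc(state)}</td></tr>")
                    for rr in res:
                        parts.append(
                            f"<tr><td>{esc(rr['metric'])}</td><td>{esc(rr['value'])}</td>"
                            f"<td>{esc(rr['qualifier'])}</td></tr>"
                        )
                parts.append("</table>")
            parts.append("</body></html>")
            p = out / f"transcript_{child.protein_id}.html"
            p.write_text("\n".join(parts) + "\n")
            written.append(p)
    return written
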