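"""Work planning, directory protocol, status files, local execution, cache."""

import json

import pytest

from vustruct.executors import default_registry, read_result, stub_executor
from vustruct.ingest import ProteinVariant
from vustruct.planner import (
    CasePaths,
    DdgCache,
    DdgCacheKey,
    ExecutorContext,
    LogicalClock,
    WORKPLAN_COLUMNS,
    job_paths,
    plan_case,
    read_status,
    read_workplan,
    run_local,
    sanitize,
    write_status,
    write_workplan,
)
from vustruct.structsel import MapSegment, ResidueMap, SelectionResult, StructureCandidate


def mk_sel(n_structures):
    cands = [
        StructureCandidate(
            f"S{i}", "PDB", "xray", 2.0, 1, "",
            ResidueMap(f"S{i}", [MapSegment("A", 1, 1, 100)]),
        )
        for i in range(n_structures)
    ]
    return SelectionResult(cands, [])


def mk_variant(gene="G1", pid="P1", tid="T1", pos=10):
    return ProteinVariant(gene, pid, tid, pos, "A", "V")


class TestPlanCase:
    def test_structural_cross_product(self):
        rows = plan_case("c", [(mk_variant(), mk_sel(2))], ["ddg_cartesian", "pathprox"])
        structural = [r for r in rows if r.structure_id]
        assert len(structural) == 4  # 1 variant x 2 structures x 2 calcs

    def test_sequence_level_rows_per_variant(self):
        rows = plan_case("c", [(mk_variant(), mk_sel(2))], ["ptm_site", "score_lookup"])
        assert len(rows) == 2 and all(r.structure_id == "" for r in rows)

    def test_digenic_pairs_choose_two(self):
        items = [
            (mk_variant("G1", "P1", "T1"), mk_sel(1)),
            (mk_variant("G2", "P2", "T2"), mk_sel(1)),
            (mk_variant("G3", "P3", "T3"), mk_sel(1)),
        ]
        rows = plan_case("c", items, ["digenic_pair"])
        assert sorted(r.gene for r in rows) == ["G1+G2", "G1+G3", "G2+G3"]

    def test_single_gene_no_digenic(self):
        rows = plan_case("c", [(mk_variant(), mk_sel(1))], ["digenic_pair"])
        assert rows == []

    def test_plan_determinism(self, tmp_path):
        items = [(mk_variant(), mk_sel(2))]
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_workplan(plan_case("c", items, ["pathprox", "ptm_site"]), a)
        write_workplan(plan_case("c", items, ["pathprox", "ptm_site"]), b)
        assert a.read_bytes() == b.read_bytes()

    def test_workplan_schema_is_scheduler_free(self, tmp_path):
        rows = plan_case("c", [(mk_variant(), mk_sel(1))], ["pathprox"])
        p = tmp_path / "w.csv"
        write_workplan(rows, p)
        header = p.read_text().splitlines()[0].split(",")
        assert tuple(header) == WORKPLAN_COLUMNS
        for banned in ("slurm", "partition", "host", "container"):
            assert banned not in p.read_text().lower()

    def test_workplan_round_trip(self, tmp_path):
        rows = plan_case("c", [(mk_variant(), mk_sel(2))], ["pathprox", "score_lookup"])
        p = tmp_path / "w.csv"
        write_workplan(rows, p)
        back = read_workplan(p)
        assert [(r.job_id, r.calc_type, r.structure_id, r.workdir) for r in back] == [
            (r.job_id, r.calc_type, r.structure_id, r.workdir) for r in rows
        ]


class TestPaths:
    def test_template_instantiation(self):
        work, status = job_paths("T1", "PDB_1ABC", "pathprox")
        assert work == "T1/PDB_1ABC/pathprox/work"
        assert status == "T1/PDB_1ABC/pathprox/status"

    def test_calc_type_distinguishes_paths(self):
        a, _ = job_paths("T1", "S", "pathprox")
        b, _ = job_paths("T1", "S", "ddg_monomer")
        assert a != b

    def test_sanitization_keeps_injectivity(self):
        assert sanitize("PDB:1ABC/x") == "PDB_1ABC_x"
        with pytest.raises(ValueError):
            sanitize("")

    def test_guid_validated(self, tmp_path):
        with pytest.raises(ValueError):
            CasePaths("c", "not-a-guid", tmp_path)
        cp = CasePaths("my case", "00000000-0000-4000-8000-000000000001", tmp_path)
        assert "my_case_00000000" in str(cp.root)


class TestStatusProtocol:
    def test_transitions_recorded_and_replayed(self, tmp_path):
        d = tmp_path / "status"
        for s in ("planned", "running", "complete"):
            write_status(d, s)
        js = read_status(d)
        assert js.state == "complete"
        assert [e.state for e in js.history] == ["planned", "running", "complete"]

    def test_empty_dir_reads_planned(self, tmp_path):
        assert read_status(tmp_path / "nowhere").state == "planned"

    def test_failure_detail_surfaced_verbatim(self, tmp_path):
        d = tmp_path / "status"
        write_status(d, "planned")
        write_status(d, "failed", detail="executor exploded: boom")
        js = read_status(d)
        assert js.state == "failed"
        assert js.history[-1].detail == "executor exploded: boom"

    def test_backward_transition_rejected(self, tmp_path):
        d = tmp_path / "status"
        write_status(d, "running")
        with pytest.raises(ValueError):
            write_status(d, "planned")

    def test_terminal_state_frozen(self, tmp_path):
        d = tmp_path / "status"
        write_status(d, "complete")
        with pytest.raises(ValueError):
            write_status(d, "failed")

    def test_torn_file_ignored(self, tmp_path):
        d = tmp_path / "status"
        write_status(d, "planned")
        write_status(d, "running")
        (d / "0002a_garbage.json").write_text("{not json")
        js = read_status(d)
        assert js.state == "running" and len(js.history) == 2


def _ten_row_plan():
    items = [
        (mk_variant("G1", "P1", "T1", 5), mk_sel(2)),
        (mk_variant("G2", "P2", "T2", 7), mk_sel(2)),
    ]
    rows = plan_case("c", items, ["ddg_cartesian", "ptm_site", "digenic_pair"])
    assert len(rows) == 2 * 2 + 2 + 1  # 4 structural + 2 sequence + 1 pair
    return rows


class TestRunLocal:
    def test_all_stub_rows_complete_with_result_files(self, tmp_path):
        rows = _ten_row_plan()
        ctx = ExecutorContext(case_root=tmp_path, seed=3, clock=LogicalClock())
        statuses = run_local(rows, default_registry(), ctx)
        assert all(s.state == "complete" for s in statuses.values())
        for r in rows:
            assert (tmp_path / r.workdir / "result.csv").exists()

    def test_single_failure_isolated(self, tmp_path):
        rows = _ten_row_plan()

        def boom(row, workdir, ctx):
            raise RuntimeError("synthetic failure")

        registry = dict(default_registry())
        registry["ptm_site"] = boom
        ctx = ExecutorContext(case_root=tmp_path, seed=3, clock=LogicalClock())
        statuses = run_local(rows, registry, ctx)
        failed = {j for j, s in statuses.items() if s.state == "failed"}
        assert len(failed) == 2  # exactly the two ptm_site jobs
        detail = read_status(tmp_path / [r for r in rows if r.job_id in failed][0].status_dir)
        assert "synthetic failure" in detail.history[-1].detail
        assert all(s.state == "complete" for j, s in statuses.items() if j not in failed)

    def test_rerun_same_seed_byte_identical_results(self, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        blobs = []
        for out in (out1, out2):
            rows = _ten_row_plan()
            ctx = ExecutorContext(case_root=out, seed=9, clock=LogicalClock())
            run_local(rows, default_registry(), ctx)
            blobs.append(
                {str(p.relative_to(out)): p.read_bytes() for p in sorted(out.rglob("result.csv"))}
            )
        assert blobs[0] == blobs[1]

    def test_missing_executor_rejected(self, tmp_path):
        rows = _ten_row_plan()
        with pytest.raises(ValueError):
            run_local(rows, {}, ExecutorContext(case_root=tmp_path, seed=0))

    def test_conservation_rows_vs_terminal_states(self, tmp_path):
        rows = _ten_row_plan()
        ctx = ExecutorContext(case_root=tmp_path, seed=3, clock=LogicalClock())
        statuses = run_local(rows, default_registry(), ctx)
        n_results = sum((tmp_path / r.workdir / "result.csv").exists() for r in rows)
        n_failed = sum(s.state == "failed" for s in statuses.values())
        assert len(rows) == len(statuses) == n_results + n_failed


class TestDdgCache:
    def test_same_key_produces_once(self, tmp_path):
        cache = DdgCache(tmp_path / "repo")
        key = DdgCacheKey("S1", "A", "cartesian", "h1")
        for _ in range(3):
            cache.get_or_create(key, lambda d: (d / "r.txt").write_text("relaxed\n"))
        assert cache.produce_calls == 1

    def test_distinct_protocol_tags_distinct_entries(self, tmp_path):
        cache = DdgCache(tmp_path / "repo")
        produce = lambda d: (d / "r.txt").write_text("x\n")
        cache.get_or_create(DdgCacheKey("S1", "A", "cartesian", "h1"), produce)
        cache.get_or_create(DdgCacheKey("S1", "A", "monomer", "h1"), produce)
        assert cache.produce_calls == 2

    def test_cleared_cache_reinvokes(self, tmp_path):
        cache = DdgCache(tmp_path / "repo")
        key = DdgCacheKey("S1", "A", "cartesian", "h1")
        produce = lambda d: (d / "r.txt").write_text("x\n")
        cache.get_or_create(key, produce)
        cache.clear()
        cache.get_or_create(key, produce)
        assert cache.produce_calls == 2

    def test_corrupt_entry_recomputed_with_warning(self, tmp_path):
        cache = DdgCache(tmp_path / "repo")
        key = DdgCacheKey("S1", "A", "cartesian", "h1")
        produce = lambda d: (d / "r.txt").write_text("x\n")
        entry = cache.get_or_create(key, produce)
        (entry / ".complete").unlink()  # simulate a torn write
        cache.get_or_create(key, produce)
        assert cache.produce_calls == 2 and cache.warnings

    def test_ddg_stub_rows_share_one_relax(self, tmp_path):
        items = [(mk_variant("G1", "P1", "T1", 5), mk_sel(1)),
                 (mk_variant("G1", "P1", "T1", 9), mk_sel(1))]
        rows = plan_case("c", items, ["ddg_cartesian"])
        ctx = ExecutorContext(case_root=tmp_path, seed=1, clock=LogicalClock(),
                              ddg_cache=DdgCache(tmp_path / "repo"))
        run_local(rows, default_registry(), ctx)
        assert ctx.ddg_cache.produce_calls == 1  # same structure & chain -> one relax
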