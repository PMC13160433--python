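import pytest

from vustruct.fixtures import FixtureSpec, make_bundle
from vustruct.pipeline import run_case
from vustruct.planner import LogicalClock

GUID = "00000000-0000-4000-8000-000000000001"


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One synthetic catalog bundle shared by the read-only tests."""
    d = tmp_path_factory.mktemp("bundle")
    return make_bundle(FixtureSpec(seed=11), d)


@pytest.fixture(scope="session")
def case_run(bundle, tmp_path_factory):
    """A completed end-to-end run over the shared bundle."""
    out = tmp_path_factory.mktemp("run")
    result = run_case(
        bundle["dir"], out, vcf=bundle["vcf"], seed=5, guid=GUID,
        clock=LogicalClock(),
    )
    assert not result.stopped
    return result


def write_vcf(path, rows, contigs=("1",)):
    """Minimal VCF writer for hand-built ingest tests."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=INH,Number=1,Type=String,Description="inheritance">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path
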