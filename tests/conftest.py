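import pytest

from cometh.aligner import OT, AlignedRead
from cometh.methylation_qc import ReadMethylation
from cometh.pattern_analysis import Window
from cometh.reference_io import ReferenceRegion


@pytest.fixture
def small_region() -> ReferenceRegion:
    # TACGTCATCGAGGCATGAT: CpGs at 2 and 8; non-CpG Cs at 5, 13;
    # non-CpG Gs at 11, 12, 16
    return ReferenceRegion.from_sequence("r1", "TACGTCATCGAGGCATGAT")


def make_aligned(seq, offset=0, strand=OT, read_id="rd", region_name="r1", mm=0):
    return AlignedRead(
        read_id=read_id, region_name=region_name, offset=offset,
        strand_mode=strand, read_seq=seq, mismatch_count=mm,
    )


def make_call(
    signature,
    sites,
    read_id="rd",
    region_name="r1",
    offset=0,
    strand=OT,
    conversion=1.0,
    identity=1.0,
    alleles=None,
):
    """Fabricate a ReadMethylation from a signature over the given sites."""
    status = dict(zip(sites, signature))
    return ReadMethylation(
        read_id=read_id, region_name=region_name, offset=offset,
        strand_mode=strand, covered_sites=tuple(sites), status=status,
        conversion_rate=conversion, identity=identity, alleles=alleles or {},
    )


def make_window(sites, region_name="r1", start=0, end=100):
    return Window(region_name=region_name, start=start, end=end, sites=tuple(sites))


def validate_bed12(line: str) -> None:
    """Assert one data line is structurally valid BED12."""
    f = line.split("\t")
    assert len(f) == 12, f"expected 12 BED fields, got {len(f)}: {line!r}"
    start, end = int(f[1]), int(f[2])
    assert 0 <= start < end
    assert 0 <= int(f[4]) <= 1000
    assert f[5] in "+-."
    thick_start, thick_end = int(f[6]), int(f[7])
    assert start <= thick_start <= thick_end <= end
    count = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    assert len(sizes) == len(starts) == count
    assert starts[0] == 0, "first block must start at chromStart"
    assert starts[-1] + sizes[-1] == end - start, "last block must end at chromEnd"
    for i in range(count):
        assert sizes[i] > 0
        assert starts[i] + sizes[i] <= end - start
        if i:
            assert starts[i] >= starts[i - 1] + sizes[i - 1], "blocks must not overlap"
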