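"""Aligner tests, including a brute-force enumeration oracle.

The oracle re-derives the mapping rules from scratch (its own conversion
tables and mismatch scan) so it is independent of the implementation's
vectorised path.
"""

import random

import pytest

from cometh.aligner import (
    OB,
    OT,
    AlignmentParams,
    BisulfiteAligner,
    align_read,
    convert_bisulfite,
    export_sam,
    import_sam,
    read_sequences,
    reverse_complement,
)
from cometh.reference_io import ReferenceRegion
from cometh.simulate import SimulationConfig, random_region, simulate_region


# --- independent oracle ----------------------------------------------------

def _oracle_convert(seq, mode):
    table = {"OT": ("C", "T"), "OB": ("G", "A")}[mode]
    return "".join(table[1] if b == table[0] else b for b in seq)


def _oracle_revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def oracle_align(seq, regions, max_mm=2, seed_len=28, seed_mm=3):
    hits = []
    for fwd, mode, revcomped in [(seq, OT, False), (_oracle_revcomp(seq), OB, True)]:
        m = len(fwd)
        sl = min(seed_len, m)
        seed_positions = set(range(m - sl, m)) if revcomped else set(range(sl))
        for ri, region in enumerate(regions):
            for off in range(len(region.sequence) - m + 1):
                ref = region.sequence[off : off + m]
                a = _oracle_convert(fwd, mode)
                b = _oracle_convert(ref, mode)
                mism = [
                    i for i in range(m)
                    if a[i] != b[i] or a[i] == "N" or b[i] == "N"
                ]
                if len(mism) > max_mm:
                    continue
                if sum(1 for i in mism if i in seed_positions) > seed_mm:
                    continue
                hits.append((len(mism), ri, off, mode))
    if not hits:
        return None
    best = min(h[0] for h in hits)
    winners = [h for h in hits if h[0] == best]
    return winners[0] if len(winners) == 1 else None


# --- unit tests ------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,mode,expected",
    [
        ("ACGT", OT, "ATGT"),
        ("ACGT", OB, "ACAT"),
        ("TTTT", OT, "TTTT"),
        ("CCGG", OB, "CCAA"),
        ("NACG", OT, "NATG"),
    ],
)
def test_convert_bisulfite(seq, mode, expected):
    assert convert_bisulfite(seq, mode) == expected


def test_exact_substring_maps_with_zero_mismatches():
    region = ReferenceRegion.from_sequence("r", "AATTACGGATTACATTGGT")
    read = convert_bisulfite(region.sequence[5:15], OT)
    hit = align_read("x", read, [region])
    assert hit is not None
    assert (hit.region_name, hit.offset, hit.strand_mode) == ("r", 5, OT)
    assert hit.mismatch_count == 0


def test_mismatch_budget_is_enforced():
    region = ReferenceRegion.from_sequence("r", "AATTAAGGATTAAATTGGT")
    read = list(region.sequence[2:16])
    for i in (0, 7, 12):  # ref T -> read A: conversion-inert mismatches
        assert read[i] == "T"
        read[i] = "A"
    read = "".join(read)
    assert align_read("x", read, [region], max_mismatches=2) is None
    assert align_read("x", read, [region], max_mismatches=3) is not None


def test_ambiguous_between_duplicate_regions_is_discarded():
    seq = "TATTAGGATTATATTGGTAT"
    r1 = ReferenceRegion.from_sequence("r1", seq)
    r2 = ReferenceRegion.from_sequence("r2", seq)
    read = seq[3:17]
    assert align_read("x", read, [r1]) is not None
    assert align_read("x", read, [r1, r2]) is None


def test_ob_read_is_reoriented_to_forward_coordinates():
    region = ReferenceRegion.from_sequence("r", "AATTACGGATTACATTGGT")
    fwd_piece = region.sequence[4:16]
    ob_read = reverse_complement(convert_bisulfite(fwd_piece, OB))
    hit = align_read("x", ob_read, [region])
    assert hit is not None
    assert hit.strand_mode == OB
    assert hit.offset == 4
    assert hit.read_seq == convert_bisulfite(fwd_piece, OB)


def test_alignment_matches_bruteforce_oracle_on_random_instances():
    rng = random.Random(20240901)
    regions = [
        ReferenceRegion.from_sequence(f"r{i}", "".join(rng.choice("ACGT") for _ in range(60)))
        for i in range(3)
    ]
    aligner = BisulfiteAligner(regions, AlignmentParams(2, 10, 3))
    for case in range(150):
        if case % 3 == 0:
            read = "".join(rng.choice("ACGT") for _ in range(20))
        else:
            ri = rng.randrange(3)
            off = rng.randrange(41)
            piece = regions[ri].sequence[off : off + 20]
            mode = rng.choice([OT, OB])
            conv = convert_bisulfite(piece, mode)
            read = conv if mode == OT else reverse_complement(conv)
            if case % 3 == 2:  # plant up to 2 substitutions
                chars = list(read)
                for pos in rng.sample(range(20), rng.randint(1, 2)):
                    chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
                read = "".join(chars)
        expected = oracle_align(read, regions, 2, 10, 3)
        got = aligner.align("q", read)
        if expected is None:
            assert got is None, f"case {case}: oracle no-hit, aligner hit {got}"
        else:
            mm, ri, off, mode = expected
            assert got is not None, f"case {case}: oracle hit {expected}, aligner no-hit"
            assert (got.mismatch_count, got.region_name, got.offset, got.strand_mode) == (
                mm, regions[ri].name, off, mode,
            )


def test_alignment_is_deterministic_and_order_independent():
    region = random_region(7, cpg_positions=(10, 30, 50))
    sim = simulate_region(
        SimulationConfig(region=region, pattern_mix=(("MMM", 0.5), ("UUU", 0.5)),
                         n_reads=60, seq_error=0.01, seed=3)
    )
    aligner = BisulfiteAligner([region])
    fwd, _ = aligner.align_all(sim.reads)
    rev, _ = aligner.align_all(list(reversed(sim.reads)))
    assert sorted(map(repr, fwd)) == sorted(map(repr, rev))


def test_noise_free_simulated_reads_all_map_to_truth():
    region = random_region(11, cpg_positions=(12, 28, 44))
    sim = simulate_region(
        SimulationConfig(region=region, pattern_mix=(("MUM", 1.0),),
                         n_reads=100, conversion_failure=0.0, seq_error=0.0, seed=5)
    )
    aligned, summary = BisulfiteAligner([region]).align_all(sim.reads)
    assert summary.mapped == summary.total == 100
    truth = sim.truth.set_index("read_id")
    for hit in aligned:
        row = truth.loc[hit.read_id]
        assert (hit.offset, hit.strand_mode) == (row["offset"], row["strand"])


def test_empty_read_file_yields_zero_summary(tmp_path):
    reads = tmp_path / "reads.fastq"
    reads.write_text("")
    region = ReferenceRegion.from_sequence("r", "ACGTACGT")
    aligned, summary = BisulfiteAligner([region]).align_all(
        read_sequences(reads)
    )
    assert (summary.total, summary.mapped, aligned) == (0, 0, [])


def test_unknown_quality_encoding_is_an_error(tmp_path):
    reads = tmp_path / "reads.fastq"
    reads.write_text("@a\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="quality encoding"):
        read_sequences(reads, "phred99")
    assert list(read_sequences(reads, "phred64")) == [("a", "ACGT")]


class TestSamRoundtrip:
    def test_export_import_preserves_alignments(self, tmp_path):
        region = random_region(2, cpg_positions=(10, 30))
        sim = simulate_region(
            SimulationConfig(region=region, pattern_mix=(("MM", 1.0),),
                             n_reads=40, conversion_failure=0.0, seq_error=0.0, seed=9)
        )
        aligned, _ = BisulfiteAligner([region]).align_all(sim.reads)
        sam = tmp_path / "out.sam"
        export_sam(sam, aligned, [region])
        back, skipped = import_sam(sam, [region])
        assert skipped == 0
        assert [(r.read_id, r.offset, r.strand_mode, r.read_seq) for r in back] == [
            (r.read_id, r.offset, r.strand_mode, r.read_seq) for r in aligned
        ]

    def test_pos_is_one_based_in_sam(self, tmp_path):
        region = ReferenceRegion.from_sequence("r", "AACGTTAAGGAATT")
        sam = tmp_path / "in.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:r\tLN:14\n"
            "q1\t0\tr\t1\t255\t6M\t*\t0\t0\tAATGTT\t*\n"
        )
        reads, skipped = import_sam(sam, [region])
        assert skipped == 0
        assert reads[0].offset == 0

    def test_gapped_cigar_is_skipped_and_counted(self, tmp_path):
        region = ReferenceRegion.from_sequence("r", "AACGTTAAGGAATT")
        sam = tmp_path / "in.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:r\tLN:14\n"
            "q1\t0\tr\t1\t255\t3M1I3M\t*\t0\t0\tAATGGTT\t*\n"
        )
        reads, skipped = import_sam(sam, [region])
        assert (reads, skipped) == ([], 1)

    def test_unknown_reference_is_an_error(self, tmp_path):
        region = ReferenceRegion.from_sequence("r", "AACGTTAAGGAATT")
        sam = tmp_path / "in.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:other\tLN:14\n"
            "q1\t0\tother\t1\t255\t4M\t*\t0\t0\tAATG\t*\n"
        )
        with pytest.raises(ValueError, match="other"):
            import_sam(sam, [region])
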