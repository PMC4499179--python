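"""Gap-free bisulfite-aware read mapping against small amplicon references.

Bisulfite conversion collapses the alphabet asymmetrically per strand: reads
from the original top strand (OT) show C->T conversions relative to the
forward reference, reads from the original bottom strand (OB), once expressed
in forward-region coordinates, show G->A conversions.  Mapping therefore
happens in "converted space": both read and reference are collapsed with the
strand-appropriate substitution and compared by Hamming distance at every
offset.  Regions are short (~100-500 bp), so a full scan over all offsets is
exact and fast; no index is needed and gaps are not modelled.

A candidate hit must respect two independent budgets, both counted in
converted space: at most ``seed_mismatches`` within the first
``seed_length`` bases of the read as sequenced, and at most
``max_mismatches`` overall.  The unique best hit (fewest total mismatches)
wins; ties across offsets, regions or strands make the read ambiguous and it
is discarded, which stands in for mapping-quality filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .reference_io import ReferenceRegion

OT = "OT"  # original top strand: C->T conversions vs forward reference
OB = "OB"  # original bottom strand: G->A conversions in forward coordinates

QUALITY_ENCODINGS = {
    "phred33": "fastq",
    "phred64": "fastq-illumina",
    "solexa": "fastq-solexa",
    "solexa1.3": "fastq-illumina",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_N = ord("N")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def convert_bisulfite(seq: str, mode: str) -> str:
    """Collapse ``seq`` into converted space: OT replaces C->T, OB G->A."""
    if mode == OT:
        return seq.replace("C", "T")
    if mode == OB:
        return seq.replace("G", "A")
    raise ValueError(f"unknown bisulfite mode {mode!r}")


@dataclass(frozen=True)
class AlignedRead:
    """A read placed on a region, expressed in forward-region orientation."""

    read_id: str
    region_name: str
    offset: int
    strand_mode: str  # OT or OB
    read_seq: str  # forward-region orientation, unconverted bases
    mismatch_count: int


@dataclass(frozen=True)
class AlignmentParams:
    max_mismatches: int = 2
    seed_length: int = 28
    seed_mismatches: int = 3
    search_complementary: bool = False  # also try CTOT/CTOB interpretations


@dataclass
class MappingSummary:
    total: int = 0
    mapped: int = 0
    per_region: dict[str, int] = field(default_factory=dict)

    @property
    def percent_mapped(self) -> float:
        return 100.0 * self.mapped / self.total if self.total else 0.0


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class BisulfiteAligner:
    """Scan aligner with per-region converted-space arrays precomputed."""

    def __init__(
        self,
        regions: Sequence[ReferenceRegion],
        params: AlignmentParams | None = None,
    ) -> None:
        self.regions = list(regions)
        self.params = params or AlignmentParams()
        self._index = []
        for region in self.regions:
            arr = _to_bytes(region.sequence)
            self._index.append(
                {
                    OT: _to_bytes(convert_bisulfite(region.sequence, OT)),
                    OB: _to_bytes(convert_bisulfite(region.sequence, OB)),
                    "n_mask": arr == _N,
                }
            )

    def _interpretations(self, seq: str) -> list[tuple[str, str, bool]]:
        # (forward-oriented sequence, strand mode, was reverse-complemented)
        interps = [(seq, OT, False), (reverse_complement(seq), OB, True)]
        if self.params.search_complementary:
            interps += [(reverse_complement(seq), OT, True), (seq, OB, False)]
        return interps

    def align(self, read_id: str, seq: str) -> Optional[AlignedRead]:
        """Best unique gap-free placement of ``seq``, or None.

        None means either no placement within the mismatch budgets, or two
        or more equal-best placements (ambiguous; discarded for
        reproducibility).
        """
        seq = seq.upper()
        if not seq:
            return None
        p = self.params
        m = len(seq)
        hits: list[tuple[int, int, int, str, str]] = []  # (mm, region_i, offset, mode, fwd_seq)
        best = p.max_mismatches + 1
        for fwd_seq, mode, revcomped in self._interpretations(seq):
            read_conv = _to_bytes(convert_bisulfite(fwd_seq, mode))
            read_n = read_conv == _N
            seed_len = min(p.seed_length, m)
            # seed = first bases of the read AS SEQUENCED; after reverse
            # complementing they sit at the end of the forward-oriented read
            seed_slice = slice(m - seed_len, m) if revcomped else slice(0, seed_len)
            for region_i, idx in enumerate(self._index):
                ref_conv = idx[mode]
                if m > ref_conv.size:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(ref_conv, m)
                n_windows = np.lib.stride_tricks.sliding_window_view(idx["n_mask"], m)
                mism = (windows != read_conv[None, :]) | n_windows | read_n[None, :]
                total = mism.sum(axis=1)
                seed_mm = mism[:, seed_slice].sum(axis=1)
                ok = np.nonzero((total <= p.max_mismatches) & (seed_mm <= p.seed_mismatches))[0]
                for off in ok:
                    mm = int(total[off])
                    if mm <= best:
                        best = mm
                        hits.append((mm, region_i, int(off), mode, fwd_seq))
        if not hits:
            return None
        winners = [h for h in hits if h[0] == best]
        if len(winners) != 1:
            return None  # ambiguous
        mm, region_i, offset, mode, fwd_seq = winners[0]
        return AlignedRead(
            read_id=read_id,
            region_name=self.regions[region_i].name,
            offset=offset,
            strand_mode=mode,
            read_seq=fwd_seq,
            mismatch_count=mm,
        )

    def align_all(
        self, reads: Iterable[tuple[str, str]]
    ) -> tuple[list[AlignedRead], MappingSummary]:
        summary = MappingSummary(per_region={r.name: 0 for r in self.regions})
        aligned: list[AlignedRead] = []
        for read_id, seq in reads:
            summary.total += 1
            hit = self.align(read_id, seq)
            if hit is not None:
                summary.mapped += 1
                summary.per_region[hit.region_name] += 1
                aligned.append(hit)
        return aligned, summary


def align_read(
    read_id: str,
    seq: str,
    regions: Sequence[ReferenceRegion],
    max_mismatches: int = 2,
    seed_length: int = 28,
    seed_mismatches: int = 3,
) -> Optional[AlignedRead]:
    """One-shot convenience wrapper around :class:`BisulfiteAligner`."""
    params = AlignmentParams(max_mismatches, seed_length, seed_mismatches)
    return BisulfiteAligner(regions, params).align(read_id, seq)


def read_sequences(path: str | Path, quality_encoding: str = "phred33") -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ.

    Format is sniffed from the first character ('>' FASTA, '@' FASTQ).  For
    FASTQ the declared quality encoding label selects the offset used to
    validate qualities; bases are returned either way since scoring does not
    use qualities.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "":
        return iter(())
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        if quality_encoding not in QUALITY_ENCODINGS:
            raise ValueError(
                f"unknown quality encoding {quality_encoding!r}; "
                f"expected one of {sorted(QUALITY_ENCODINGS)}"
            )
        fmt = QUALITY_ENCODINGS[quality_encoding]
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")

    def _iter() -> Iterator[tuple[str, str]]:
        for rec in SeqIO.parse(str(path), fmt):
            yield rec.id, str(rec.seq).upper()

    return _iter()


def align_file(
    path: str | Path,
    regions: Sequence[ReferenceRegion],
    params: AlignmentParams | None = None,
    quality_encoding: str = "phred33",
) -> tuple[list[AlignedRead], MappingSummary]:
    aligner = BisulfiteAligner(regions, params)
    return aligner.align_all(read_sequences(path, quality_encoding))


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------

def import_sam(path: str | Path, regions: Sequence[ReferenceRegion]) -> tuple[list[AlignedRead], int]:
    """Import gap-free alignments from SAM as AlignedRead records.

    Reference names must match region names.  Unmapped records and records
    whose CIGAR contains anything but a single match run (M/=/X) are skipped;
    the skip count is returned alongside the reads.  Strand mode comes from
    the Bismark-style XG tag when present (CT -> OT, GA -> OB), otherwise
    from whichever interpretation yields fewer converted-space mismatches.
    """
    import pysam

    by_name = {r.name: r for r in regions}
    reads: list[AlignedRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped += 1
                continue
            if rec.reference_name not in by_name:
                raise ValueError(
                    f"SAM reference {rec.reference_name!r} not among region names"
                )
            cigar = rec.cigartuples or []
            if len(cigar) != 1 or cigar[0][0] not in (0, 7, 8):  # M, =, X
                skipped += 1
                continue
            region = by_name[rec.reference_name]
            seq = (rec.query_sequence or "").upper()
            offset = rec.reference_start
            if not seq or offset + len(seq) > len(region):
                skipped += 1
                continue
            mode = None
            if rec.has_tag("XG"):
                tag = rec.get_tag("XG")
                mode = OT if tag == "CT" else OB if tag == "GA" else None
            if mode is None:
                mode = _infer_strand_mode(seq, region.sequence[offset : offset + len(seq)])
            mm = _converted_mismatches(seq, region.sequence[offset : offset + len(seq)], mode)
            reads.append(
                AlignedRead(
                    read_id=rec.query_name or "",
                    region_name=region.name,
                    offset=offset,
                    strand_mode=mode,
                    read_seq=seq,
                    mismatch_count=mm,
                )
            )
    return reads, skipped


def _converted_mismatches(read_fwd: str, ref: str, mode: str) -> int:
    a = convert_bisulfite(read_fwd, mode)
    b = convert_bisulfite(ref, mode)
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def _infer_strand_mode(read_fwd: str, ref: str) -> str:
    mm_ot = _converted_mismatches(read_fwd, ref, OT)
    mm_ob = _converted_mismatches(read_fwd, ref, OB)
    return OT if mm_ot <= mm_ob else OB


def export_sam(
    path: str | Path,
    reads: Sequence[AlignedRead],
    regions: Sequence[ReferenceRegion],
) -> None:
    """Write accepted alignments as minimal SAM (header + one line per read)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for region in regions:
            fh.write(f"@SQ\tSN:{region.name}\tLN:{len(region)}\n")
        for r in reads:
            flag = 0 if r.strand_mode == OT else 16
            xg = "CT" if r.strand_mode == OT else "GA"
            fh.write(
                f"{r.read_id}\t{flag}\t{r.region_name}\t{r.offset + 1}\t255\t"
                f"{len(r.read_seq)}M\t*\t0\t0\t{r.read_seq}\t*\tXG:Z:{xg}\n"
            )
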