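"""Per-read methylation calling and read-level quality control.

Each aligned read yields a methylation status call at every CpG site it
fully covers, plus two QC metrics used for filtering:

* bisulfite conversion rate — the fraction of the read's non-CpG cytosines
  (on its own bisulfite strand) observed as converted.  Unmethylated non-CpG
  cytosines should all read as T (OT) / A (OB, forward coordinates), so a
  low rate flags incomplete chemical conversion.
* sequence identity — the fraction of read positions matching the reference
  under bisulfite-compatible matching (ref C vs read T is a match on OT,
  ref G vs read A on OB).

Default thresholds (conversion >= 0.95, identity >= 0.9) are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .aligner import OB, OT, AlignedRead
from .reference_io import ReferenceRegion

METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "?"

DEFAULT_MIN_CONVERSION = 0.95
DEFAULT_MIN_IDENTITY = 0.9


@dataclass(frozen=True)
class ReadMethylation:
    """A read's methylation status over the CpG sites it covers, plus QC.

    ``covered_sites`` are the region CpG sites whose C and G bases both fall
    inside the read (required so calls are possible from either strand);
    ``status`` maps each covered site to M/U/?.  ``alleles`` maps every
    covered, non-conversion-confounded reference position to the read base,
    for downstream mutation pileups.
    """

    read_id: str
    region_name: str
    offset: int
    strand_mode: str
    covered_sites: tuple[int, ...]
    status: dict[int, str]
    conversion_rate: float
    identity: float
    alleles: dict[int, str]

    def signature(self, sites: Sequence[int]) -> str:
        """Status string over ``sites`` (e.g. 'MUM'); KeyError if uncovered."""
        return "".join(self.status[s] for s in sites)


def covered_cpg_sites(read: AlignedRead, region: ReferenceRegion) -> tuple[int, ...]:
    lo, hi = read.offset, read.offset + len(read.read_seq)
    return tuple(s for s in region.cpg_sites if lo <= s and s + 1 < hi)


def call_read_methylation(read: AlignedRead, region: ReferenceRegion) -> ReadMethylation:
    """Call methylation status at each covered CpG site and compute QC.

    OT reads are informative at the C of a CpG (C = methylated,
    T = unmethylated); OB reads at the G in forward orientation
    (G = methylated, A = unmethylated, i.e. the complement-strand C was or
    was not converted).  Any other base is an AMBIGUOUS call — likelier a
    variant or sequencing error than a methylation state.
    """
    if read.offset < 0 or read.offset + len(read.read_seq) > len(region):
        raise ValueError(f"read {read.read_id!r} extends beyond region {region.name!r}")
    sites = covered_cpg_sites(read, region)
    status: dict[int, str] = {}
    for s in sites:
        if read.strand_mode == OT:
            base = read.read_seq[s - read.offset]
            status[s] = {"C": METHYLATED, "T": UNMETHYLATED}.get(base, AMBIGUOUS)
        else:
            base = read.read_seq[s + 1 - read.offset]
            status[s] = {"G": METHYLATED, "A": UNMETHYLATED}.get(base, AMBIGUOUS)
    return ReadMethylation(
        read_id=read.read_id,
        region_name=read.region_name,
        offset=read.offset,
        strand_mode=read.strand_mode,
        covered_sites=sites,
        status=status,
        conversion_rate=bisulfite_conversion_rate(read, region),
        identity=sequence_identity(read, region),
        alleles=_allele_bases(read, region),
    )


def _non_cpg_cytosine_positions(region: ReferenceRegion, mode: str) -> Iterable[int]:
    """Positions whose conversion state is informative for ``mode``.

    OT: reference C not followed by G (the read's own strand cytosines
    outside CpG context).  OB: reference G not preceded by C — these are the
    bottom strand's non-CpG cytosines seen as G in forward coordinates.
    """
    seq = region.sequence
    if mode == OT:
        for i, b in enumerate(seq):
            if b == "C" and not (i + 1 < len(seq) and seq[i + 1] == "G"):
                yield i
    else:
        for i, b in enumerate(seq):
            if b == "G" and not (i > 0 and seq[i - 1] == "C"):
                yield i


def bisulfite_conversion_rate(read: AlignedRead, region: ReferenceRegion) -> float:
    """Fraction of covered non-CpG cytosines observed as converted.

    A read covering no such position passes trivially (rate 1.0): there is
    no evidence of conversion failure, and discarding would bias against
    cytosine-poor windows.
    """
    lo, hi = read.offset, read.offset + len(read.read_seq)
    converted_base = "T" if read.strand_mode == OT else "A"
    total = 0
    converted = 0
    for pos in _non_cpg_cytosine_positions(region, read.strand_mode):
        if lo <= pos < hi:
            total += 1
            if read.read_seq[pos - lo] == converted_base:
                converted += 1
    return converted / total if total else 1.0


def sequence_identity(read: AlignedRead, region: ReferenceRegion) -> float:
    """Bisulfite-compatible match fraction over the full read length.

    A position matches if the read base equals the reference base, or is the
    expected conversion of it for the read's strand (OT: ref C / read T;
    OB: ref G / read A).  N never matches.
    """
    lo = read.offset
    matches = 0
    for i, rb in enumerate(read.read_seq):
        ref = region.sequence[lo + i]
        if rb == "N" or ref == "N":
            continue
        if rb == ref:
            matches += 1
        elif read.strand_mode == OT and ref == "C" and rb == "T":
            matches += 1
        elif read.strand_mode == OB and ref == "G" and rb == "A":
            matches += 1
    return matches / len(read.read_seq) if read.read_seq else 0.0


def _allele_bases(read: AlignedRead, region: ReferenceRegion) -> dict[int, str]:
    """Read base per covered position, excluding conversion-confounded ones.

    For OT reads every reference-C position is skipped (a read T there may be
    conversion, not genotype); for OB reads every reference-G position is
    skipped.  A CpG's C is therefore only genotyped from OB reads and its G
    only from OT reads.
    """
    skip = "C" if read.strand_mode == OT else "G"
    lo = read.offset
    out: dict[int, str] = {}
    for i, rb in enumerate(read.read_seq):
        if region.sequence[lo + i] != skip:
            out[lo + i] = rb
    return out


@dataclass(frozen=True)
class DiscardedRead:
    call: ReadMethylation
    reason: str  # "conversion" or "identity"


def filter_reads(
    calls: Iterable[ReadMethylation],
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[list[ReadMethylation], list[DiscardedRead]]:
    """Partition reads into kept / discarded by the two inclusive thresholds."""
    for label, value in (("min_conversion", min_conversion), ("min_identity", min_identity)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{label} must be in [0, 1], got {value}")
    kept: list[ReadMethylation] = []
    discarded: list[DiscardedRead] = []
    for call in calls:
        if call.conversion_rate < min_conversion:
            discarded.append(DiscardedRead(call, "conversion"))
        elif call.identity < min_identity:
            discarded.append(DiscardedRead(call, "identity"))
        else:
            kept.append(call)
    return kept, discarded


def qc_table(
    kept: Sequence[ReadMethylation], discarded: Sequence[DiscardedRead]
) -> pd.DataFrame:
    """Per-read QC metrics as a DataFrame (for the optional TSV dump)."""
    rows = []
    for call in kept:
        rows.append(_qc_row(call, "kept", ""))
    for d in discarded:
        rows.append(_qc_row(d.call, "discarded", d.reason))
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "region", "offset", "strand",
            "conversion_rate", "identity", "status", "reason",
        ],
    )


def _qc_row(call: ReadMethylation, status: str, reason: str) -> dict:
    return {
        "read_id": call.read_id,
        "region": call.region_name,
        "offset": call.offset,
        "strand": call.strand_mode,
        "conversion_rate": call.conversion_rate,
        "identity": call.identity,
        "status": status,
        "reason": reason,
    }
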