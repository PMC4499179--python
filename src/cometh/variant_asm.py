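"""Mutation calling from mismatch pileups and allele-specific methylation.

A mutation here is deliberately simple: a mismatch carried by an excessive
fraction of covering reads (default >= 0.2), with a coverage floor to keep
sequencing noise out.  Pileups exclude conversion-confounded comparisons —
an OT read's T at a reference C may be bisulfite conversion rather than
genotype, so reference-C positions are only genotyped from OB reads and
reference-G positions only from OT reads.

Given a mutation, reads split into a reference-allele group and a
variant-allele group.  Each group's per-site methylation level is binned
into LOW (<= 20% of reads methylated), HIGH (>= 80%) or INTERMEDIATE, and
the region is a candidate allele-specific methylation (ASM) region when at
least one CpG site falls in different categories between the groups AND the
absolute level difference there exceeds 20 percentage points.  Each group
also gets its own co-occurrence PatternSet.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .methylation_qc import ReadMethylation
from .pattern_analysis import (
    PatternSet,
    Window,
    group_patterns,
    reads_covering_window,
    site_methylation_levels,
)
from .reference_io import ReferenceRegion

LOW = "LOW"
HIGH = "HIGH"
INTERMEDIATE = "INTERMEDIATE"

DEFAULT_MUTATION_THRESHOLD = 0.2
DEFAULT_MIN_COVERAGE = 10
DEFAULT_MIN_GROUP_SIZE = 10
ASM_LEVEL_DIFFERENCE = 0.20

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Mutation:
    region_name: str
    position: int  # 0-based region offset
    ref_allele: str
    var_allele: str
    var_fraction: float
    covering: int  # reads contributing counts at the position
    dbsnp_id: Optional[str] = None


@dataclass(frozen=True)
class AlleleGroup:
    allele: str  # "REF" or "VAR"
    reads: tuple[ReadMethylation, ...]
    site_levels: dict[int, float]
    site_categories: dict[int, str]


@dataclass(frozen=True)
class ASMResult:
    mutation: Mutation
    ref_group: AlleleGroup
    var_group: AlleleGroup
    is_candidate: bool
    discriminating_sites: tuple[int, ...]
    ref_patterns: PatternSet
    var_patterns: PatternSet


def count_alleles(
    reads: Iterable[ReadMethylation], region: ReferenceRegion
) -> dict[int, Counter]:
    """Per-position base counts from QC-passed reads.

    Conversion-confounded positions are already excluded per read (see
    ``ReadMethylation.alleles``); N bases are ignored.
    """
    counts: dict[int, Counter] = {pos: Counter() for pos in range(len(region))}
    for read in reads:
        for pos, base in read.alleles.items():
            if base in _BASES:
                counts[pos][base] += 1
    return counts


def call_mutations(
    counts: dict[int, Counter],
    region: ReferenceRegion,
    threshold: float = DEFAULT_MUTATION_THRESHOLD,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[Mutation]:
    """Mutations at positions where the top non-reference base reaches
    ``threshold`` among counted reads, subject to the coverage floor."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"mutation threshold must be in (0, 1], got {threshold}")
    out: list[Mutation] = []
    for pos in sorted(counts):
        tally = counts[pos]
        total = sum(tally.values())
        if total < min_coverage:
            continue
        ref = region.sequence[pos]
        variants = [(c, b) for b, c in tally.items() if b != ref]
        if not variants:
            continue
        var_count, var_base = max(variants)  # most frequent non-reference base
        fraction = var_count / total
        if fraction >= threshold:
            out.append(Mutation(region.name, pos, ref, var_base, fraction, total))
    return out


def split_by_allele(
    reads: Sequence[ReadMethylation], mutation: Mutation
) -> tuple[list[ReadMethylation], list[ReadMethylation], list[ReadMethylation]]:
    """Partition reads into (ref, var, unassigned) at the mutation position.

    Unassigned = reads not covering the position, reads whose strand
    confounds it (position absent from their allele map), or reads carrying
    a third base.
    """
    ref_group: list[ReadMethylation] = []
    var_group: list[ReadMethylation] = []
    unassigned: list[ReadMethylation] = []
    for read in reads:
        base = read.alleles.get(mutation.position)
        if base == mutation.ref_allele:
            ref_group.append(read)
        elif base == mutation.var_allele:
            var_group.append(read)
        else:
            unassigned.append(read)
    return ref_group, var_group, unassigned


def categorize_level(level: float) -> str:
    """Bin a methylation level: <=0.20 LOW, >=0.80 HIGH, else INTERMEDIATE."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"methylation level must be in [0, 1], got {level}")
    if level <= 0.20:
        return LOW
    if level >= 0.80:
        return HIGH
    return INTERMEDIATE


def _make_group(allele: str, reads: Sequence[ReadMethylation], window: Window) -> AlleleGroup:
    levels = site_methylation_levels(reads, window.sites)
    categories = {s: categorize_level(v) for s, v in levels.items()}
    return AlleleGroup(allele, tuple(reads), levels, categories)


def detect_asm(
    ref_reads: Sequence[ReadMethylation],
    var_reads: Sequence[ReadMethylation],
    window: Window,
    mutation: Mutation,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> Optional[ASMResult]:
    """Evaluate the two allele groups for candidate ASM over ``window``.

    A window site discriminates when the groups' categories differ AND the
    absolute level difference is strictly greater than 0.20.  Returns None
    (insufficient data) when either group is below the size floor.
    """
    if len(ref_reads) < min_group_size or len(var_reads) < min_group_size:
        return None
    ref_group = _make_group("REF", ref_reads, window)
    var_group = _make_group("VAR", var_reads, window)
    discriminating = tuple(
        s
        for s in window.sites
        if ref_group.site_categories[s] != var_group.site_categories[s]
        and abs(ref_group.site_levels[s] - var_group.site_levels[s]) > ASM_LEVEL_DIFFERENCE
    )
    return ASMResult(
        mutation=mutation,
        ref_group=ref_group,
        var_group=var_group,
        is_candidate=bool(discriminating),
        discriminating_sites=discriminating,
        ref_patterns=group_patterns(ref_group.reads, window),
        var_patterns=group_patterns(var_group.reads, window),
    )


def analyze_asm(
    kept_reads: Sequence[ReadMethylation],
    region: ReferenceRegion,
    window: Window,
    threshold: float = DEFAULT_MUTATION_THRESHOLD,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    dbsnp: Optional[dict[tuple[str, int], str]] = None,
) -> tuple[list[Mutation], list[ASMResult]]:
    """Full per-region ASM pass.

    Mutations are called from pileups over all QC-passed reads of the
    region; each mutation inside the window is then evaluated independently
    on the window-covering reads.  ``dbsnp`` maps (region name, 0-based
    position) -> variant ID for optional annotation.
    """
    counts = count_alleles(kept_reads, region)
    mutations = call_mutations(counts, region, threshold, min_coverage)
    if dbsnp:
        mutations = [
            m if (m.region_name, m.position) not in dbsnp
            else Mutation(
                m.region_name, m.position, m.ref_allele, m.var_allele,
                m.var_fraction, m.covering, dbsnp[(m.region_name, m.position)],
            )
            for m in mutations
        ]
    covering = reads_covering_window(kept_reads, window)
    results: list[ASMResult] = []
    for mutation in mutations:
        if not window.start <= mutation.position < window.end:
            continue
        ref_reads, var_reads, _ = split_by_allele(covering, mutation)
        res = detect_asm(ref_reads, var_reads, window, mutation, min_group_size)
        if res is not None:
            results.append(res)
    return mutations, results


def load_dbsnp_vcf(path: str, regions: Sequence[ReferenceRegion]) -> dict[tuple[str, int], str]:
    """Map (region, 0-based offset) -> dbSNP ID from a local VCF.

    The VCF CHROM/POS are matched against each region's genome coordinates;
    regions without coordinates cannot be annotated.  Plain-text VCF only.
    """
    lookup: dict[tuple[str, int], str] = {}
    with_coords = [r for r in regions if r.genome is not None]
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[1].isdigit():
                continue
            chrom, pos1, vid = fields[0], int(fields[1]), fields[2]
            for region in with_coords:
                g = region.genome
                offset = pos1 - 1 - g.start
                if g.chrom == chrom and 0 <= offset < len(region):
                    lookup[(region.name, offset)] = vid
    return lookup
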