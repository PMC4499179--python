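"""Reference amplicon handling: FASTA loading, CpG indexing, genome coordinates.

Targeted bisulfite amplicon experiments work against a handful of short
reference regions (typically ~100-500 bp), supplied by the user as one FASTA
record per region.  Genome coordinates are optional metadata used only for
browser-track output; they are attached from a BED6 or simple tab-delimited
file rather than looked up remotely.

All coordinates are 0-based half-open internally; human-readable report
writers convert to 1-based inclusive at the last moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

SUPPORTED_ASSEMBLIES = ("hg38", "hg19", "hg18")

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeCoords:
    """Placement of a region on a genome assembly.

    ``start`` is the 0-based genome position of region offset 0; ``strand``
    is '+' or '-'; ``assembly`` is one of hg38/hg19/hg18.
    """

    chrom: str
    start: int
    strand: str = "+"
    assembly: str = "hg38"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.assembly not in SUPPORTED_ASSEMBLIES:
            raise ValueError(
                f"unsupported assembly {self.assembly!r}; "
                f"expected one of {SUPPORTED_ASSEMBLIES}"
            )
        if self.start < 0:
            raise ValueError("genome start must be non-negative")


@dataclass(frozen=True)
class ReferenceRegion:
    """One targeted amplicon: name, uppercase sequence, indexed CpG sites.

    ``cpg_sites`` holds the 0-based offset of the C of every CpG dinucleotide
    on the forward strand, in increasing order and exhaustively.
    """

    name: str
    sequence: str
    cpg_sites: tuple[int, ...]
    genome: Optional[GenomeCoords] = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"region {self.name!r}: invalid bases {sorted(bad)} "
                "(expected A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(
        cls, name: str, sequence: str, genome: Optional[GenomeCoords] = None
    ) -> "ReferenceRegion":
        seq = sequence.upper()
        return cls(name=name, sequence=seq, cpg_sites=tuple(find_cpg_sites(seq)), genome=genome)


def find_cpg_sites(sequence: str) -> list[int]:
    """Return 0-based offsets of every 'CG' dinucleotide in ``sequence``.

    N never forms a CpG; CG occurrences cannot overlap, so a linear scan
    yields exactly the exhaustive, strictly increasing site list.
    """
    sites: list[int] = []
    start = 0
    while True:
        i = sequence.find("CG", start)
        if i == -1:
            return sites
        sites.append(i)
        start = i + 2


def load_references(path: str | Path) -> list[ReferenceRegion]:
    """Load reference amplicons from a FASTA file, one region per record.

    Sequences are uppercased (soft-masking is irrelevant here) and CpG sites
    indexed.  Record order is preserved.  Raises on empty records and on
    duplicate region names.
    """
    path = Path(path)
    regions: list[ReferenceRegion] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises ValueError subclasses
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    for rec in records:
        if not rec.id:
            raise ValueError(f"malformed FASTA {path}: record with empty name")
        if len(rec.seq) == 0:
            raise ValueError(f"malformed FASTA {path}: record {rec.id!r} is empty")
        if rec.id in seen:
            raise ValueError(f"duplicate region name {rec.id!r} in {path}")
        seen.add(rec.id)
        regions.append(ReferenceRegion.from_sequence(rec.id, str(rec.seq)))
    return regions


def write_references(path: str | Path, regions: Sequence[ReferenceRegion]) -> None:
    """Write regions back out as FASTA (one unwrapped sequence line each)."""
    with open(path, "w") as fh:
        for region in regions:
            fh.write(f">{region.name}\n{region.sequence}\n")


def load_region_coords(
    path: str | Path, regions: Sequence[ReferenceRegion]
) -> list[ReferenceRegion]:
    """Attach genome coordinates to regions from a BED6 or 4-column file.

    Two layouts are accepted, sniffed per line:

    * BED6: ``chrom  start  end  name  score  strand`` (0-based half-open)
    * simple: ``name  chrom  start  strand``

    An optional trailing column in either layout names the assembly
    (default hg38).  Lines naming unknown regions are skipped with a
    warning; malformed lines raise with their line number.  For duplicate
    entries the first wins.  Regions absent from the file keep
    ``genome=None`` (track output is then unavailable for them).
    """
    by_name = {r.name: i for i, r in enumerate(regions)}
    out = list(regions)
    assigned: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                name, coords = _parse_coord_line(fields)
            except Exception as exc:
                raise ValueError(
                    f"{path}: malformed coordinates line {lineno}: {exc}"
                ) from exc
            if name not in by_name:
                warnings.warn(
                    f"{path}: line {lineno} names unknown region {name!r}; skipped"
                )
                continue
            if name in assigned:  # first-wins
                continue
            assigned.add(name)
            idx = by_name[name]
            out[idx] = replace(out[idx], genome=coords)
    return out


def _parse_coord_line(fields: list[str]) -> tuple[str, GenomeCoords]:
    if len(fields) >= 6 and fields[1].isdigit() and fields[2].isdigit():
        # BED6 (+ optional assembly col 7)
        chrom, start, _end, name, _score, strand = fields[:6]
        assembly = fields[6] if len(fields) > 6 else "hg38"
        return name, GenomeCoords(chrom, int(start), strand, assembly)
    if len(fields) >= 4:
        name, chrom, start, strand = fields[:4]
        if not start.lstrip("-").isdigit():
            raise ValueError(f"start {start!r} is not an integer")
        assembly = fields[4] if len(fields) > 4 else "hg38"
        return name, GenomeCoords(chrom, int(start), strand, assembly)
    raise ValueError(f"expected BED6 or 'name chrom start strand', got {len(fields)} fields")
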