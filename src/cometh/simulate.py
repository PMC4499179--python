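"""Synthetic bisulfite amplicon reads with known ground truth.

The generator emulates targeted deep amplicon bisulfite sequencing: short
reads (default 75 bp) drawn from a small region (default 127 bp, matching
typical amplicon designs), carrying a mixture of planted methylation
signatures over the window CpG sites, with a bisulfite conversion-failure
rate, a per-base sequencing-error rate, both bisulfite strands, and an
optional variant allele whose frequency may be linked to methylation state.

Reads from the original bottom strand are emitted reverse-complemented in
the FASTQ, as a sequencer would produce them, so the aligner's orientation
logic is exercised.  Every read's planted signature, allele, offset and
strand are recorded in a truth table.  Output is deterministic given the
seed, which is also recorded in each FASTQ header comment for provenance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aligner import OB, OT, reverse_complement
from .pattern_analysis import Window, select_window
from .reference_io import ReferenceRegion, write_references

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantSpec:
    """Optional variant allele linked (or not) to a methylation mix.

    ``position`` is a 0-based region offset; the variant base replaces the
    reference base on variant-allele templates.  When
    ``var_pattern_mix`` is given, variant-allele reads draw their signature
    from it instead of the global mix — that linkage is what makes a region
    allele-specifically methylated.
    """

    position: int
    var_base: str
    frequency: float
    var_pattern_mix: Optional[tuple[tuple[str, float], ...]] = None


@dataclass(frozen=True)
class SimulationConfig:
    region: ReferenceRegion
    pattern_mix: tuple[tuple[str, float], ...]
    n_reads: int = 1000
    read_length: int = 75
    conversion_failure: float = 0.01
    seq_error: float = 0.005
    strand_mix: float = 0.5  # proportion of OT reads
    variant: Optional[VariantSpec] = None
    window: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        _check_mix(self.pattern_mix)
        if self.variant and self.variant.var_pattern_mix:
            _check_mix(self.variant.var_pattern_mix)
        for label, p in (
            ("conversion_failure", self.conversion_failure),
            ("seq_error", self.seq_error),
            ("strand_mix", self.strand_mix),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be a probability, got {p}")
        if self.read_length > len(self.region):
            raise ValueError("read_length exceeds region length")


def _check_mix(mix: Sequence[tuple[str, float]]) -> None:
    total = sum(p for _, p in mix)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"pattern mix proportions must sum to 1, got {total}")
    if any(p < 0 for _, p in mix):
        raise ValueError("pattern mix proportions must be non-negative")
    lengths = {len(sig) for sig, _ in mix}
    if len(lengths) > 1:
        raise ValueError("all signatures in a mix must have equal length")


def independent_site_mix(k: int, p_methylated: float) -> tuple[tuple[str, float], ...]:
    """Signature mix equivalent to independent per-site Bernoulli methylation."""
    mix = []
    for combo in itertools.product("MU", repeat=k):
        prob = 1.0
        for c in combo:
            prob *= p_methylated if c == "M" else 1.0 - p_methylated
        mix.append(("".join(combo), prob))
    return tuple(mix)


def uniform_mix(k: int) -> tuple[tuple[str, float], ...]:
    """All 2^k signatures, equiprobable."""
    sigs = ["".join(c) for c in itertools.product("MU", repeat=k)]
    return tuple((s, 1.0 / len(sigs)) for s in sigs)


def random_region(
    seed: int, name: str = "sim_region", length: int = 127, cpg_positions: Optional[Sequence[int]] = None
) -> ReferenceRegion:
    """Random amplicon with CpG sites exactly at ``cpg_positions``.

    Accidental CG dinucleotides in the random background are scrubbed before
    planting, so the region's CpG index is fully controlled.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(_BASES, size=length))
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    if cpg_positions is None:
        cpg_positions = list(range(10, length - 10, max(12, length // 8)))[:6]
    for p in cpg_positions:
        if p + 1 >= length:
            raise ValueError(f"CpG position {p} does not fit in length {length}")
        seq[p], seq[p + 1] = "C", "G"
        if p >= 1 and seq[p - 1] == "C":
            seq[p - 1] = "A"  # would otherwise create an unplanned CpG at p-1
        if p + 2 < length and seq[p + 2] == "G":
            pass  # G after our G cannot form CG
    sequence = "".join(seq)
    region = ReferenceRegion.from_sequence(name, sequence)
    if list(region.cpg_sites) != sorted(cpg_positions):
        raise AssertionError("CpG planting failed to produce the requested site set")
    return region


@dataclass
class SimulatedReads:
    config: SimulationConfig
    window: Window
    reads: list[tuple[str, str]]  # (read_id, sequence as sequenced)
    truth: pd.DataFrame = field(repr=False)


def simulate_region(config: SimulationConfig) -> SimulatedReads:
    """Generate reads for one region per the config; see module docstring.

    Offsets are drawn uniformly among placements covering every window CpG
    site (so every read is usable for pattern analysis); raises if no such
    placement exists.
    """
    region = config.region
    window = select_window(region, config.window)
    k = len(window.sites)
    for sig, _ in config.pattern_mix:
        if len(sig) != k:
            raise ValueError(
                f"signature length {len(sig)} != {k} window sites"
            )
    lo_site, hi_site = window.sites[0], window.sites[-1]
    min_off = max(0, hi_site + 2 - config.read_length)
    max_off = min(lo_site, len(region) - config.read_length)
    if min_off > max_off:
        raise ValueError(
            "read_length cannot cover all window CpG sites from any offset"
        )
    offsets = np.arange(min_off, max_off + 1)

    rng = np.random.default_rng(config.seed)
    ref_sigs = [s for s, _ in config.pattern_mix]
    ref_probs = np.array([p for _, p in config.pattern_mix])
    ref_probs = ref_probs / ref_probs.sum()
    var = config.variant
    if var is not None and var.var_pattern_mix is not None:
        var_sigs = [s for s, _ in var.var_pattern_mix]
        var_probs = np.array([p for _, p in var.var_pattern_mix])
        var_probs = var_probs / var_probs.sum()
    else:
        var_sigs, var_probs = ref_sigs, ref_probs

    templates = {"REF": region.sequence}
    if var is not None:
        t = list(region.sequence)
        t[var.position] = var.var_base
        templates["VAR"] = "".join(t)

    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(config.n_reads):
        allele = "VAR" if var is not None and rng.random() < var.frequency else "REF"
        if allele == "VAR":
            sig = var_sigs[rng.choice(len(var_sigs), p=var_probs)]
        else:
            sig = ref_sigs[rng.choice(len(ref_sigs), p=ref_probs)]
        strand = OT if rng.random() < config.strand_mix else OB
        offset = int(rng.choice(offsets))
        template = templates[allele]
        # methylation only protects intact CpG dinucleotides on this template
        methylated_c = {
            s
            for s, c in zip(window.sites, sig)
            if c == "M" and template[s : s + 2] == "CG"
        }
        chars = list(template[offset : offset + config.read_length])
        for j, base in enumerate(chars):
            pos = offset + j
            if strand == OT and base == "C":
                if pos not in methylated_c and rng.random() >= config.conversion_failure:
                    chars[j] = "T"
            elif strand == OB and base == "G":
                protected = (pos - 1) in methylated_c
                if not protected and rng.random() >= config.conversion_failure:
                    chars[j] = "A"
        if config.seq_error > 0:
            for j in range(len(chars)):
                if rng.random() < config.seq_error:
                    choices = [b for b in "ACGT" if b != chars[j]]
                    chars[j] = choices[rng.integers(3)]
        fwd = "".join(chars)
        emitted = fwd if strand == OT else reverse_complement(fwd)
        read_id = f"read{i:06d}"
        reads.append((read_id, emitted))
        rows.append(
            {
                "read_id": read_id,
                "region": region.name,
                "signature": sig,
                "allele": allele,
                "offset": offset,
                "strand": strand,
            }
        )
    truth = pd.DataFrame(rows, columns=["read_id", "region", "signature", "allele", "offset", "strand"])
    return SimulatedReads(config=config, window=window, reads=reads, truth=truth)


def write_fastq(path: str | Path, sim: SimulatedReads) -> None:
    """Phred33 FASTQ with constant quality 'I'; seed noted in the comment."""
    with open(path, "w") as fh:
        for read_id, seq in sim.reads:
            fh.write(f"@{read_id} seed={sim.config.seed}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(path: str | Path, sim: SimulatedReads) -> None:
    sim.truth.to_csv(path, sep="\t", index=False)


def _write_config(path: Path, config: SimulationConfig) -> None:
    lines = [
        f"region={config.region.name}",
        f"n_reads={config.n_reads}",
        f"read_length={config.read_length}",
        f"conversion_failure={config.conversion_failure}",
        f"seq_error={config.seq_error}",
        f"strand_mix={config.strand_mix}",
        f"seed={config.seed}",
        "pattern_mix=" + ";".join(f"{s}:{p:.6g}" for s, p in config.pattern_mix),
    ]
    if config.variant is not None:
        v = config.variant
        lines.append(f"variant={v.position}:{v.var_base}:{v.frequency}")
        if v.var_pattern_mix:
            lines.append(
                "var_pattern_mix=" + ";".join(f"{s}:{p:.6g}" for s, p in v.var_pattern_mix)
            )
    path.write_text("\n".join(lines) + "\n")


def fixture_configs(seed: int = 0) -> dict[str, SimulationConfig]:
    """The four canonical simulation scenarios.

    * null_uniform — signatures uniform over all 2^3 patterns: no pattern
      should be called significant much above the nominal rate.
    * planted_mixture — three signatures at 0.6/0.3/0.1: recoverable mixture.
    * planted_asm — an A->T variant at frequency 0.5 whose variant allele is
      hypomethylated (per-site 0.1) while the reference allele is
      hypermethylated (0.9): a clear ASM candidate.
    * methylation_duality — half fully methylated, half fully unmethylated
      reads: two significant patterns with intermediate per-site levels.
    """
    region3 = random_region(seed * 4 + 1, "null_region", cpg_positions=(12, 30, 52))
    region4 = random_region(seed * 4 + 2, "mixture_region", cpg_positions=(10, 26, 44, 60))
    asm_region = random_region(seed * 4 + 3, "asm_region", cpg_positions=(12, 30, 52))
    # variant position: pick an A inside the window, away from CpGs, so the
    # A->T swap is immune to bisulfite conversion on both strands
    var_pos = _find_variant_position(asm_region)
    dual_region = random_region(seed * 4 + 4, "duality_region", cpg_positions=(10, 26, 44, 60))
    return {
        "null_uniform": SimulationConfig(
            region=region3, pattern_mix=uniform_mix(3), n_reads=600,
            conversion_failure=0.01, seq_error=0.005, seed=seed * 10 + 1,
        ),
        "planted_mixture": SimulationConfig(
            region=region4,
            pattern_mix=(("MMMM", 0.6), ("UUUU", 0.3), ("MUMU", 0.1)),
            n_reads=800, conversion_failure=0.01, seq_error=0.005, seed=seed * 10 + 2,
        ),
        "planted_asm": SimulationConfig(
            region=asm_region,
            pattern_mix=independent_site_mix(3, 0.9),
            variant=VariantSpec(
                position=var_pos, var_base="T", frequency=0.5,
                var_pattern_mix=independent_site_mix(3, 0.1),
            ),
            n_reads=600, conversion_failure=0.01, seq_error=0.005, seed=seed * 10 + 3,
        ),
        "methylation_duality": SimulationConfig(
            region=dual_region,
            pattern_mix=(("MMMM", 0.5), ("UUUU", 0.5)),
            n_reads=600, conversion_failure=0.01, seq_error=0.005, seed=seed * 10 + 4,
        ),
    }


def _find_variant_position(region: ReferenceRegion) -> int:
    window = select_window(region)
    near_cpg = {s + d for s in region.cpg_sites for d in (-1, 0, 1, 2)}
    for pos in range(window.start, window.end):
        if region.sequence[pos] == "A" and pos not in near_cpg:
            return pos
    raise ValueError("no suitable variant position in window")


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the four canonical scenarios (FASTA + FASTQ + truth + config).

    Each scenario directory also gets a coordinates file so track rendering
    is exercisable.  Returns scenario name -> directory path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for i, (name, config) in enumerate(sorted(fixture_configs(seed).items())):
        d = outdir / name
        d.mkdir(exist_ok=True)
        sim = simulate_region(config)
        write_references(d / "reference.fa", [config.region])
        write_fastq(d / "reads.fastq", sim)
        write_truth(d / "truth.tsv", sim)
        _write_config(d / "config.txt", config)
        start = 1_000_000 + 10_000 * i
        (d / "coords.bed").write_text(
            f"chr1\t{start}\t{start + len(config.region)}\t{config.region.name}\t0\t+\thg38\n"
        )
        paths[name] = d
    return paths
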