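# cometh

Methylation **co**-occurrence pattern analysis for targeted bisulfite
amplicon sequencing (**meth**ylation).

Deep amplicon bisulfite sequencing reads a small genomic region (typically
~100–500 bp) at thousands-fold coverage after bisulfite treatment, which
converts unmethylated cytosines to uracil (read as T) while methylated
cytosines stay C. At that depth each read reports the *joint* methylation
state of all CpG sites it spans — an epiallele — so one can ask questions
that per-site methylation levels cannot answer: which combinations of
methylated/unmethylated CpGs actually co-occur on single molecules, whether
neighbouring CpGs are methylated together, and whether methylation tracks a
nearby sequence variant (allele-specific methylation, ASM).

`cometh` is a small command-line tool and library for exactly that
workflow:

1. **Mapping** — gap-free bisulfite-aware alignment of FASTA/FASTQ reads to
   the amplicon references in converted space (C→T for original-top-strand
   reads, G→A for original-bottom-strand reads in forward coordinates),
   with a seed and a total mismatch budget; ambiguous best hits are
   discarded. Pre-aligned SAM (e.g. Bismark-style) can be imported instead.
2. **QC and methylation calling** — per-read bisulfite conversion rate
   (over non-CpG cytosines) and bisulfite-compatible sequence identity,
   with inclusive default thresholds 0.95 and 0.9; per-read M/U calls at
   every fully covered CpG.
3. **Pattern analysis** — within a window (default: 70 bp from the first
   CpG), reads covering all k window CpGs are grouped by signature into
   co-occurrence patterns. Each pattern with read fraction p̂ among n reads
   is scored one-sided against the baseline p₀ = 1/(number of observed
   patterns):

   Z = (p̂ − p₀) / √( p̂(1 − p̂) / n )

   Patterns with p < 0.05 are reported in descending significance.
   Pairwise CpG co-methylation is tested by Pearson χ² (1 df) on the 2×2
   read-count table aggregated from pattern supports.
4. **Mutations and ASM** — a mutation is a mismatch carried by ≥ 20 % of
   covering reads (conversion-confounded positions excluded per strand).
   Reads split by allele; a region is an ASM candidate when some CpG site
   falls in different methylation categories (≤ 20 % low / ≥ 80 % high /
   otherwise intermediate) between the allele groups with a level
   difference > 20 points.
5. **Reports** — a fixed-width text encoding (`@@` methylated CpG, `**`
   unmethylated, `-` non-CpG base, variant alleles as their base), a UCSC
   Genome Browser custom track (BED12), a PNG/EPS figure, and TSV tables.

A fully seeded simulator generates amplicon reads with known truth
(signature mixtures, conversion failures, sequencing errors, both strands,
optional methylation-linked variants), so the entire pipeline is testable
without external data.

## Worked example

Generate the built-in allele-specific-methylation scenario and run the full
workflow on it:

```bash
cometh simulate --out-dir fixtures --seed 1
cometh run \
    --reads fixtures/planted_asm/reads.fastq \
    --reference fixtures/planted_asm/reference.fa \
    --coords fixtures/planted_asm/coords.bed \
    --out-dir results_asm
```

Printed output:

```
590/600 reads mapped uniquely (98.33%)
asm_region: 480 covering reads, 8 patterns, 1 mutations, 1 ASM candidates
```

600 simulated reads carry an A→T variant at 50 % frequency whose variant
allele is hypomethylated (per-site level 0.1) while the reference allele is
hypermethylated (0.9). 590 reads map uniquely within the mismatch budget;
480 QC-passed reads cover all three window CpGs. The top of the text report
(`results_asm/asm_region.report.txt`):

```
asm_region	13-82	n=480
@@----------------@@--------------------@@----------------------------	173	36.0%
**----------------**--------------------**----------------------------	158	32.9%
```

i.e. the all-methylated and all-unmethylated epialleles dominate — the
mixture expected when methylation is allele-linked — and their percentages
need not sum to 100 because minor patterns are not significant. The ASM
table (`results_asm/asm.tsv`) shows the called mutation and the per-allele
site levels:

```
region      mutation_position  ref_allele  var_allele  var_fraction  ...  cpg_site  ref_level  ref_category  var_level  var_category  discriminating  asm_candidate
asm_region  17                 A           T           0.4825        ...  13        0.8911     HIGH          0.1082     LOW           True            True
```

Every CpG site discriminates (HIGH vs LOW, difference ≫ 20 points), so the
region is flagged as an ASM candidate. `asm_region.track.bed` is ready to
paste into the UCSC Genome Browser, and `asm_region.patterns.png` shows the
patterns graphically (filled circle = methylated, last row coloured green →
red by per-site level, blue bar = variant).

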