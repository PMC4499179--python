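# Methods

## Model and procedure

`cometh` analyses targeted deep bisulfite amplicon sequencing. The object
of inference is the distribution of methylation *co-occurrence patterns*
(epialleles): for a window containing k CpG sites, each molecule carries
one of 2^k joint states, and reads sampled from the amplicon estimate the
mixture over those states. The pipeline is:

align → per-read methylation calls + QC → window selection → pattern
grouping and significance → pairwise CpG dependence → mutation calling →
allele-specific methylation (ASM) evaluation → reports.

### Bisulfite-aware mapping

Bisulfite treatment converts unmethylated C to T on each original strand.
Reads from the original top strand (OT) therefore match the forward
reference up to C→T changes; reads from the original bottom strand (OB),
once reverse-complemented into forward coordinates, match up to G→A
changes. Mapping is done in *converted space*: read and reference are both
collapsed with the strand-appropriate substitution and compared by Hamming
distance at every offset of every region (regions are short, so the full
scan is exact; no index, no gaps). Two budgets apply, both counted in
converted space: at most `seed_mismatches` (default 3) within the first
`seed_length` bases of the read as sequenced, and at most `max_mismatches`
(default 2) overall. The seed length default of 28 is a conventional
short-read seed; it is a free parameter because the seed concept itself
does not fix one. The unique best hit wins; any tie across offsets,
regions or strands discards the read as ambiguous, which doubles as the
"low mapping quality" filter and keeps the mapper fully deterministic.
Base qualities are parsed and validated (phred33 default; phred64, solexa,
solexa1.3 accepted) but never scored: quality-weighted scoring would make
results depend on instrument calibration without changing the amplicon
placements, which are dominated by the mismatch budget. N counts as a
mismatch everywhere. The complementary strands (CTOT/CTOB) are off by
default — directional libraries are the amplicon norm — and can be enabled
(`search_complementary`).

### Methylation calls and QC

A CpG site is *covered* by a read only when both its C and its G are
inside the read: OT reads are informative at the C (C = methylated,
T = unmethylated), OB reads at the G in forward coordinates
(G = methylated, A = unmethylated), and requiring both bases makes the two
strands call exactly the same site set, so OT/OB reads of one template
yield identical signatures. Any other base is an AMBIGUOUS call — likelier
a variant or error than a methylation state — which excludes the read from
pattern analysis for windows containing that site but not from mutation
pileups.

Per-read QC:

* **conversion rate** = converted / total over the read's covered non-CpG
  cytosines on its own strand (OT: C not followed by G; OB: G not preceded
  by C, the bottom strand's cytosines). A read covering no such position
  passes with rate 1.0 — there is no evidence of failure, and discarding
  would bias against C-poor windows. The rate is per read, matching
  per-read filtering semantics, not a pooled library rate.
* **identity** = bisulfite-compatible matches / read length (ref C vs read
  T matches on OT, ref G vs read A on OB; N never matches). The
  denominator is the full read because alignments are gap-free and
  contained. This resolves an ambiguity the filter definition leaves open;
  it is a design choice, stated here deliberately.

Defaults: conversion ≥ 0.95, identity ≥ 0.9, both inclusive ("rate 0.95"
reads naturally as the minimum acceptable value).

### Patterns and significance

The analysis window defaults to 70 bp starting at the region's first CpG
site, clipped to the region; a user window (per region) overrides it. Only
reads covering *all* window sites with unambiguous calls enter the tally.
Reads sharing a signature form a pattern with support n_pattern, fraction
p̂ = n_pattern/n. The baseline probability is p₀ = 1/(number of observed
patterns) — deliberately data-driven rather than 1/2^k, since neighbouring
CpGs are correlated and n may be small relative to 2^k. Each pattern is
tested one-sided (H₁: p̂ > p₀) with

    Z = (p̂ − p₀) / sqrt( p̂ (1 − p̂) / n ),

the standard error evaluated at the observed p̂ (this exact form is the
package's defining statistic and is kept as is; a textbook one-sample test
would put p₀ in the denominator, making the test slightly conservative for
p̂ > p₀ — the null-calibration test bounds the consequence, a flag rate
≤ 0.08 at α = 0.05). Degenerate unanimity p̂ = 1 has zero standard error:
it is scored significant (Z = +∞, p = 0) when p₀ < 1 (alternatives were
observed conceivable) and trivially non-significant (Z = 0, p = 1) when it
is the only pattern. Significant patterns (p < α, default 0.05; optional
minimum-fraction filter; optional Bonferroni α/#patterns, off by default)
are reported in descending Z; ties break by descending support, then
signature (M before U) — invented purely for output determinism.

Pairwise CpG dependence: the 2×2 table of read counts
(methylated/unmethylated at site a × site b) is aggregated from pattern
supports and tested by Pearson χ² with 1 df, no continuity correction. A
zero margin carries no dependence information and is defined as χ² = 0,
p = 1. The χ² is computed directly from the closed form (so the degenerate
rule is explicit) and is cross-checked against
`scipy.stats.chi2_contingency` in the tests. Reports include all k·(k−1)/2
pairs, uncorrected — an exploratory screen, not a confirmatory test.

### Mutations and allele-specific methylation

Pileups count read bases per reference position over QC-passed reads,
*excluding conversion-confounded comparisons*: OT reads are skipped at
every reference-C position and OB reads at every reference-G position,
because a read T under a reference C (or A under G) may be conversion
rather than genotype. A CpG's C is therefore genotyped only from OB reads
and its G only from OT reads. A mutation is called where the most frequent
non-reference base reaches the threshold (default 0.2) among counted
reads, with a coverage floor (default 10 reads) to suppress noise; only
the single most frequent variant base is considered (biallelic model).

For each mutation inside the window, window-covering reads split into
reference-allele and variant-allele groups (reads not covering the
position, confounded at it, or carrying a third base stay unassigned; the
three sets partition the input). Per group and per site, the methylation
level is binned: ≤ 0.20 LOW, ≥ 0.80 HIGH, otherwise INTERMEDIATE. The
region is an ASM candidate when at least one site differs in category
between groups AND the absolute level difference is strictly greater than
0.20 (strict, consistent with the inclusive category bounds being ≤/≥).
Each group also gets its own pattern analysis. Groups below the size floor
(default 10 reads) yield "insufficient data" rather than a call. Optional
annotation maps mutation positions to variant IDs from a local plain-text
VCF via the region's genome coordinates; no network access.

### Reports

Text: header (region, 1-based inclusive window), then one fixed-width line
per significant pattern — `@@` methylated CpG, `**` unmethylated CpG, `-`
non-CpG base, variant alleles as their base character — suffixed with
support and percentage (one decimal). Track: a UCSC custom track of BED12
lines, one per significant pattern with methylated CpGs as 2-bp blocks and
score = round(fraction×1000) clamped to [0, 1000], plus one single-block
line per CpG site scored by its overall methylation level. Because BED12
requires the first block to start at chromStart and the last to end at
chromEnd, 1-bp anchor blocks are inserted at the window edges when no
methylated-site block touches them; browsers render these as thin ticks.
All BED coordinates are 0-based half-open; human-readable outputs are
1-based inclusive; genome position of region offset x is `start + x`
regardless of strand (the strand only fills the BED strand column).
Figure: one row of circles per pattern (filled = methylated, blue bar at
variant positions, percentage at row end) and a summary row coloured green
(low) → red (high) by per-site level; PNG or EPS. Pattern percentages need
not sum to 100, since reads outside significant patterns are not drawn.
Text and track renderers are pure string functions — identical inputs give
byte-identical files.

## Simulator

The generator emulates the targeted amplicon setting: a ~127 bp region
(amplicon-typical) with planted CpG positions (accidental background CpGs
are scrubbed so the site index is fully controlled), 75 bp reads (within
the common 69–80 bp post-trimming range), a signature mixture over the
window sites, per-non-CpG-cytosine conversion-failure probability, per-base
substitution-error probability, a 50/50 OT/OB strand mix, and an optional
variant whose allele can carry its own signature mix (the ASM mechanism).
Conversion is applied to the variant-applied template, so a CpG-destroying
variant naturally loses protection at that site. OB reads are emitted
reverse-complemented, as sequenced. Everything is driven by one explicit
seed (recorded in the FASTQ header comments); identical configs give
byte-identical FASTQ.

Four canonical scenarios ship with the tool (`cometh simulate`):
`null_uniform` (k = 3, uniform signatures, n = 600), `planted_mixture`
(0.6/0.3/0.1 over k = 4, n = 800), `planted_asm` (A→T variant at frequency
0.5, per-site levels 0.9 vs 0.1, n = 600 — the variant position is chosen
as an A away from CpGs so the A↔T swap is conversion-immune on both
strands), and `methylation_duality` (50/50 fully methylated / fully
unmethylated, n = 600). Scenario sizes are chosen to keep the default test
suite fast while leaving binomial noise far below every tolerance used.

What the simulator does *not* model — and hence what passing tests do not
establish about real libraries: PCR duplicates and amplification bias,
indel sequencing errors (the aligner is gap-free by design),
quality-score-correlated errors, chimeric reads, hemimethylation
(OT and OB are simulated from one symmetric methylation state), and
non-CpG (CHH/CHG) methylation, which the conversion-rate filter assumes
absent.

## Numerical and interface choices

* Coordinates: 0-based half-open internally everywhere; 1-based inclusive
  only in human-readable output. BED input/output follows the BED
  standard. Lowercase reference bases are uppercased on load; N never
  forms a CpG.
* Genome coordinates are user-supplied metadata (BED6 or a simple
  name/chrom/start/strand table; assemblies hg38/hg19/hg18); they gate
  only track output. Conflicting duplicate entries: first wins.
* Z and p-values print in scientific notation with 3 significant digits;
  percentages with one decimal; these are formatting conventions only.
* Determinism: alignment, grouping, sorting and rendering are
  deterministic and independent of read order; the CLI writes a run
  manifest with every threshold for provenance.
* Degenerate inputs: empty read files, windowless regions and
  zero-covering windows produce empty outputs with warnings, not errors.

## Known limitations

* The mutation caller is intentionally simple (fraction threshold over a
  pileup); it has no base-quality model, no strand-bias test, and cannot
  see variants at positions confounded on both strands.
* p₀ depends on the observed pattern count, so significance is not
  comparable across windows with very different pattern richness.
* The χ² pair screen is uncorrected by design; with many CpGs, expect
  false positives at the nominal rate per pair.
* Paired-end reads, gapped alignment and genome-scale references are out
  of scope: the tool assumes reads shorter than the (short) amplicon
  references.
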