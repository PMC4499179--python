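"""Methylation co-occurrence pattern grouping and significance testing.

Within an analysis window holding k CpG sites, every read that covers all k
sites carries a signature: its joint methylation status vector (an
epiallele).  Reads sharing a signature form a co-occurrence pattern whose
read count is its support.  Pattern prevalence is scored with a one-sample
proportion Z statistic,

    Z = (p_hat - p0) / sqrt(p_hat (1 - p_hat) / n),

where p_hat is the pattern's read fraction, n the total read count, and the
baseline p0 is one over the number of observed patterns — a data-driven
stand-in for the naive 1/2^k that would ignore the strong dependence of
neighbouring CpG sites.  The test is one-sided (H1: p_hat > p0); the
denominator deliberately uses p_hat, the binomial standard error at the
observed frequency.  Pairwise dependence between two CpG sites is assessed
with a Pearson chi-square on the 2x2 table of read counts aggregated from
pattern supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .methylation_qc import AMBIGUOUS, METHYLATED, ReadMethylation, UNMETHYLATED
from .reference_io import ReferenceRegion

DEFAULT_WINDOW_SIZE = 70
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Window:
    """Analysis window on a region: [start, end) plus the CpG sites fully inside."""

    region_name: str
    start: int
    end: int
    sites: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def select_window(
    region: ReferenceRegion,
    user_window: Optional[tuple[int, int]] = None,
    size: int = DEFAULT_WINDOW_SIZE,
) -> Window:
    """Choose the analysis window.

    With no user window the default starts at the region's first CpG site
    and spans ``size`` bases (clipped to the region end).  A user window is
    clipped to the region.  A window must contain at least one complete CpG
    (both bases inside).
    """
    if user_window is not None:
        start = max(0, user_window[0])
        end = min(len(region), user_window[1])
        if start >= end:
            raise ValueError(f"empty window {user_window} for region {region.name!r}")
    else:
        if not region.cpg_sites:
            raise ValueError(f"no CpG sites in region {region.name!r} and no window given")
        start = region.cpg_sites[0]
        end = min(start + size, len(region))
    sites = tuple(s for s in region.cpg_sites if start <= s and s + 1 < end)
    if not sites:
        raise ValueError(
            f"window [{start},{end}) of region {region.name!r} contains no complete CpG site"
        )
    return Window(region.name, start, end, sites)


@dataclass(frozen=True)
class Pattern:
    """One co-occurrence pattern: signature, support, fraction, Z, p."""

    signature: str  # one char per window site: M or U
    support: int
    fraction: float  # p_hat
    z: float
    p_value: float


@dataclass(frozen=True)
class PatternSet:
    """All observed patterns in a window, with n and the baseline p0."""

    window: Optional[Window]
    n: int
    patterns: tuple[Pattern, ...]
    p0: float

    def __len__(self) -> int:
        return len(self.patterns)


def pattern_zscore(p_hat: float, p0: float, n: int) -> tuple[float, float]:
    """One-sided proportion Z statistic and upper-tail p-value.

    Degenerate unanimity (p_hat == 1, zero standard error): significant
    (z=inf, p=0) when alternatives were observed possible (p0 < 1), and
    trivially non-significant (z=0, p=1) when it is the only pattern
    (p0 == 1).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < p_hat <= 1.0 or not 0.0 < p0 <= 1.0:
        raise ValueError(f"p_hat and p0 must be in (0, 1], got {p_hat}, {p0}")
    if p_hat == 1.0:
        if p0 < 1.0:
            return math.inf, 0.0
        return 0.0, 1.0
    z = (p_hat - p0) / math.sqrt(p_hat * (1.0 - p_hat) / n)
    return z, float(stats.norm.sf(z))


def pattern_set_from_signatures(
    signatures: Iterable[str], window: Optional[Window] = None
) -> PatternSet:
    """Group raw signature strings into a scored PatternSet.

    This is the core tally: one pattern per distinct signature, supports
    summing to n, p0 = 1 / number of distinct signatures, Z and p per
    pattern.  Patterns are listed in descending support (ties by signature)
    for stable output.
    """
    counts: dict[str, int] = {}
    n = 0
    for sig in signatures:
        counts[sig] = counts.get(sig, 0) + 1
        n += 1
    if n == 0:
        return PatternSet(window=window, n=0, patterns=(), p0=1.0)
    p0 = 1.0 / len(counts)
    patterns = []
    for sig, support in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        p_hat = support / n
        z, p = pattern_zscore(p_hat, p0, n)
        patterns.append(Pattern(sig, support, p_hat, z, p))
    return PatternSet(window=window, n=n, patterns=tuple(patterns), p0=p0)


def reads_covering_window(
    calls: Iterable[ReadMethylation], window: Window
) -> list[ReadMethylation]:
    """Reads covering every window site with an unambiguous call at each."""
    site_set = set(window.sites)
    out = []
    for call in calls:
        if not site_set.issubset(call.covered_sites):
            continue
        if any(call.status[s] == AMBIGUOUS for s in window.sites):
            continue
        out.append(call)
    return out


def group_patterns(
    covering_reads: Sequence[ReadMethylation], window: Window
) -> PatternSet:
    """PatternSet over the window from pre-filtered covering reads."""
    return pattern_set_from_signatures(
        (read.signature(window.sites) for read in covering_reads), window
    )


def significant_patterns(
    ps: PatternSet,
    alpha: float = DEFAULT_ALPHA,
    min_fraction: Optional[float] = None,
    bonferroni: bool = False,
) -> list[Pattern]:
    """Patterns with p < alpha (optionally Bonferroni: alpha / #patterns),
    and fraction >= min_fraction if given, in descending significance.

    Order: descending z, ties by descending support, then signature
    (M sorts before U).
    """
    threshold = alpha / len(ps.patterns) if bonferroni and ps.patterns else alpha
    selected = [
        p
        for p in ps.patterns
        if p.p_value < threshold and (min_fraction is None or p.fraction >= min_fraction)
    ]
    return sorted(selected, key=lambda p: (-p.z, -p.support, p.signature))


def cpg_pair_dependency(
    ps: PatternSet, site_index_a: int, site_index_b: int
) -> tuple[float, float, list[list[int]]]:
    """Pearson chi-square (1 df, no continuity correction) for co-methylation
    of two window sites, on the 2x2 read-count table aggregated from pattern
    supports.

    Table layout: rows = site a methylated/unmethylated, columns = site b.
    A zero margin carries no dependence information: chi2 = 0, p = 1.
    """
    k = len(ps.patterns[0].signature) if ps.patterns else 0
    for idx in (site_index_a, site_index_b):
        if not 0 <= idx < k:
            raise IndexError(f"site index {idx} out of range for {k} window sites")
    table = [[0, 0], [0, 0]]
    for pat in ps.patterns:
        i = 0 if pat.signature[site_index_a] == METHYLATED else 1
        j = 0 if pat.signature[site_index_b] == METHYLATED else 1
        table[i][j] += pat.support
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (row1, row2, col1, col2):
        return 0.0, 1.0, table
    chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    return chi2, float(stats.chi2.sf(chi2, df=1)), table


def all_pair_dependencies(ps: PatternSet) -> list[tuple[int, int, float, float]]:
    """chi2/p for every pair of window sites (k choose 2), uncorrected."""
    k = len(ps.patterns[0].signature) if ps.patterns else 0
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            chi2, p, _ = cpg_pair_dependency(ps, i, j)
            out.append((i, j, chi2, p))
    return out


def site_methylation_levels(
    reads: Sequence[ReadMethylation], sites: Sequence[int]
) -> dict[int, float]:
    """Per-site fraction of methylated calls among non-ambiguous calls."""
    levels: dict[int, float] = {}
    for s in sites:
        m = u = 0
        for read in reads:
            call = read.status.get(s)
            if call == METHYLATED:
                m += 1
            elif call == UNMETHYLATED:
                u += 1
        levels[s] = m / (m + u) if (m + u) else 0.0
    return levels
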