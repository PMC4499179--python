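"""Report renderers: text patterns, UCSC custom track, and pattern figure.

Three views of the same PatternSet:

* text — one fixed-width line per significant pattern: '@@' methylated CpG,
  '**' unmethylated CpG, '-' non-CpG position, and a variant allele shown as
  its base character; each line is suffixed with support and percentage.
* UCSC custom track — a track header plus BED12 lines, one per significant
  pattern (methylated CpG sites as 2-bp blocks, score = fraction x 1000) and
  one per CpG site with its overall methylation level as the score.
* figure — one row of circles per pattern (filled = methylated) plus a
  summary row coloured green (low) to red (high) by per-site level.

The text and track renderers are pure string functions so identical inputs
give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .methylation_qc import METHYLATED
from .pattern_analysis import (
    DEFAULT_ALPHA,
    Pattern,
    PatternSet,
    Window,
    significant_patterns,
    site_methylation_levels,
)
from .reference_io import ReferenceRegion
from .variant_asm import ASMResult, Mutation


def _fmt_stat(v: float) -> str:
    """Scientific notation, 3 significant digits; inf printed as 'inf'."""
    import math

    if math.isinf(v):
        return "inf"
    return f"{v:.2e}"


def pattern_cells(
    signature: str, window: Window, mutations: Optional[Sequence[Mutation]] = None
) -> str:
    """Fixed-width character cells for one pattern over the window."""
    cells = ["-"] * (window.end - window.start)
    for sig_char, site in zip(signature, window.sites):
        mark = "@" if sig_char == METHYLATED else "*"
        cells[site - window.start] = mark
        cells[site + 1 - window.start] = mark
    for mut in mutations or ():
        if window.start <= mut.position < window.end:
            cells[mut.position - window.start] = mut.var_allele
    return "".join(cells)


def render_text(
    ps: PatternSet,
    window: Window,
    mutations: Optional[Sequence[Mutation]] = None,
    alpha: float = DEFAULT_ALPHA,
    min_fraction: Optional[float] = None,
) -> list[str]:
    """Text-format report lines: header then one line per significant pattern.

    Window coordinates in the header are 1-based inclusive; percentages have
    one decimal place.
    """
    lines = [f"{window.region_name}\t{window.start + 1}-{window.end}\tn={ps.n}"]
    for pat in significant_patterns(ps, alpha=alpha, min_fraction=min_fraction):
        pct = 100.0 * pat.fraction
        lines.append(
            f"{pattern_cells(pat.signature, window, mutations)}"
            f"\t{pat.support}\t{pct:.1f}%"
        )
    return lines


def _bed12_line(
    chrom: str,
    start: int,
    end: int,
    name: str,
    score: int,
    strand: str,
    blocks: list[tuple[int, int]],
) -> str:
    """One BED12 line; ``blocks`` are (relative start, size), strictly
    increasing.  1-bp anchor blocks are added so the first block starts at
    chromStart and the last ends at chromEnd, as BED12 requires."""
    span = end - start
    blocks = sorted(blocks)
    if not blocks or blocks[0][0] > 0:
        blocks.insert(0, (0, 1))
    last_start, last_size = blocks[-1]
    if last_start + last_size < span:
        blocks.append((span - 1, 1))
    sizes = ",".join(str(size) for _, size in blocks)
    starts = ",".join(str(s) for s, _ in blocks)
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}"
        f"\t{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{starts}"
    )


def render_track(
    ps: PatternSet,
    region: ReferenceRegion,
    reads=None,
    sample: str = "sample",
    alpha: float = DEFAULT_ALPHA,
    min_fraction: Optional[float] = None,
) -> str:
    """UCSC Genome Browser custom-track text for one region.

    Requires genome coordinates on the region.  Emits one BED12 line per
    significant pattern (blocks = methylated CpG sites, score =
    round(fraction x 1000)) and one summary line per window CpG site whose
    score is the site's overall methylation level x 1000.  All coordinates
    0-based half-open per BED.
    """
    if region.genome is None:
        raise ValueError(
            f"region {region.name!r} has no genome coordinates; supply a "
            "coordinates file (BED6 or name/chrom/start/strand) to enable track output"
        )
    window = ps.window
    if window is None:
        raise ValueError("PatternSet has no window; track output needs one")
    g = region.genome
    gstart = g.start + window.start
    gend = g.start + window.end
    lines = [
        f'track name="{region.name}_patterns" '
        f'description="methylation co-occurrence patterns ({sample}, {g.assembly})" '
        'itemRgb="Off" visibility=2'
    ]
    for i, pat in enumerate(
        significant_patterns(ps, alpha=alpha, min_fraction=min_fraction), start=1
    ):
        blocks = [
            (site - window.start, 2)
            for sig_char, site in zip(pat.signature, window.sites)
            if sig_char == METHYLATED
        ]
        score = max(0, min(1000, round(pat.fraction * 1000)))
        lines.append(
            _bed12_line(
                g.chrom, gstart, gend, f"p{i}_{pat.signature}", score, g.strand, blocks
            )
        )
    levels = _summary_levels(ps, reads, window)
    for site in window.sites:
        score = max(0, min(1000, round(levels.get(site, 0.0) * 1000)))
        site_start = g.start + site
        lines.append(
            _bed12_line(
                g.chrom, site_start, site_start + 2,
                f"site_{site + 1}", score, g.strand, [(0, 2)],
            )
        )
    return "\n".join(lines) + "\n"


def _summary_levels(ps: PatternSet, reads, window: Window) -> dict[int, float]:
    """Per-site methylation level, from reads when given else pattern supports."""
    if reads is not None:
        return site_methylation_levels(reads, window.sites)
    levels: dict[int, float] = {}
    if ps.n == 0:
        return {s: 0.0 for s in window.sites}
    for j, site in enumerate(window.sites):
        m = sum(p.support for p in ps.patterns if p.signature[j] == METHYLATED)
        levels[site] = m / ps.n
    return levels


def render_figure(
    ps: PatternSet,
    window: Window,
    path: str | Path,
    region: Optional[ReferenceRegion] = None,
    asm: Optional[ASMResult] = None,
    alpha: float = DEFAULT_ALPHA,
    min_fraction: Optional[float] = None,
    fmt: Optional[str] = None,
) -> Path:
    """Graphical pattern report (PNG or EPS by extension or ``fmt``).

    One row per significant pattern: filled circle = methylated CpG, open
    circle = unmethylated, blue bar at variant positions, support percentage
    at the row end.  The last row shows the proportion of methylated reads
    per site on a green (low) to red (high) colour scale.  Note the pattern
    percentages need not sum to 100: reads outside any significant pattern
    are not shown.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".") or "png").lower()
    if fmt not in ("png", "eps"):
        raise ValueError(f"unsupported figure format {fmt!r} (PNG or EPS)")

    sig = significant_patterns(ps, alpha=alpha, min_fraction=min_fraction)
    sites = window.sites
    if region is not None and region.genome is not None:
        xs = [region.genome.start + s for s in sites]
        xlabel = f"{region.genome.chrom} ({region.genome.assembly})"
    else:
        xs = [s + 1 for s in sites]
        xlabel = f"{window.region_name} position"
    mutations: list[Mutation] = []
    if asm is not None:
        mutations = [asm.mutation]

    n_rows = len(sig) + 1
    fig, ax = plt.subplots(figsize=(max(4.0, 0.5 * len(sites) + 2.5), 0.6 * n_rows + 1.2))
    cmap = LinearSegmentedColormap.from_list("meth", ["green", "yellow", "red"])
    span = (max(xs) - min(xs)) or 1
    for row, pat in enumerate(sig):
        y = n_rows - 1 - row
        for x, sig_char in zip(xs, pat.signature):
            filled = sig_char == METHYLATED
            ax.scatter(
                [x], [y], s=120,
                facecolors="black" if filled else "white",
                edgecolors="black", zorder=3,
            )
        for mut in mutations:
            gx = (
                region.genome.start + mut.position
                if region is not None and region.genome is not None
                else mut.position + 1
            )
            ax.plot([gx, gx], [y - 0.3, y + 0.3], color="blue", lw=4, zorder=2)
        ax.text(
            max(xs) + 0.04 * span, y, f"{100 * pat.fraction:.1f}% ({pat.support})",
            va="center", fontsize=9,
        )
    levels = _summary_levels(ps, None, window)
    for x, site in zip(xs, sites):
        ax.scatter(
            [x], [0], s=120, facecolors=cmap(levels.get(site, 0.0)),
            edgecolors="black", zorder=3,
        )
    ax.text(max(xs) + 0.04 * span, 0, "% methylated", va="center", fontsize=9)
    if not sig:
        ax.set_title(f"{window.region_name}: no significant patterns", fontsize=10)
    else:
        ax.set_title(f"{window.region_name} methylation co-occurrence patterns", fontsize=10)
    ax.set_xlabel(xlabel)
    ax.set_yticks([])
    ax.set_ylim(-0.8, n_rows - 0.2)
    ax.margins(x=0.15)
    fig.tight_layout()
    fig.savefig(path, format=fmt, dpi=120)
    plt.close(fig)
    return path


def pattern_table(ps: PatternSet, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Pattern summary table (window coordinates 1-based inclusive)."""
    window = ps.window
    sig = {p.signature for p in significant_patterns(ps, alpha=alpha)}
    rows = []
    for pat in ps.patterns:
        rows.append(
            {
                "region": window.region_name if window else "",
                "window_start": window.start + 1 if window else "",
                "window_end": window.end if window else "",
                "signature": pat.signature,
                "support": pat.support,
                "fraction": f"{pat.fraction:.6f}",
                "z": _fmt_stat(pat.z),
                "p_value": _fmt_stat(pat.p_value),
                "significant": pat.signature in sig,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "window_start", "window_end", "signature",
            "support", "fraction", "z", "p_value", "significant",
        ],
    )


def asm_table(results: Sequence[ASMResult]) -> pd.DataFrame:
    """ASM summary table, one row per (mutation, CpG site)."""
    rows = []
    for res in results:
        m = res.mutation
        for site in res.ref_group.site_levels:
            rows.append(
                {
                    "region": m.region_name,
                    "mutation_position": m.position + 1,
                    "ref_allele": m.ref_allele,
                    "var_allele": m.var_allele,
                    "var_fraction": f"{m.var_fraction:.4f}",
                    "dbsnp_id": m.dbsnp_id or "",
                    "cpg_site": site + 1,
                    "ref_level": f"{res.ref_group.site_levels[site]:.4f}",
                    "ref_category": res.ref_group.site_categories[site],
                    "var_level": f"{res.var_group.site_levels[site]:.4f}",
                    "var_category": res.var_group.site_categories[site],
                    "discriminating": site in res.discriminating_sites,
                    "asm_candidate": res.is_candidate,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "mutation_position", "ref_allele", "var_allele",
            "var_fraction", "dbsnp_id", "cpg_site", "ref_level", "ref_category",
            "var_level", "var_category", "discriminating", "asm_candidate",
        ],
    )
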