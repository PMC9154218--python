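"""Figure rendering: score distributions, segment plots, locus/region/composite.

Strictly a view layer — nothing here mutates the data structures it draws.
The locus figure follows a fixed panel grammar, top to bottom: gene models,
read alignments (motif sites as open/closed dots), the genome→motif-space
translation fan, the raw per-call score scatter, and the smoothed
methylation-fraction profile.  Region figures reuse the translation/smoothed
panels over motif-normalized bins; composite figures show the pooled
consensus-space profile above a handful of per-element tracks.

SVG output is deterministic for a fixed input (the figure date metadata is
suppressed and the hash salt pinned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .calls import CallState, CutoffConfig
from .composite import CompositeProfile
from .profiles import LocusData, RegionData
from .store import ScoreDistribution

logger = logging.getLogger(__name__)

#: Colour-blind-safe categorical palette, keyed by sample/group order.
PALETTE = ["#0072B2", "#D55E00", "#009E73", "#CC79A7", "#F0E442", "#56B4E9",
           "#E69F00", "#999999"]

_SVG_SALT = "methkit"


@dataclass
class PlotSpec:
    """Figure-level options shared by the multi-panel plots."""

    width: float = 10.0
    height: float = 8.0
    dpi: int = 150
    palette: Sequence[str] = field(default_factory=lambda: list(PALETTE))
    panel_ratios: Tuple[float, ...] = (1, 4, 1, 2, 2)  # genes:reads:translation:raw:smoothed
    show_genes: bool = True
    show_reads: bool = True
    show_translation: bool = True
    show_raw: bool = True
    show_smoothed: bool = True
    fontsize: float = 8.0

    def color(self, i: int) -> str:
        return self.palette[i % len(self.palette)]


def _save(fig, out: str, dpi: int = 150) -> None:
    with matplotlib.rc_context({"svg.hashsalt": _SVG_SALT}):
        if str(out).endswith(".svg"):
            fig.savefig(out, metadata={"Date": None})
        else:
            fig.savefig(out, dpi=dpi)
    plt.close(fig)


def plot_scoredist(
    dists: Sequence[ScoreDistribution],
    out: str,
    cutoffs: Optional[CutoffConfig] = None,
    spec: Optional[PlotSpec] = None,
) -> str:
    """Kernel density estimate of scores per sample, with cutoff lines.

    Dashed vertical lines mark the unmethylated (left) and methylated
    (right) call cutoffs; omit ``cutoffs`` to omit them.
    """
    spec = spec or PlotSpec()
    fig, ax = plt.subplots(figsize=(spec.width, spec.height / 2))
    for i, d in enumerate(dists):
        ax.plot(d.grid, d.density, color=spec.color(i), label=d.sample)
        ax.fill_between(d.grid, d.density, alpha=0.15, color=spec.color(i))
    if cutoffs is not None:
        for x in (cutoffs.lo, cutoffs.hi):
            ax.axvline(x, linestyle="--", color="0.3", linewidth=1)
    ax.set_xlabel("log probability ratio")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    sns.despine(ax=ax)
    _save(fig, out, spec.dpi)
    return out


def plot_segplot(
    segmeth_df: pd.DataFrame,
    out: str,
    style: str = "ridge",
    value: str = "meth_fraction",
    spec: Optional[PlotSpec] = None,
) -> str:
    """Distribution of per-segment methylation fractions by group and sample.

    ``style`` is one of strip / violin / ridge; one distribution per
    (group, sample) combination.
    """
    spec = spec or PlotSpec()
    df = segmeth_df.dropna(subset=[value]).copy()
    df["group"] = df["group"].fillna("all")
    samples = sorted(df["sample"].unique())
    groups = sorted(df["group"].unique())
    colors = {s: spec.color(i) for i, s in enumerate(samples)}

    if style == "strip":
        fig, ax = plt.subplots(figsize=(spec.width, spec.height / 2))
        sns.stripplot(data=df, x="group", y=value, hue="sample",
                      dodge=True, palette=colors, size=3, ax=ax)
        sns.despine(ax=ax)
    elif style == "violin":
        fig, ax = plt.subplots(figsize=(spec.width, spec.height / 2))
        sns.violinplot(data=df, x="group", y=value, hue="sample",
                       palette=colors, cut=0, ax=ax)
        sns.despine(ax=ax)
    elif style == "ridge":
        fig, axes = plt.subplots(
            len(groups), 1, sharex=True,
            figsize=(spec.width, max(2.0, 0.9 * len(groups))),
        )
        axes = np.atleast_1d(axes)
        for ax, g in zip(axes, groups):
            sub = df[df["group"] == g]
            for s in samples:
                vals = sub.loc[sub["sample"] == s, value].to_numpy()
                if np.unique(vals).size > 1:
                    sns.kdeplot(x=vals, ax=ax, fill=True, alpha=0.4,
                                color=colors[s], label=s, clip=(0, 1),
                                warn_singular=False)
                elif vals.size:
                    ax.axvline(vals[0], color=colors[s], alpha=0.7, label=s)
            ax.set_ylabel(g, rotation=0, ha="right", fontsize=spec.fontsize)
            ax.set_yticks([])
            sns.despine(ax=ax, left=True)
        axes[0].legend(frameon=False, fontsize=spec.fontsize)
        axes[-1].set_xlabel(value)
    else:
        raise ValueError(f"unknown segplot style {style!r}; use strip, violin or ridge")
    _save(fig, out, spec.dpi)
    return out


# ---------------------------------------------------------------------------
# locus plot
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A transcript for the annotation track: exon boxes, intron lines."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]]


def read_gene_models(path: str) -> List[GeneModel]:
    """Load gene models from BED12 (blocked) or BED6/BED4 (one box each)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}"
            strand = f[5] if len(f) > 5 else "+"
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            else:
                exons = [(start, end)]
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return genes


def _stack_rows(intervals: List[Tuple[int, int]]) -> List[int]:
    """Greedy first-fit row assignment by start coordinate (display stacking)."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i][0])
    row_ends: List[int] = []
    rows = [0] * len(intervals)
    for i in order:
        s, e = intervals[i]
        for r, re_ in enumerate(row_ends):
            if s > re_:
                rows[i] = r
                row_ends[r] = e
                break
        else:
            rows[i] = len(row_ends)
            row_ends.append(e)
    return rows


def plot_locus(
    data: LocusData,
    out: str,
    genes: Optional[Sequence[GeneModel]] = None,
    spec: Optional[PlotSpec] = None,
) -> str:
    """Multi-panel locus figure in the fixed top-to-bottom panel order.

    Panels: gene models; reads with motif sites drawn as closed (MOD),
    open (UNMOD) or small grey (AMBIG) dots; the genome→motif-space
    translation fan; raw per-call scores; smoothed methylation fraction.
    Panels can be hidden through the spec; highlight intervals are shaded
    through every panel.
    """
    spec = spec or PlotSpec()
    idx = data.index
    panels = []
    names = ("genes", "reads", "translation", "raw", "smoothed")
    shown = (spec.show_genes and genes is not None, spec.show_reads,
             spec.show_translation, spec.show_raw, spec.show_smoothed)
    ratios = [r for r, s in zip(spec.panel_ratios, shown) if s]
    names = [n for n, s in zip(names, shown) if s]
    if not names:
        raise ValueError("all panels hidden")

    fig, axes = plt.subplots(
        len(names), 1, figsize=(spec.width, spec.height),
        gridspec_kw={"height_ratios": ratios},
    )
    axes = np.atleast_1d(axes)
    ax_by = dict(zip(names, axes))
    colors = {g: spec.color(i) for i, g in enumerate(data.groups)}
    genome_axes = [ax_by[n] for n in ("genes", "reads", "translation") if n in ax_by]
    motif_axes = [ax_by[n] for n in ("raw", "smoothed") if n in ax_by]

    for s, e in data.highlights:
        for ax in genome_axes:
            ax.axvspan(s, e, color="#ffe9a8", zorder=0)
        ranks = [idx.rank_of(p) for p in idx.positions if s <= p < e]
        ranks = [r for r in ranks if r is not None]
        if ranks:
            for ax in motif_axes:
                ax.axvspan(min(ranks) - 0.5, max(ranks) + 0.5,
                           color="#ffe9a8", zorder=0)

    if "genes" in ax_by:
        ax = ax_by["genes"]
        rows = _stack_rows([(g.start, g.end) for g in genes]) if genes else []
        for g, row in zip(genes or [], rows):
            y = -row
            ax.plot([g.start, g.end], [y, y], color="0.2", linewidth=1)
            for es, ee in g.exons:
                ax.add_patch(plt.Rectangle((es, y - 0.3), ee - es, 0.6,
                                           color="0.2"))
            ax.text(g.start, y + 0.45, g.name, fontsize=spec.fontsize)
        ax.set_ylim(-(max(rows) if rows else 0) - 1, 1)
        ax.set_yticks([])

    if "reads" in ax_by:
        ax = ax_by["reads"]
        rows = _stack_rows([(r.start, r.end) for r in data.reads])
        marker = {CallState.MOD: dict(marker="o", fillstyle="full"),
                  CallState.UNMOD: dict(marker="o", fillstyle="none"),
                  CallState.AMBIG: dict(marker=".", color="0.6")}
        for read, row in zip(data.reads, rows):
            y = -row
            c = colors[read.group]
            ax.plot([read.start, read.end], [y, y], color=c, linewidth=0.8,
                    alpha=0.7)
            for rank, state in enumerate(read.states):
                if state is CallState.NOCALL:
                    continue
                m = marker[state]
                ax.plot(idx.positions[rank], y, markersize=3,
                        markeredgecolor=c if state is not CallState.AMBIG else "0.6",
                        markerfacecolor=c if state is CallState.MOD else "none",
                        linestyle="none", marker=m["marker"])
        ax.set_yticks([])
        ax.set_ylabel("reads", fontsize=spec.fontsize)

    if "translation" in ax_by:
        ax = ax_by["translation"]
        n = len(idx)
        span = idx.end - idx.start
        for rank, pos in enumerate(idx.positions):
            x_motif = idx.start + (rank + 0.5) / n * span
            ax.plot([pos, x_motif], [1, 0], color="0.5", linewidth=0.4)
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel("motif\nspace", fontsize=spec.fontsize)

    for ax in genome_axes:
        ax.set_xlim(idx.start, idx.end)

    if "raw" in ax_by:
        ax = ax_by["raw"]
        for g in data.groups:
            ranks, scores, _states = data.raw_points[g]
            ax.plot(ranks, scores, ".", markersize=2.5, alpha=0.5,
                    color=colors[g], label=g)
        ax.axhline(0, color="0.8", linewidth=0.6)
        ax.set_ylabel("log prob ratio", fontsize=spec.fontsize)

    if "smoothed" in ax_by:
        ax = ax_by["smoothed"]
        for g in data.groups:
            frac = data.smoothed[g]
            ax.plot(np.arange(len(frac)), frac, color=colors[g], label=g)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("meth. fraction", fontsize=spec.fontsize)
        ax.set_xlabel(f"{idx.motif} site rank")
        ax.legend(frameon=False, fontsize=spec.fontsize)

    for ax in motif_axes:
        ax.set_xlim(-0.5, len(idx) - 0.5)
    for ax in axes:
        sns.despine(ax=ax)
    _save(fig, out, spec.dpi)
    return out


def plot_region(
    data: RegionData,
    out: str,
    spec: Optional[PlotSpec] = None,
) -> str:
    """Binned region figure: per-bin fractions plus smoothed profile.

    The x axis is the methylation-bin index; masked bins (no motif site)
    leave gaps.
    """
    spec = spec or PlotSpec()
    fig, ax = plt.subplots(figsize=(spec.width, spec.height / 2))
    for i, (sample, bdf) in enumerate(sorted(data.bins.items())):
        c = spec.color(i)
        ax.plot(bdf["bin"], bdf["meth_fraction"], ".", markersize=2.5,
                alpha=0.35, color=c)
        bins, frac = data.smoothed[sample]
        ax.plot(bins, frac, color=c, label=sample)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(f"methylation bin ({data.bin_size} bp)")
    ax.set_ylabel("meth. fraction")
    ax.legend(frameon=False, fontsize=spec.fontsize)
    sns.despine(ax=ax)
    _save(fig, out, spec.dpi)
    return out


def plot_composite(
    profile: CompositeProfile,
    out: str,
    spec: Optional[PlotSpec] = None,
) -> str:
    """Consensus-space composite: pooled fraction plus per-element tracks.

    Ticks along the top mark motif sites on the consensus; element tracks
    show each retained copy's calls as closed/open dots.
    """
    spec = spec or PlotSpec()
    n_tracks = len(profile.element_tracks)
    fig, (ax0, ax1) = plt.subplots(
        2, 1, sharex=True, figsize=(spec.width, spec.height * 0.6),
        gridspec_kw={"height_ratios": (3, max(1, n_tracks))},
    )
    pooled = profile.pooled
    on = pooled[pooled["on_motif"]]
    ax0.plot(on["cons_pos"], on["fraction"], "-o", markersize=3,
             color=spec.color(0))
    for p in profile.motif_sites:
        ax0.plot(p, 1.06, marker="|", color="0.4", markersize=4, clip_on=False)
    ax0.set_ylim(-0.02, 1.02)
    ax0.set_ylabel(f"pooled fraction (n={profile.n_elements})",
                   fontsize=spec.fontsize)

    for row, (name, states) in enumerate(profile.element_tracks):
        y = -row
        ax1.plot([0, profile.consensus_length], [y, y], color="0.8",
                 linewidth=0.7)
        for cpos, state in sorted(states.items()):
            if state is CallState.AMBIG:
                ax1.plot(cpos, y, ".", color="0.6", markersize=2.5)
            else:
                ax1.plot(cpos, y, "o", markersize=3,
                         markeredgecolor=spec.color(0),
                         markerfacecolor=spec.color(0)
                         if state is CallState.MOD else "none")
        ax1.text(-0.01 * profile.consensus_length, y, name,
                 ha="right", va="center", fontsize=spec.fontsize)
    ax1.set_yticks([])
    ax1.set_xlim(0, profile.consensus_length)
    ax1.set_xlabel("consensus position (bp)")
    for ax in (ax0, ax1):
        sns.despine(ax=ax)
    _save(fig, out, spec.dpi)
    return out
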