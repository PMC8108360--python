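"""Constituent-enhancer definition, 12.5 kb stitching, and super-enhancer calling.

Constituent enhancers are H3K27ac peaks overlapping an H3K4me1 peak by at
least one nucleotide.  Constituents lying within the stitch distance
(12,500 bp by convention) are merged into stitched enhancers, which are then
ranked by total signal; the super-enhancer cutoff is the geometric "elbow" of
the rank/signal curve scaled to the unit square — the point where the curve's
slope reaches 1, found as the point minimising y - x (equivalent to the
first-slope>1 scan on convex curves, and robust to local rank noise).
Enhancers whose total signal lies strictly above the cutoff signal are
super-enhancers; the rest are typical enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import GenomicInterval, Peak, intersect_sets

__all__ = [
    "StitchedEnhancer",
    "SECall",
    "constituent_enhancers",
    "stitch",
    "rank_and_cut",
    "typical_enhancers",
    "super_enhancers",
]

DEFAULT_STITCH_DISTANCE = 12_500

CutRule = Literal["min_y_minus_x", "first_slope"]


@dataclass(frozen=True)
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: tuple[Peak, ...]
    total_signal: float

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("a stitched enhancer needs at least one constituent")
        if self.total_signal < 0:
            raise ValueError("total_signal must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass(frozen=True)
class SECall:
    enhancer: StitchedEnhancer
    rank: int  # 1-based, ascending total signal
    is_super: bool
    cutoff_signal: float


def constituent_enhancers(
    h3k27ac: Sequence[Peak],
    h3k4me1: Sequence[Peak],
) -> list[Peak]:
    """H3K27ac peaks overlapping >= 1 H3K4me1 peak by >= 1 bp, signals kept."""
    return intersect_sets(list(h3k27ac), h3k4me1)


def stitch(
    constituents: Sequence[Peak],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
) -> list[StitchedEnhancer]:
    """Greedily merge constituents within ``stitch_distance`` per chromosome.

    A peak is merged into the current stitched span when its start lies at
    most ``stitch_distance`` beyond the span's end (gap comparison inclusive:
    a gap of exactly 12,500 bp merges).  Total signal is the sum of the
    constituent signals.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    by_chrom: dict[str, list[Peak]] = {}
    for p in constituents:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: list[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        group: list[Peak] = []
        span_end = -1
        for p in peaks:
            if group and p.start - span_end > stitch_distance:
                out.append(_make_stitched(group))
                group = []
                span_end = -1
            group.append(p)
            span_end = max(span_end, p.end)
        if group:
            out.append(_make_stitched(group))
    return out


def _make_stitched(group: list[Peak]) -> StitchedEnhancer:
    chrom = group[0].chrom
    start = min(p.start for p in group)
    end = max(p.end for p in group)
    return StitchedEnhancer(
        interval=GenomicInterval(chrom, start, end),
        constituents=tuple(group),
        total_signal=float(sum(p.signal for p in group)),
    )


def rank_and_cut(
    stitched: Sequence[StitchedEnhancer],
    rule: CutRule = "min_y_minus_x",
) -> list[SECall]:
    """Rank stitched enhancers by signal and separate supers at the elbow.

    Signals and ranks are scaled to [0, 1]; the cutoff signal is taken at the
    elbow point (see module docstring) and enhancers strictly above it are
    super-enhancers.  A flat (all-equal) signal curve is the degenerate
    diagonal, which has no excess over the trend: zero super-enhancers and
    the cutoff at the maximum.  Ties in total signal are ranked in genomic
    order.  Requires at least 3 stitched enhancers.
    """
    n = len(stitched)
    if n < 3:
        raise ValueError("rank_and_cut requires at least 3 stitched enhancers")
    order = sorted(
        range(n),
        key=lambda i: (
            stitched[i].total_signal,
            stitched[i].chrom,
            stitched[i].interval.start,
            stitched[i].interval.end,
        ),
    )
    signals = np.array([stitched[i].total_signal for i in order], dtype=float)
    smin, smax = signals[0], signals[-1]
    if smax == smin:
        cutoff = float(smax)
    else:
        x = np.arange(n, dtype=float) / (n - 1)
        y = (signals - smin) / (smax - smin)
        if rule == "min_y_minus_x":
            idx = int(np.argmin(y - x))
        elif rule == "first_slope":
            slopes = np.diff(y) / np.diff(x)
            above = np.flatnonzero(slopes > 1.0)
            idx = int(above[0]) if above.size else n - 1
        else:
            raise ValueError(f"unknown cut rule {rule!r}")
        cutoff = float(signals[idx])
    calls = [
        SECall(
            enhancer=stitched[i],
            rank=rank,
            is_super=stitched[i].total_signal > cutoff,
            cutoff_signal=cutoff,
        )
        for rank, i in enumerate(order, start=1)
    ]
    calls.sort(key=lambda c: c.rank)
    return calls


def super_enhancers(calls: Sequence[SECall]) -> list[StitchedEnhancer]:
    return [c.enhancer for c in calls if c.is_super]


def typical_enhancers(calls: Sequence[SECall]) -> list[StitchedEnhancer]:
    """Complement of the super set; supers and typicals partition the input."""
    return [c.enhancer for c in calls if not c.is_super]


def plot_hockey_stick(calls: Sequence[SECall], path: str) -> None:
    """Rank-vs-signal plot with the cutoff marked (optional diagnostic PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranks = [c.rank for c in calls]
    signals = [c.enhancer.total_signal for c in calls]
    cutoff = calls[0].cutoff_signal if calls else 0.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ranks, signals, s=8, c=["tab:red" if c.is_super else "0.6" for c in calls])
    ax.axhline(cutoff, ls="--", lw=0.8, c="k")
    ax.set_xlabel("rank (ascending signal)")
    ax.set_ylabel("stitched enhancer signal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
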