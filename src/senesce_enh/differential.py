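"""Summit-centered differential enrichment scoring between two conditions.

For each peak the KO/WT enrichment ratio f(k) = enrichment_KO(k) /
enrichment_WT(k) is aggregated over all bins k covering the window
summit +- 15 kb.  Two aggregates are exposed:

* ``mean_of_ratios`` (default): Fc = (1/N) * sum_k (ko_k + eps) / (wt_k + eps)
  — the per-position ratio sum normalised by the number of bins, so the
  result is directly comparable to a fold-change cutoff regardless of window
  size;
* ``ratio_of_sums``: Fc = (sum_k ko_k + eps) / (sum_k wt_k + eps).

A region is called *up* (hyper-acetylated for H3K27ac) when log2(Fc) >= cutoff
and *down* (de-methylated for H3K27me3) when log2(Fc) <= -cutoff; the default
cutoff is |log2(Fc)| >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import Peak, SignalTrack

__all__ = [
    "DifferentialScore",
    "summit_ratio_score",
    "call_differential_regions",
    "split_by_mark",
]

Mode = Literal["mean_of_ratios", "ratio_of_sums"]
Call = Literal["up", "down", "unchanged"]


@dataclass(frozen=True)
class DifferentialScore:
    peak: Peak
    window_bp: int
    fc: float
    log2fc: float
    n_bins: int
    call: Call

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fc must be positive")


def _assign_call(log2fc: float, cutoff: float) -> Call:
    if log2fc >= cutoff:
        return "up"
    if log2fc <= -cutoff:
        return "down"
    return "unchanged"


def summit_ratio_score(
    peak: Peak,
    track_ko: SignalTrack,
    track_wt: SignalTrack,
    window_bp: int = 15_000,
    pseudocount: float = 1.0,
    mode: Mode = "mean_of_ratios",
    cutoff: float = 1.0,
) -> DifferentialScore:
    """Score one peak on the bins covering ``[summit - w, summit + w]``.

    The window is clipped at chromosome boundaries and ``n_bins`` reflects the
    bins actually summed.  Both tracks must share bin width and chromosomes.
    """
    if track_ko.bin_width != track_wt.bin_width:
        raise ValueError("tracks must share bin_width")
    if window_bp < track_ko.bin_width:
        raise ValueError("window_bp must be at least one bin wide")
    if peak.chrom not in track_ko.values or peak.chrom not in track_wt.values:
        raise KeyError(f"chromosome {peak.chrom!r} absent from a track")
    if mode not in ("mean_of_ratios", "ratio_of_sums"):
        raise ValueError(f"unknown mode {mode!r}")

    # closed window [summit - w, summit + w] expressed half-open
    start = peak.summit - window_bp
    end = peak.summit + window_bp + 1
    ko = track_ko.window_values(peak.chrom, start, end)
    wt = track_wt.window_values(peak.chrom, start, end)
    n_bins = int(ko.size)
    eps = float(pseudocount)
    if mode == "mean_of_ratios":
        fc = float(np.mean((ko + eps) / (wt + eps)))
    else:
        fc = float((ko.sum() + eps) / (wt.sum() + eps))
    log2fc = float(np.log2(fc))
    return DifferentialScore(
        peak=peak,
        window_bp=window_bp,
        fc=fc,
        log2fc=log2fc,
        n_bins=n_bins,
        call=_assign_call(log2fc, cutoff),
    )


def call_differential_regions(
    peaks: Sequence[Peak],
    track_ko: SignalTrack,
    track_wt: SignalTrack,
    cutoff: float = 1.0,
    window_bp: int = 15_000,
    pseudocount: float = 1.0,
    mode: Mode = "mean_of_ratios",
) -> list[DifferentialScore]:
    """Score every peak and sort by |log2fc| descending (ties: genomic order)."""
    scores = [
        summit_ratio_score(
            p, track_ko, track_wt,
            window_bp=window_bp, pseudocount=pseudocount, mode=mode, cutoff=cutoff,
        )
        for p in peaks
    ]
    scores.sort(
        key=lambda s: (-abs(s.log2fc), s.peak.chrom, s.peak.start, s.peak.end)
    )
    return scores


def split_by_mark(
    scores: Sequence[DifferentialScore],
    mark: Literal["H3K27ac", "H3K27me3"],
) -> tuple[list[DifferentialScore], list[DifferentialScore]]:
    """Partition non-unchanged scores into the biologically gained/lost sets.

    For H3K27ac the *up* set is the hyper-acetylated one; for H3K27me3 the
    *down* set is the de-methylated one.  Returns ``(up_set, down_set)``.
    """
    if mark not in ("H3K27ac", "H3K27me3"):
        raise ValueError(f"unknown mark {mark!r}")
    up = [s for s in scores if s.call == "up"]
    down = [s for s in scores if s.call == "down"]
    return up, down
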