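"""Genomic coordinate conventions, interval/peak data model and BED-family I/O.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` has length ``end - start`` and two abutting intervals do not
overlap.  Strand is carried for annotation purposes but ignored by all overlap
arithmetic, since ChIP enrichment is unstranded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "overlaps",
    "overlap_length",
    "intersect_sets",
    "replicate_overlap_fraction",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "build_interval_trees",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """An enriched region with a summit (position of maximal signal).

    The summit anchors every windowed analysis downstream (the differential
    statistic is computed on summit +- 15 kb).
    """

    interval: GenomicInterval
    summit: int
    signal: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def with_signal(self, signal: float) -> "Peak":
        return replace(self, signal=signal)


class SignalTrack:
    """Binned, non-negative enrichment coverage for one sample.

    Per chromosome an array of ``ceil(length / bin_width)`` bins; bin *i*
    covers bases ``[i * bin_width, (i + 1) * bin_width)``.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        bin_width: int,
        values: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        if bin_width <= 0:
            raise ValueError("bin_width must be a positive integer")
        self.chrom_lengths = dict(chrom_lengths)
        self.bin_width = int(bin_width)
        self.values: dict[str, np.ndarray] = {}
        for chrom, length in self.chrom_lengths.items():
            n = self.n_bins(chrom)
            if values is not None and chrom in values:
                arr = np.asarray(values[chrom], dtype=float)
                if arr.shape != (n,):
                    raise ValueError(
                        f"{chrom}: expected {n} bins for length {length}, got {arr.shape}"
                    )
                if np.any(arr < 0):
                    raise ValueError(f"{chrom}: negative enrichment values")
                self.values[chrom] = arr
            else:
                self.values[chrom] = np.zeros(n, dtype=float)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_width)

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values of the bins intersecting ``[start, end)``, clipped at bounds."""
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} absent from track")
        start = max(0, start)
        end = min(self.chrom_lengths[chrom], end)
        if end <= start:
            return np.empty(0, dtype=float)
        lo = start // self.bin_width
        hi = (end - 1) // self.bin_width + 1
        return self.values[chrom][lo:hi]

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.chrom_lengths,
            self.bin_width,
            {c: v.copy() for c, v in self.values.items()},
        )

    def to_bedgraph(self, path: str | Path) -> None:
        """Write fixed-width bins as 4-column bedGraph text.

        Runs of equal-valued consecutive bins are merged into one line; float
        values are printed at full precision so a round-trip is exact.
        """
        path = Path(path)
        with path.open("w") as fh:
            for chrom in sorted(self.chrom_lengths):
                arr = self.values[chrom]
                length = self.chrom_lengths[chrom]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{s * self.bin_width}"
                        f"\t{min(e * self.bin_width, length)}\t{float(arr[s])!r}\n"
                    )

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        chrom_lengths: Mapping[str, int],
        bin_width: int,
    ) -> "SignalTrack":
        track = cls(chrom_lengths, bin_width)
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                chrom, start, end, value = parts
                start, end = int(start), int(end)
                if start % bin_width:
                    raise ValueError(
                        f"{path}:{lineno}: interval not aligned to {bin_width} bp bins"
                    )
                lo = start // bin_width
                hi = (end - 1) // bin_width + 1
                track.values[chrom][lo:hi] = float(value)
        return track


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases.

    With the default ``min_bp=1`` this is the "overlap of at least one
    nucleotide" criterion used for all peak/atlas intersections.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def build_interval_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _as_interval(x: GenomicInterval | Peak) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


def intersect_sets(
    a: Sequence[Peak],
    b: Iterable[GenomicInterval | Peak],
) -> list[Peak]:
    """Order-preserving subset of ``a`` overlapping (>= 1 bp) any interval of ``b``."""
    trees = build_interval_trees(_as_interval(x) for x in b)
    out = []
    for peak in a:
        tree = trees.get(peak.chrom)
        if tree is not None and tree.overlap(peak.start, peak.end):
            out.append(peak)
    return out


def replicate_overlap_fraction(rep1: Sequence[Peak], rep2: Sequence[Peak]) -> float:
    """Fraction of peaks of the smaller replicate overlapping the other (>= 1 bp).

    Replicate QC passes when the fraction is at least 0.27.
    """
    if not rep1 or not rep2:
        raise ValueError("replicate peak sets must be non-empty")
    small, big = (rep1, rep2) if len(rep1) <= len(rep2) else (rep2, rep1)
    return len(intersect_sets(list(small), big)) / len(small)


def read_bed(path: str | Path, with_summit: bool = False) -> list[Peak]:
    """Read BED3/BED6/narrowPeak-style tab-separated text into peaks.

    Summit resolution: a 7-column file (our BED6+summit flavour) or a
    10-column narrowPeak carries the summit as an offset from ``start``
    (narrowPeak ``-1`` means unknown); otherwise, or when the offset is
    unknown, the summit defaults to the interval midpoint (floor).
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if not 3 <= len(parts) <= 10:
                raise ValueError(f"{path}:{lineno}: expected 3-10 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
            signal = 0.0
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    signal = float(parts[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed score") from exc
            strand = parts[5] if len(parts) > 5 and parts[5] in _VALID_STRANDS else "."
            summit = (start + end) // 2
            offset = None
            if len(parts) == 7:
                offset = int(parts[6])
            elif len(parts) == 10:
                offset = int(parts[9])
            if offset is not None and offset >= 0:
                summit = start + offset
            interval = GenomicInterval(chrom, start, end, strand)
            peaks.append(Peak(interval, summit, max(signal, 0.0), name))
    # with_summit only documents intent: a missing summit column falls back to
    # the midpoint either way, so summits are always populated
    del with_summit
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6+summit (summit as offset from start), no header."""
    path = Path(path)
    with path.open("w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{float(p.signal)!r}"
                f"\t{p.interval.strand}\t{p.summit - p.start}\n"
            )


def write_intervals_bed(
    intervals: Sequence[GenomicInterval], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    return [p.interval for p in read_bed(path)]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
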