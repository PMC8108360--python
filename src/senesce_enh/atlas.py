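"""Senescence enhancer atlas construction and genomic-element enrichment.

The senescence super-enhancer atlas (SES) is the union of SE interval sets
from independent senescence studies.  Genomic element classes (SES, SESM,
TES, promoter, exon, intron, intergenic) are made mutually exclusive by a
precedence order: a lower-precedence class is clipped by everything above it,
so every base pair belongs to at most one class.  Regions are assigned to the
class containing their summit, and per-class enrichment is the observed
fraction of regions divided by the fraction of the genome the class covers.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, Peak, build_interval_trees

__all__ = [
    "ElementAtlas",
    "EnrichmentRow",
    "HUMAN_FEMALE_GENOME_LENGTH",
    "DEFAULT_PRECEDENCE",
    "merge_intervals",
    "subtract_interval_sets",
    "total_bp",
    "build_ses_atlas",
    "resolve_classes",
    "assign_regions",
    "element_enrichment",
    "closest_active_gene",
    "promoter_intervals",
    "atlas_overlap_fraction",
    "round_half_up_percent",
]

#: Length of the female haploid human genome, used as the coverage
#: denominator when real human coordinates are analysed.  Synthetic runs use
#: the generated genome size instead.
HUMAN_FEMALE_GENOME_LENGTH = 3_184_709_445

#: Highest precedence first; the enhancer classes are the objects of study
#: and therefore clip the gene-model classes.
DEFAULT_PRECEDENCE = (
    "SES",
    "SESM",
    "TES",
    "promoter",
    "exon",
    "intron",
    "intergenic",
)


def _to_arrays(
    intervals: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Per-chromosome (n, 2) arrays of merged, sorted half-open intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:  # overlapping or adjacent
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _from_arrays(arrays: Mapping[str, np.ndarray]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for chrom in sorted(arrays):
        for s, e in arrays[chrom]:
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals with overlapping/adjacent spans merged, sorted."""
    return _from_arrays(_to_arrays(intervals))


def _subtract_arrays(
    a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom, spans in a.items():
        cuts = b.get(chrom)
        if cuts is None or cuts.size == 0:
            out[chrom] = spans.copy()
            continue
        kept: list[tuple[int, int]] = []
        for s, e in spans:
            cur = int(s)
            for cs, ce in cuts:
                if ce <= cur:
                    continue
                if cs >= e:
                    break
                if cs > cur:
                    kept.append((cur, int(min(cs, e))))
                cur = max(cur, int(ce))
                if cur >= e:
                    break
            if cur < e:
                kept.append((cur, int(e)))
        out[chrom] = (
            np.asarray(kept, dtype=np.int64) if kept else np.empty((0, 2), np.int64)
        )
    return out


def subtract_interval_sets(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base pairs of ``a`` not covered by ``b`` (both merged first)."""
    return _from_arrays(_subtract_arrays(_to_arrays(a), _to_arrays(b)))


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Non-redundant base pairs covered (intervals are merged first)."""
    arrays = _to_arrays(intervals)
    return int(sum((a[:, 1] - a[:, 0]).sum() for a in arrays.values()))


def build_ses_atlas(
    se_sets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Union of super-enhancer interval sets into one merged, sorted atlas."""
    if not se_sets:
        raise ValueError("need at least one SE interval set")
    all_ivs = [iv for s in se_sets for iv in s]
    return merge_intervals(all_ivs)


@dataclass
class ElementAtlas:
    """Mutually disjoint genomic element classes with coverage bookkeeping."""

    classes: dict[str, list[GenomicInterval]]  # in precedence order
    chrom_lengths: dict[str, int]
    genome_length: int
    coverage: dict[str, int]

    def class_labels(self) -> list[str]:
        return list(self.classes)


def resolve_classes(
    raw: Mapping[str, Sequence[GenomicInterval]],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    chrom_lengths: Mapping[str, int] | None = None,
    genome_length: int | None = None,
) -> ElementAtlas:
    """Clip each class by all higher-precedence classes so no bp is shared.

    ``intergenic``, when listed in the precedence but absent from ``raw``, is
    computed as the genomic complement of all other classes (requires
    ``chrom_lengths``).  ``genome_length`` defaults to the sum of chromosome
    lengths.
    """
    labels = list(precedence)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in precedence")
    missing = set(raw) - set(labels)
    if missing:
        raise ValueError(f"precedence does not cover classes: {sorted(missing)}")
    if chrom_lengths is None:
        raise ValueError("chrom_lengths is required to resolve an atlas")
    chrom_lengths = dict(chrom_lengths)
    if genome_length is None:
        genome_length = int(sum(chrom_lengths.values()))

    resolved: dict[str, dict[str, np.ndarray]] = {}
    occupied: dict[str, np.ndarray] = {}
    for label in labels:
        if label == "intergenic" and label not in raw:
            arrays = _to_arrays(
                GenomicInterval(c, 0, ln) for c, ln in chrom_lengths.items()
            )
        else:
            arrays = _to_arrays(raw.get(label, []))
        arrays = _subtract_arrays(arrays, occupied)
        resolved[label] = arrays
        # extend the occupied mask
        merged: dict[str, list[np.ndarray]] = {}
        for src in (occupied, arrays):
            for chrom, spans in src.items():
                merged.setdefault(chrom, []).append(spans)
        occupied = _to_arrays(
            GenomicInterval(chrom, int(s), int(e))
            for chrom, parts in merged.items()
            for arr in parts
            for s, e in arr
            if e > s
        )

    classes = {label: _from_arrays(resolved[label]) for label in labels}
    coverage = {
        label: int(sum((a[:, 1] - a[:, 0]).sum() for a in resolved[label].values()))
        for label in labels
    }
    if sum(coverage.values()) > genome_length:
        raise ValueError("resolved coverages exceed the genome length")
    return ElementAtlas(
        classes=classes,
        chrom_lengths=chrom_lengths,
        genome_length=genome_length,
        coverage=coverage,
    )


def assign_regions(
    regions: Sequence[Peak],
    atlas: ElementAtlas,
) -> dict[str, list[Peak]]:
    """Assign each region to the single class containing its summit.

    Classes are disjoint after resolution, so at most one class matches; a
    summit in no class falls into ``intergenic``.
    """
    lookup: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for label, ivs in atlas.classes.items():
        arrays = _to_arrays(ivs)
        lookup[label] = {
            c: (a[:, 0].copy(), a[:, 1].copy()) for c, a in arrays.items()
        }
    assigned: dict[str, list[Peak]] = {label: [] for label in atlas.classes}
    assigned.setdefault("intergenic", [])
    for region in regions:
        hit = None
        for label, per_chrom in lookup.items():
            se = per_chrom.get(region.chrom)
            if se is None:
                continue
            starts, ends = se
            i = int(np.searchsorted(starts, region.summit, side="right")) - 1
            if i >= 0 and region.summit < ends[i]:
                hit = label
                break
        assigned[hit if hit is not None else "intergenic"].append(region)
    return assigned


@dataclass(frozen=True)
class EnrichmentRow:
    label: str
    n_regions: int
    observed_frac: float
    expected_frac: float
    fold: float  # inf flagged as float("inf") when expected_frac == 0


def element_enrichment(
    assigned: Mapping[str, Sequence[Peak]],
    atlas: ElementAtlas,
) -> list[EnrichmentRow]:
    """Observed/expected fold per class, expected from genome coverage.

    Classes with zero coverage and zero regions are omitted; zero coverage
    with regions assigned yields an infinite fold flag.
    """
    n_total = sum(len(v) for v in assigned.values())
    if n_total == 0:
        raise ValueError("no regions assigned")
    rows: list[EnrichmentRow] = []
    labels = list(atlas.classes)
    for extra in assigned:
        if extra not in labels:
            labels.append(extra)
    unaccounted = atlas.genome_length - sum(atlas.coverage.values())
    for label in labels:
        n = len(assigned.get(label, []))
        cov = atlas.coverage.get(label)
        if cov is None:
            # implicit complement class (summits falling in no resolved class)
            cov = max(unaccounted, 0)
        if cov == 0 and n == 0:
            continue
        observed = n / n_total
        expected = cov / atlas.genome_length
        fold = observed / expected if expected > 0 else float("inf")
        rows.append(
            EnrichmentRow(
                label=label,
                n_regions=n,
                observed_frac=observed,
                expected_frac=expected,
                fold=fold,
            )
        )
    return rows


def promoter_intervals(
    genes: pd.DataFrame,
    window: int = 2_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """TSS +- window per gene, clipped at chromosome bounds (not merged).

    ``genes`` needs columns ``chrom`` and ``tss``.
    """
    out: list[GenomicInterval] = []
    for chrom, tss in zip(genes["chrom"], genes["tss"]):
        start = max(0, int(tss) - window)
        end = int(tss) + window
        if chrom_lengths is not None:
            end = min(end, int(chrom_lengths[chrom]))
        if end > start:
            out.append(GenomicInterval(str(chrom), start, end))
    return out


def closest_active_gene(
    se: GenomicInterval,
    genes: pd.DataFrame,
    active_genes: set[str],
) -> tuple[str, int]:
    """Nearest active gene by TSS distance ("closest active" association).

    Distance is 0 when the TSS lies inside the SE.  Ties prefer the smaller
    TSS coordinate, then the lexicographically smaller gene id.  Returns
    ``("unassigned", -1)`` when the SE's chromosome has no active gene.

    ``genes`` needs columns ``gene``, ``chrom``, ``tss``.
    """
    sub = genes[(genes["chrom"] == se.chrom) & genes["gene"].isin(active_genes)]
    if sub.empty:
        return "unassigned", -1
    best: tuple[int, int, str] | None = None
    for gene, tss in zip(sub["gene"], sub["tss"]):
        tss = int(tss)
        if se.start <= tss < se.end:
            d = 0
        elif tss < se.start:
            d = se.start - tss
        else:
            d = tss - (se.end - 1)
        key = (d, tss, str(gene))
        if best is None or key < best:
            best = key
    return best[2], best[0]


def atlas_overlap_fraction(
    query: Sequence[GenomicInterval | Peak],
    atlas_class: Sequence[GenomicInterval | Peak],
) -> tuple[int, float]:
    """Count and fraction of query intervals overlapping the class by >= 1 bp."""
    if not query:
        raise ValueError("query interval set is empty")
    trees = build_interval_trees(
        x.interval if isinstance(x, Peak) else x for x in atlas_class
    )
    n = 0
    for q in query:
        iv = q.interval if isinstance(q, Peak) else q
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            n += 1
    return n, n / len(query)


def round_half_up_percent(numerator: float, denominator: float) -> int:
    """Integer percentage with half-up rounding (142/230 -> 62)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(floor(100.0 * numerator / denominator + 0.5))
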