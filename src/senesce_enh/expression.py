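"""DEG calling, cross-clone consensus signature and active-gene table.

A gene is differentially expressed in one comparison (e.g. one knockout
clone vs control) when |fold change| > 2 and adjusted p < 0.05, both strict.
The consensus signature is the set of genes called in *every* comparison
with a consistent direction; its induced fraction is the percentage of
consensus genes whose fold change is positive (142 up of 230 -> 62%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import round_half_up_percent

__all__ = [
    "DEGConsensus",
    "read_expression_table",
    "call_degs",
    "consensus_signature",
    "induced_fraction",
    "active_gene_table",
    "DEFAULT_FC_CUTOFF",
    "DEFAULT_P_CUTOFF",
]

DEFAULT_FC_CUTOFF = 2.0
DEFAULT_P_CUTOFF = 0.05

REQUIRED_COLUMNS = ("gene", "comparison", "fold_change")


@dataclass(frozen=True)
class DEGConsensus:
    """Per-comparison DEG sets and their direction-consistent intersection."""

    per_comparison: dict[str, dict[str, int]]  # comparison -> {gene: +1/-1}
    consensus: dict[str, int]  # gene -> +1 (induced) / -1 (repressed)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.consensus.values() if d > 0)

    @property
    def n_total(self) -> int:
        return len(self.consensus)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns gene, comparison, fold_change, p_adj (or p)."""
    df = pd.read_csv(path, sep="\t")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    return df


def _ensure_p_adj(records: pd.DataFrame) -> pd.DataFrame:
    """Use p_adj as given; fall back to per-comparison Benjamini-Hochberg."""
    if "p_adj" in records.columns:
        return records
    if "p" not in records.columns:
        raise ValueError("expression table needs a p_adj or p column")
    records = records.copy()
    records["p_adj"] = np.nan
    for _, idx in records.groupby("comparison").groups.items():
        _, adj, _, _ = multipletests(records.loc[idx, "p"], method="fdr_bh")
        records.loc[idx, "p_adj"] = adj
    return records


def call_degs(
    records: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> dict[str, dict[str, int]]:
    """DEG set per comparison: |fold_change| > fc_cutoff and p_adj < p_cutoff.

    Both inequalities are strict.  Fold changes are signed linear ratios
    (negative = repressed); direction is their sign.  Duplicate
    (gene, comparison) rows are an error.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    if records.duplicated(subset=["gene", "comparison"]).any():
        dupes = records[records.duplicated(subset=["gene", "comparison"])]
        raise ValueError(
            f"duplicate (gene, comparison) rows, e.g. {dupes.iloc[0]['gene']!r}"
        )
    if (records["fold_change"] == 0).any():
        raise ValueError("fold_change must be non-zero")
    records = _ensure_p_adj(records)
    hit = (records["fold_change"].abs() > fc_cutoff) & (records["p_adj"] < p_cutoff)
    out: dict[str, dict[str, int]] = {
        str(c): {} for c in records["comparison"].unique()
    }
    for _, row in records[hit].iterrows():
        out[str(row["comparison"])][str(row["gene"])] = (
            1 if row["fold_change"] > 0 else -1
        )
    return out


def consensus_signature(
    per_comparison: Mapping[str, Mapping[str, int]],
) -> DEGConsensus:
    """Genes DEG in every comparison with the same direction everywhere."""
    if len(per_comparison) < 2:
        raise ValueError("consensus requires at least 2 comparisons")
    comparisons = list(per_comparison)
    shared = set(per_comparison[comparisons[0]])
    for c in comparisons[1:]:
        shared &= set(per_comparison[c])
    consensus: dict[str, int] = {}
    for gene in shared:
        directions = {per_comparison[c][gene] for c in comparisons}
        if len(directions) == 1:
            consensus[gene] = directions.pop()
    return DEGConsensus(
        per_comparison={c: dict(v) for c, v in per_comparison.items()},
        consensus=consensus,
    )


def induced_fraction(consensus: DEGConsensus) -> int:
    """Induced percentage of the consensus signature, half-up rounded."""
    if consensus.n_total == 0:
        raise ValueError("consensus signature is empty")
    return round_half_up_percent(consensus.n_up, consensus.n_total)


def active_gene_table(
    records: pd.DataFrame,
    rule: str = "median",
    threshold: float | None = None,
) -> set[str]:
    """Genes considered transcriptionally active (for closest-active lookup).

    ``rule="median"`` (default): baseline expression at or above the median
    baseline over genes (all-equal baselines therefore mean every gene is
    active).  ``rule="threshold"``: baseline >= ``threshold``.  A boolean
    ``active`` column, when present, wins over either rule.
    """
    if "active" in records.columns:
        sub = records[["gene", "active"]].drop_duplicates("gene")
        return set(sub[sub["active"].astype(bool)]["gene"].astype(str))
    if "baseline" not in records.columns:
        raise ValueError("expression table lacks a baseline column")
    base = records[["gene", "baseline"]].drop_duplicates("gene")
    if rule == "median":
        cut = float(base["baseline"].median())
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("rule='threshold' needs a threshold value")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown activity rule {rule!r}")
    return set(base[base["baseline"] >= cut]["gene"].astype(str))
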