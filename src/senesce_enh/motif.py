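"""Known-motif PWM scanning and target-vs-background enrichment.

Sequences are scanned on both strands with a log-odds position weight matrix
(bits, log2(p/background)); a window is a hit when its score reaches the
PWM's threshold (default: 80% of the maximal achievable log-odds).
Enrichment is region-level — a region counts once if it carries >= 1 hit —
and tested with a one-sided hypergeometric test on the 2x2 target/background
table; a motif is significant below p = 0.5e-4.

``N`` bases contribute a log-odds of 0 (they score as background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PWM",
    "MotifHit",
    "MotifEnrichment",
    "scan_pwm",
    "motif_enrichment",
    "builtin_motifs",
    "ap1_pwm",
    "nfkb_pwm",
    "read_meme_motifs",
    "MOTIF_P_THRESHOLD",
]

MOTIF_P_THRESHOLD = 0.5e-4

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC code -> base probability row used to build consensus PWMs.
_IUPAC = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "T": (0, 0, 0, 1),
    "R": (0.5, 0, 0.5, 0),
    "Y": (0, 0.5, 0, 0.5),
    "S": (0, 0.5, 0.5, 0),
    "W": (0.5, 0, 0, 0.5),
    "N": (0.25, 0.25, 0.25, 0.25),
}


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with a log-odds scan threshold.

    ``matrix`` is (length, 4) over A/C/G/T; each row sums to 1.  The
    threshold is in bits; when None it defaults to 80% of the maximal
    achievable log-odds score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("matrix must be (length >= 4, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 5) log2(p/bg) with -inf for zero-probability bases.

        The 5th column (index 4) is the ``N`` column, fixed at 0.
        """
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background)
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def effective_threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return 0.8 * self.max_score


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based on the forward strand (leftmost base of the site)
    strand: str  # "+" or "-"
    score: float


@dataclass(frozen=True)
class MotifEnrichment:
    motif: str
    n_target_hit: int
    n_target: int
    n_bg_hit: int
    n_bg: int
    p_value: float
    significant: bool


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)  # default: N
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _scan_strand(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Scores of every window on one strand (vectorised sliding window)."""
    L = log_odds.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return log_odds[np.arange(L), windows].sum(axis=1)


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def scan_pwm(sequence: str, pwm: PWM) -> list[MotifHit]:
    """All windows on both strands scoring at or above the PWM threshold.

    Positions are 0-based, referring to the leftmost base of the site on the
    forward strand for both orientations.  A sequence shorter than the motif
    yields no hits.
    """
    L = len(pwm)
    if len(sequence) < L:
        return []
    threshold = pwm.effective_threshold
    lo = pwm.log_odds
    fwd_codes = _encode(sequence)
    rev_codes = _encode(reverse_complement(sequence))
    hits: list[MotifHit] = []
    fwd = _scan_strand(fwd_codes, lo)
    for pos in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(int(pos), "+", float(fwd[pos])))
    rev = _scan_strand(rev_codes, lo)
    n = len(sequence)
    for pos in np.flatnonzero(rev >= threshold):
        hits.append(MotifHit(int(n - L - pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def has_hit(sequence: str, pwm: PWM) -> bool:
    return bool(scan_pwm(sequence, pwm))


def motif_enrichment(
    targets: Sequence[str],
    background: Sequence[str],
    pwm: PWM,
    alpha: float = MOTIF_P_THRESHOLD,
) -> MotifEnrichment:
    """Region-level one-sided hypergeometric enrichment of a motif.

    The population is all regions, of which ``K`` carry >= 1 hit; the p-value
    is the probability of drawing at least the observed number of hit regions
    in a sample of ``len(targets)`` regions.
    """
    if not targets or not background:
        raise ValueError("target and background sets must be non-empty")
    k_t = sum(has_hit(s, pwm) for s in targets)
    k_b = sum(has_hit(s, pwm) for s in background)
    n_t, n_b = len(targets), len(background)
    # P(X >= k_t), X ~ Hypergeom(N = n_t + n_b, K = k_t + k_b, n = n_t)
    p = float(stats.hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return MotifEnrichment(
        motif=pwm.name,
        n_target_hit=int(k_t),
        n_target=n_t,
        n_bg_hit=int(k_b),
        n_bg=n_b,
        p_value=p,
        significant=bool(p < alpha),
    )


def consensus_pwm(name: str, consensus: str) -> PWM:
    """Build a PWM from an IUPAC consensus string (exact-probability rows)."""
    rows = []
    for c in consensus.upper():
        if c not in _IUPAC:
            raise ValueError(f"unsupported IUPAC code {c!r}")
        rows.append(_IUPAC[c])
    return PWM(name=name, matrix=np.asarray(rows, dtype=float))


def ap1_pwm() -> PWM:
    """AP-1 (JUN/FOS) TPA-response element, consensus TGA(C/G)TCA."""
    return consensus_pwm("AP-1", "TGASTCA")


def nfkb_pwm() -> PWM:
    """NF-kB consensus GGGRNNYYCC."""
    return consensus_pwm("NFKB", "GGGRNNYYCC")


def builtin_motifs() -> list[PWM]:
    """The two senescence-enhancer motifs shipped with the package."""
    return [ap1_pwm(), nfkb_pwm()]


def read_meme_motifs(path: str | Path) -> list[PWM]:
    """Read motifs from a MEME minimal-format file (via Biopython)."""
    from Bio import motifs as bio_motifs

    with Path(path).open() as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        counts = np.array(
            [[rec.counts[b][i] for b in _BASES] for i in range(rec.length)],
            dtype=float,
        )
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.array([rec.background[b] for b in _BASES], dtype=float)
        out.append(PWM(name=rec.name or rec.consensus, matrix=probs, background=bg))
    return out
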