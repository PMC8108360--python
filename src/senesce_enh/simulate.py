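"""Single-seed synthetic epigenome generator.

Emulates the data structure of a paired WT/KO H3K27 ChIP-seq + expression
study on a small genome: coverage tracks with locus-specific planted fold
changes at summit-centered windows, peak sets with controllable replicate
overlap, enhancer constituents organised into stitched units with planted
super-enhancers, an interval atlas with SES/TES/SESM classes, genes with
active/inactive expression states and planted DEGs shared across two
knockout clones, and motif-bearing region sequences.

Layout: each chromosome is divided into equal blocks, one differential-
statistic peak per block (so summit +- 15 kb scoring windows never overlap
each other), plus one auxiliary slot per block allocated deterministically
to enhancer units, lineage (SESM) intervals, extra HDAC4 peaks, or
replicate-unique peaks.  All randomness flows from ``config.seed`` through a
single generator, so a given config is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    Peak,
    SignalTrack,
    write_bed,
    write_chrom_sizes,
    write_intervals_bed,
)

__all__ = ["SimConfig", "SyntheticDataset", "generate", "emit_files"]

AP1_SITES = ("TGACTCA", "TGAGTCA")  # the two TGA(C/G)TCA variants


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    bin_width: int = 50
    # differential statistic universe
    n_peaks: int = 400
    frac_differential: float = 0.25
    planted_log2fc: float = 2.0
    noise_cv: float = 0.2
    window_bp: int = 15_000
    baseline_enrichment: float = 10.0
    # enhancer / super-enhancer universe
    n_enhancers: int = 300
    n_se_planted: int = 15
    se_signal_multiplier: float = 6.0
    # genes and expression
    n_genes: int = 1_000
    frac_active_genes: float = 0.5
    n_deg_planted: int = 40
    deg_induced_frac: float = 0.6
    # motif regions
    n_motif_regions: int = 100
    motif_frac_target: float = 0.5
    motif_frac_background: float = 0.05
    # replicates
    n_replicate_peaks: int = 60
    replicate_shared_frac: float = 0.5
    # atlas classes
    n_ses_atlas: int = 60
    n_tes_atlas: int = 50
    n_sesm_atlas: int = 20
    n_hdac4_extra: int = 15

    def __post_init__(self) -> None:
        fracs = {
            "frac_differential": self.frac_differential,
            "frac_active_genes": self.frac_active_genes,
            "motif_frac_target": self.motif_frac_target,
            "motif_frac_background": self.motif_frac_background,
            "replicate_shared_frac": self.replicate_shared_frac,
            "deg_induced_frac": self.deg_induced_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        counts = {
            "n_chroms": self.n_chroms,
            "n_peaks": self.n_peaks,
            "n_enhancers": self.n_enhancers,
            "n_se_planted": self.n_se_planted,
            "n_genes": self.n_genes,
            "n_deg_planted": self.n_deg_planted,
            "n_motif_regions": self.n_motif_regions,
            "n_replicate_peaks": self.n_replicate_peaks,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.chrom_length < 10 * self.bin_width:
            raise ValueError("chrom_length must be at least 10 bins")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.se_signal_multiplier <= 1:
            raise ValueError("se_signal_multiplier must exceed 1")
        if self.n_se_planted > self.n_enhancers:
            raise ValueError("planted super-enhancers exceed stitched units")
        if self.n_deg_planted > self.n_genes:
            raise ValueError("planted DEGs exceed gene count")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class SyntheticDataset:
    config: SimConfig
    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # gene, chrom, start, end, tss, strand
    exons: list[GenomicInterval]
    atlas: dict[str, list[GenomicInterval]]  # SES / TES / SESM
    peaks_wt: list[Peak]
    peaks_ko: list[Peak]
    peaks_wt_rep1: list[Peak]
    peaks_wt_rep2: list[Peak]
    h3k27ac_enhancers: list[Peak]
    h3k4me1_peaks: list[Peak]
    hdac4_peaks: list[Peak]
    track_wt: SignalTrack
    track_ko: SignalTrack
    expression: pd.DataFrame  # gene, comparison, baseline, fold_change, p_adj
    sequences: dict[str, str]
    truth: dict


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    seq = "".join(rng.choice(list("ACGT"), size=n))
    # scrub spontaneous AP-1 consensus so planted motif truth is exact
    # (the two variants are reverse complements, so this covers both strands)
    while True:
        pos = min(
            (seq.find(s) for s in AP1_SITES if seq.find(s) >= 0),
            default=-1,
        )
        if pos < 0:
            return seq
        seq = seq[:pos] + "".join(rng.choice(list("ACGT"), size=7)) + seq[pos + 7 :]


def _plant_ap1(rng: np.random.Generator, seq: str) -> tuple[str, int]:
    site = AP1_SITES[int(rng.integers(2))]
    offset = int(rng.integers(0, len(seq) - len(site) + 1))
    return seq[:offset] + site + seq[offset + len(site) :], offset


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate(config: SimConfig) -> SyntheticDataset:
    """Build the full synthetic dataset; deterministic for a given config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom_lengths = cfg.chrom_lengths
    chroms = list(chrom_lengths)

    # ----- block layout -------------------------------------------------
    base, extra = divmod(cfg.n_peaks, cfg.n_chroms)
    peaks_per_chrom = {
        c: base + (1 if i < extra else 0) for i, c in enumerate(chroms)
    }
    blocks: list[tuple[str, int, int]] = []  # (chrom, block_start, block_size)
    for c in chroms:
        n_c = peaks_per_chrom[c]
        if n_c == 0:
            continue
        bsize = cfg.chrom_length // n_c
        if bsize < 2 * cfg.window_bp + 2_000:
            raise ValueError(
                "infeasible config: peaks too dense for non-overlapping "
                f"summit windows (block {bsize} bp < {2 * cfg.window_bp + 2000} bp)"
            )
        for i in range(n_c):
            blocks.append((c, i * bsize, bsize))
    n_blocks = len(blocks)

    n_rep_shared = round(cfg.replicate_shared_frac * cfg.n_replicate_peaks)
    n_rep_unique = cfg.n_replicate_peaks - n_rep_shared
    n_slots_needed = (
        cfg.n_enhancers + cfg.n_sesm_atlas + cfg.n_hdac4_extra + 2 * n_rep_unique
    )
    if n_slots_needed > n_blocks:
        raise ValueError(
            f"infeasible config: {n_slots_needed} auxiliary features "
            f"but only {n_blocks} blocks"
        )
    if cfg.n_replicate_peaks > cfg.n_peaks:
        raise ValueError("replicate peak count exceeds peak count")

    # ----- differential peaks -------------------------------------------
    peak_ivs: list[GenomicInterval] = []
    summits: list[int] = []
    for chrom, bstart, bsize in blocks:
        width = int(rng.integers(600, 1601))
        center = bstart + int(0.30 * bsize) + int(rng.integers(-1000, 1001))
        start = max(0, center - width // 2)
        end = min(chrom_lengths[chrom], start + width)
        summit = start + width // 2 + int(rng.integers(-width // 4, width // 4 + 1))
        summit = min(max(summit, start), end - 1)
        peak_ivs.append(GenomicInterval(chrom, start, end))
        summits.append(summit)

    n_diff = round(cfg.frac_differential * cfg.n_peaks)
    diff_idx = np.sort(rng.choice(cfg.n_peaks, size=n_diff, replace=False))
    diff_set = set(int(i) for i in diff_idx)

    # ----- tracks --------------------------------------------------------
    bw = cfg.bin_width
    mu: dict[str, np.ndarray] = {}
    for c in chroms:
        mu[c] = np.full(math.ceil(chrom_lengths[c] / bw), cfg.baseline_enrichment)
    amplitudes = rng.uniform(5.0, 20.0, size=cfg.n_peaks)
    for i, (iv, summit) in enumerate(zip(peak_ivs, summits)):
        lo, hi = iv.start // bw, (iv.end - 1) // bw + 1
        centers = (np.arange(lo, hi) + 0.5) * bw
        half = max(iv.length / 2.0, bw)
        shape = np.clip(1.0 - np.abs(centers - summit) / half, 0.0, 1.0)
        mu[iv.chrom][lo:hi] += amplitudes[i] * shape

    track_wt = SignalTrack(chrom_lengths, bw)
    track_ko = SignalTrack(chrom_lengths, bw)
    for c in chroms:
        n = mu[c].size
        track_wt.values[c] = mu[c] * _lognormal_noise(rng, cfg.noise_cv, n)
        track_ko.values[c] = mu[c] * _lognormal_noise(rng, cfg.noise_cv, n)
    factor = 2.0 ** cfg.planted_log2fc
    for i in diff_set:
        iv, summit = peak_ivs[i], summits[i]
        start = max(0, summit - cfg.window_bp)
        end = min(chrom_lengths[iv.chrom], summit + cfg.window_bp + 1)
        lo, hi = start // bw, (end - 1) // bw + 1
        track_ko.values[iv.chrom][lo:hi] *= factor

    def _peak_from_track(i: int, track: SignalTrack, prefix: str) -> Peak:
        iv, summit = peak_ivs[i], summits[i]
        sig = float(np.mean(track.window_values(iv.chrom, iv.start, iv.end)))
        return Peak(iv, summit, sig, f"{prefix}_{i:04d}")

    peaks_wt = [_peak_from_track(i, track_wt, "peak") for i in range(cfg.n_peaks)]
    peaks_ko = [_peak_from_track(i, track_ko, "peak") for i in range(cfg.n_peaks)]

    # ----- auxiliary slot allocation -------------------------------------
    slot_order = rng.permutation(n_blocks)
    cursor = 0

    def _take(n: int) -> list[int]:
        nonlocal cursor
        taken = [int(s) for s in slot_order[cursor : cursor + n]]
        cursor += n
        return taken

    enhancer_slots = _take(cfg.n_enhancers)
    sesm_slots = _take(cfg.n_sesm_atlas)
    hdac4_extra_slots = _take(cfg.n_hdac4_extra)
    rep_a_slots = _take(n_rep_unique)
    rep_b_slots = _take(n_rep_unique)

    def _slot_pos(slot: int) -> tuple[str, int]:
        chrom, bstart, bsize = blocks[slot]
        return chrom, bstart + int(0.72 * bsize)

    # ----- enhancer constituents and planted super-enhancers -------------
    cluster_units = set(int(i) for i in rng.choice(
        cfg.n_enhancers, size=cfg.n_se_planted, replace=False
    ))
    bg_totals = rng.uniform(20.0, 60.0, size=cfg.n_enhancers)
    bg_median = float(np.median(bg_totals)) if cfg.n_enhancers else 40.0

    h3k27ac_enh: list[Peak] = []
    h3k4me1: list[Peak] = []
    planted_se: list[GenomicInterval] = []
    enh_id = 0
    for u, slot in enumerate(enhancer_slots):
        chrom, pos = _slot_pos(slot)
        if u in cluster_units:
            n_const = int(rng.integers(3, 5))
            total = (
                cfg.se_signal_multiplier * bg_median * float(rng.uniform(0.95, 1.15))
            )
            weights = rng.uniform(0.8, 1.2, size=n_const)
            shares = total * weights / weights.sum()
            offsets = [int(k * 9_000 / max(n_const - 1, 1)) for k in range(n_const)]
            first, last = None, None
            for off, share in zip(offsets, shares):
                width = int(rng.integers(800, 2001))
                start = pos + off
                end = min(chrom_lengths[chrom], start + width)
                ivc = GenomicInterval(chrom, start, end)
                h3k27ac_enh.append(
                    Peak(ivc, start + width // 2, float(share), f"enh_{enh_id:04d}")
                )
                enh_id += 1
                first = start if first is None else first
                last = end
            planted_se.append(GenomicInterval(chrom, first, last))
        else:
            n_const = 1 if rng.random() < 0.8 else 2
            shares = (
                [bg_totals[u]]
                if n_const == 1
                else [0.6 * bg_totals[u], 0.4 * bg_totals[u]]
            )
            for k, share in enumerate(shares):
                width = int(rng.integers(800, 2501))
                start = pos + k * 3_000
                end = min(chrom_lengths[chrom], start + width)
                ivc = GenomicInterval(chrom, start, end)
                h3k27ac_enh.append(
                    Peak(ivc, start + width // 2, float(share), f"enh_{enh_id:04d}")
                )
                enh_id += 1
    for p in h3k27ac_enh:
        shift = int(rng.integers(-200, 201))
        start = max(0, p.start + shift)
        end = min(chrom_lengths[p.chrom], p.end + shift)
        h3k4me1.append(
            Peak(
                GenomicInterval(p.chrom, start, end),
                min(max(p.summit, start), end - 1),
                float(rng.uniform(5, 30)),
                p.name.replace("enh", "k4me1"),
            )
        )

    # ----- replicate peak sets -------------------------------------------
    shared_idx = [int(i) for i in rng.choice(
        cfg.n_peaks, size=n_rep_shared, replace=False
    )]
    shared_peaks = [peaks_wt[i] for i in shared_idx]

    def _unique_peaks(slots: list[int], prefix: str) -> list[Peak]:
        out = []
        for j, slot in enumerate(slots):
            chrom, pos = _slot_pos(slot)
            start = pos + 1_000
            end = min(chrom_lengths[chrom], start + 1_200)
            out.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    (start + end) // 2,
                    float(rng.uniform(5, 30)),
                    f"{prefix}_{j:04d}",
                )
            )
        return out

    peaks_wt_rep1 = shared_peaks + _unique_peaks(rep_a_slots, "rep1u")
    peaks_wt_rep2 = shared_peaks + _unique_peaks(rep_b_slots, "rep2u")

    # ----- atlas classes and HDAC4 peaks ---------------------------------
    null_idx = [i for i in range(cfg.n_peaks) if i not in diff_set]
    n_ses_diff = min(cfg.n_ses_atlas * 3 // 5, len(diff_set))
    n_ses_null = min(cfg.n_ses_atlas - n_ses_diff, len(null_idx))
    ses_diff_idx = [int(i) for i in rng.choice(
        sorted(diff_set), size=n_ses_diff, replace=False
    )] if n_ses_diff else []
    remaining_null = list(null_idx)
    ses_null_idx = [int(i) for i in rng.choice(
        remaining_null, size=n_ses_null, replace=False
    )] if n_ses_null else []
    remaining_null = [i for i in remaining_null if i not in set(ses_null_idx)]
    n_tes = min(cfg.n_tes_atlas, len(remaining_null))
    tes_idx = [int(i) for i in rng.choice(
        remaining_null, size=n_tes, replace=False
    )] if n_tes else []

    def _window_iv(i: int, half: int) -> GenomicInterval:
        chrom = peak_ivs[i].chrom
        s = max(0, summits[i] - half)
        e = min(chrom_lengths[chrom], summits[i] + half)
        return GenomicInterval(chrom, s, e)

    ses_entries = []  # (interval, peak_idx or None, differential flag)
    for i in ses_diff_idx:
        ses_entries.append((_window_iv(i, 7_500), i, True))
    for i in ses_null_idx:
        ses_entries.append((_window_iv(i, 7_500), i, False))
    ses_intervals = [e[0] for e in ses_entries]
    tes_intervals = [_window_iv(i, 750) for i in tes_idx]
    sesm_intervals = []
    for slot in sesm_slots:
        chrom, pos = _slot_pos(slot)
        sesm_intervals.append(
            GenomicInterval(chrom, pos, min(chrom_lengths[chrom], pos + 10_000))
        )

    # HDAC4 binding: a subset of differential SES, a few null SES, extras
    n_hdac4_diff = min(max(n_ses_diff * 5 // 9, 0), n_ses_diff)
    n_hdac4_null = min(5, n_ses_null)
    hdac4_diff_pos = sorted(
        int(i) for i in rng.choice(n_ses_diff, size=n_hdac4_diff, replace=False)
    ) if n_hdac4_diff else []
    hdac4_null_pos = sorted(
        n_ses_diff + int(i)
        for i in rng.choice(n_ses_null, size=n_hdac4_null, replace=False)
    ) if n_hdac4_null else []
    hdac4_bound_ses = set(hdac4_diff_pos) | set(hdac4_null_pos)

    hdac4_peaks: list[Peak] = []
    for pos_idx in sorted(hdac4_bound_ses):
        _, peak_i, _ = ses_entries[pos_idx]
        chrom = peak_ivs[peak_i].chrom
        s = max(0, summits[peak_i] - 300)
        e = min(chrom_lengths[chrom], summits[peak_i] + 300)
        hdac4_peaks.append(
            Peak(GenomicInterval(chrom, s, e), summits[peak_i],
                 float(rng.uniform(5, 30)), f"hdac4_ses{pos_idx:04d}")
        )
    for j, slot in enumerate(hdac4_extra_slots):
        chrom, pos = _slot_pos(slot)
        s, e = pos + 2_000, min(chrom_lengths[chrom], pos + 2_600)
        hdac4_peaks.append(
            Peak(GenomicInterval(chrom, s, e), (s + e) // 2,
                 float(rng.uniform(5, 30)), f"hdac4_x{j:04d}")
        )

    # AP-1-bearing subset of the HDAC4-bound differential SES
    n_ap1 = max(len(hdac4_diff_pos) * 3 // 5, 0)
    ap1_ses = set(
        int(hdac4_diff_pos[i])
        for i in rng.choice(len(hdac4_diff_pos), size=n_ap1, replace=False)
    ) if n_ap1 else set()

    # ----- genes, exons --------------------------------------------------
    genes_per_chrom_base, g_extra = divmod(cfg.n_genes, cfg.n_chroms)
    gene_rows = []
    exons: list[GenomicInterval] = []
    gi = 0
    for ci, c in enumerate(chroms):
        n_g = genes_per_chrom_base + (1 if ci < g_extra else 0)
        if n_g == 0:
            continue
        spacing = chrom_lengths[c] // n_g
        for k in range(n_g):
            tss = k * spacing + spacing // 2 + int(rng.integers(-spacing // 10,
                                                                spacing // 10 + 1))
            tss = min(max(tss, 0), chrom_lengths[c] - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            span = int(rng.integers(5_000, 15_001))
            if strand == "+":
                gstart, gend = tss, min(chrom_lengths[c], tss + span)
            else:
                gstart, gend = max(0, tss - span), tss + 1
            gene_rows.append(
                dict(gene=f"gene_{gi:04d}", chrom=c, start=gstart, end=gend,
                     tss=tss, strand=strand)
            )
            n_ex = int(rng.integers(2, 4))
            for x in range(n_ex):
                ex_start = gstart + int(
                    (gend - gstart) * (x + 0.1) / n_ex
                )
                ex_len = int(rng.integers(200, 801))
                ex_end = min(gend, ex_start + ex_len)
                if ex_end > ex_start:
                    exons.append(GenomicInterval(c, ex_start, ex_end, strand))
            gi += 1
    genes = pd.DataFrame(gene_rows)

    # ----- expression table ----------------------------------------------
    active_flags = rng.random(cfg.n_genes) < cfg.frac_active_genes
    baseline = np.where(
        active_flags,
        rng.lognormal(math.log(200.0), 0.5, size=cfg.n_genes),
        rng.lognormal(math.log(20.0), 0.5, size=cfg.n_genes),
    )
    deg_idx = [int(i) for i in rng.choice(
        cfg.n_genes, size=cfg.n_deg_planted, replace=False
    )]
    n_up = round(cfg.deg_induced_frac * cfg.n_deg_planted)
    deg_dirs = {g: (1 if j < n_up else -1) for j, g in enumerate(deg_idx)}
    non_deg = [i for i in range(cfg.n_genes) if i not in deg_dirs]
    n_clone_specific = min(20, max(len(non_deg) // 2 - 1, 0))
    clone_only = {
        "clone_sg1": set(int(i) for i in rng.choice(
            non_deg, size=n_clone_specific, replace=False
        )) if n_clone_specific else set(),
    }
    rest = [i for i in non_deg if i not in clone_only["clone_sg1"]]
    clone_only["clone_sg2"] = set(int(i) for i in rng.choice(
        rest, size=min(n_clone_specific, len(rest)), replace=False
    )) if n_clone_specific else set()

    expr_rows = []
    for comparison in ("clone_sg1", "clone_sg2"):
        for i in range(cfg.n_genes):
            gene = f"gene_{i:04d}"
            if i in deg_dirs:
                fc = deg_dirs[i] * float(rng.uniform(2.5, 8.0))
                p_adj = float(rng.uniform(1e-6, 0.01))
            elif i in clone_only[comparison]:
                sign = 1 if rng.random() < 0.5 else -1
                fc = sign * float(rng.uniform(2.5, 6.0))
                p_adj = float(rng.uniform(1e-5, 0.02))
            else:
                sign = 1 if rng.random() < 0.5 else -1
                fc = sign * float(rng.uniform(1.0, 1.8))
                p_adj = float(rng.uniform(0.06, 1.0))
            expr_rows.append(
                dict(gene=gene, comparison=comparison,
                     baseline=float(baseline[i]), fold_change=fc, p_adj=p_adj)
            )
    expression = pd.DataFrame(expr_rows)

    # ----- sequences ------------------------------------------------------
    sequences: dict[str, str] = {}
    motif_rows = []
    n_target_planted = round(cfg.motif_frac_target * cfg.n_motif_regions)
    n_bg_planted = round(cfg.motif_frac_background * cfg.n_motif_regions)
    for j in range(cfg.n_motif_regions):
        seq = _rand_seq(rng, 500)
        offset = -1
        if j < n_target_planted:
            seq, offset = _plant_ap1(rng, seq)
        name = f"target_{j:04d}"
        sequences[name] = seq
        motif_rows.append(dict(region=name, planted=j < n_target_planted,
                               offset=offset))
    for j in range(cfg.n_motif_regions):
        seq = _rand_seq(rng, 500)
        offset = -1
        if j < n_bg_planted:
            seq, offset = _plant_ap1(rng, seq)
        name = f"background_{j:04d}"
        sequences[name] = seq
        motif_rows.append(dict(region=name, planted=j < n_bg_planted,
                               offset=offset))
    ses_flag_rows = []
    for pos_idx, (iv, peak_i, is_diff) in enumerate(ses_entries):
        seq = _rand_seq(rng, 600)
        offset = -1
        if pos_idx in ap1_ses:
            seq, offset = _plant_ap1(rng, seq)
        name = f"ses_{pos_idx:04d}"
        sequences[name] = seq
        ses_flag_rows.append(
            dict(ses_id=name, chrom=iv.chrom, start=iv.start, end=iv.end,
                 differential=is_diff, hdac4_bound=pos_idx in hdac4_bound_ses,
                 ap1=pos_idx in ap1_ses)
        )

    # ----- truth ----------------------------------------------------------
    truth_diff = pd.DataFrame(
        dict(
            name=[peaks_wt[i].name for i in sorted(diff_set)],
            chrom=[peak_ivs[i].chrom for i in sorted(diff_set)],
            summit=[summits[i] for i in sorted(diff_set)],
            log2fc=[cfg.planted_log2fc] * len(diff_set),
        )
    )
    truth_se = pd.DataFrame(
        dict(
            chrom=[iv.chrom for iv in planted_se],
            start=[iv.start for iv in planted_se],
            end=[iv.end for iv in planted_se],
        )
    )
    truth_degs = pd.DataFrame(
        dict(
            gene=[f"gene_{i:04d}" for i in deg_idx],
            direction=[deg_dirs[i] for i in deg_idx],
        )
    )
    ses_flags = pd.DataFrame(ses_flag_rows)
    truth = dict(
        differential=truth_diff,
        super_enhancers=planted_se,
        super_enhancers_table=truth_se,
        degs=truth_degs,
        active_genes={f"gene_{i:04d}" for i in range(cfg.n_genes)
                      if active_flags[i]},
        motif_regions=pd.DataFrame(motif_rows),
        ses_flags=ses_flags,
        screen=dict(
            n_ses_differential=int(ses_flags["differential"].sum()),
            n_ses_hdac4_bound=int(
                (ses_flags["differential"] & ses_flags["hdac4_bound"]).sum()
            ),
            n_ses_ap1=int(ses_flags["ap1"].sum()),
        ),
        replicate_shared=n_rep_shared,
    )

    return SyntheticDataset(
        config=cfg,
        chrom_lengths=chrom_lengths,
        genes=genes,
        exons=exons,
        atlas=dict(SES=ses_intervals, TES=tes_intervals, SESM=sesm_intervals),
        peaks_wt=peaks_wt,
        peaks_ko=peaks_ko,
        peaks_wt_rep1=peaks_wt_rep1,
        peaks_wt_rep2=peaks_wt_rep2,
        h3k27ac_enhancers=h3k27ac_enh,
        h3k4me1_peaks=h3k4me1,
        hdac4_peaks=hdac4_peaks,
        track_wt=track_wt,
        track_ko=track_ko,
        expression=expression,
        sequences=sequences,
        truth=truth,
    )


def emit_files(ds: SyntheticDataset, out_dir: str | Path) -> pd.DataFrame:
    """Write the dataset as plain-text files; returns the manifest.

    The manifest (also written as ``manifest.tsv``) lists every file with its
    row count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    manifest: list[tuple[str, int]] = []

    def _note(name: str, rows: int) -> None:
        manifest.append((name, rows))

    write_chrom_sizes(ds.chrom_lengths, out / "chrom.sizes")
    _note("chrom.sizes", len(ds.chrom_lengths))

    genes_bed = out / "genes.bed"
    with genes_bed.open("w") as fh:
        # BED6+1: the 7th column is the TSS as an offset from start, matching
        # the summit-offset convention of the peak files
        for row in ds.genes.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene}\t0\t{row.strand}"
                f"\t{row.tss - row.start}\n"
            )
    _note("genes.bed", len(ds.genes))

    write_intervals_bed(ds.exons, out / "exons.bed")
    _note("exons.bed", len(ds.exons))

    for label, ivs in ds.atlas.items():
        name = f"atlas_{label.lower()}.bed"
        write_intervals_bed(ivs, out / name)
        _note(name, len(ivs))

    peak_files = {
        "peaks_wt.bed": ds.peaks_wt,
        "peaks_ko.bed": ds.peaks_ko,
        "peaks_wt_rep1.bed": ds.peaks_wt_rep1,
        "peaks_wt_rep2.bed": ds.peaks_wt_rep2,
        "peaks_h3k27ac_enh.bed": ds.h3k27ac_enhancers,
        "peaks_h3k4me1.bed": ds.h3k4me1_peaks,
        "peaks_hdac4.bed": ds.hdac4_peaks,
    }
    for name, peaks in peak_files.items():
        write_bed(peaks, out / name)
        _note(name, len(peaks))

    ds.track_wt.to_bedgraph(out / "track_wt.bedgraph")
    _note("track_wt.bedgraph", sum(
        ds.track_wt.n_bins(c) for c in ds.chrom_lengths
    ))
    ds.track_ko.to_bedgraph(out / "track_ko.bedgraph")
    _note("track_ko.bedgraph", sum(
        ds.track_ko.n_bins(c) for c in ds.chrom_lengths
    ))

    with (out / "regions.fasta").open("w") as fh:
        for name in sorted(ds.sequences):
            fh.write(f">{name}\n{ds.sequences[name]}\n")
    _note("regions.fasta", len(ds.sequences))

    ds.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    _note("expression.tsv", len(ds.expression))

    truth_tables = {
        "truth/differential.tsv": ds.truth["differential"],
        "truth/super_enhancers.tsv": ds.truth["super_enhancers_table"],
        "truth/degs.tsv": ds.truth["degs"],
        "truth/motif_regions.tsv": ds.truth["motif_regions"],
        "truth/ses_flags.tsv": ds.truth["ses_flags"],
    }
    for name, df in truth_tables.items():
        df.to_csv(out / name, sep="\t", index=False)
        _note(name, len(df))

    mdf = pd.DataFrame(manifest, columns=["file", "rows"])
    mdf.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return mdf
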