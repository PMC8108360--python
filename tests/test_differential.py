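"""Summit-centered KO/WT ratio statistic and differential region calling."""

import numpy as np
import pytest

from senesce_enh.core import GenomicInterval, Peak, SignalTrack
from senesce_enh.differential import (
    call_differential_regions,
    split_by_mark,
    summit_ratio_score,
)
from senesce_enh.simulate import SimConfig, generate

BW = 50
CHROM_LEN = 200_000


def _track(values):
    return SignalTrack({"chr1": CHROM_LEN}, BW, {"chr1": np.asarray(values, float)})


def _peak(summit=100_000):
    return Peak(GenomicInterval("chr1", summit - 500, summit + 500), summit, 1.0, "p")


@pytest.fixture
def flat_tracks():
    n = CHROM_LEN // BW
    return _track(np.full(n, 7.0)), _track(np.full(n, 7.0))


class TestSummitRatioScore:
    @pytest.mark.parametrize("mode", ["mean_of_ratios", "ratio_of_sums"])
    def test_identical_tracks_score_one(self, flat_tracks, mode):
        ko, wt = flat_tracks
        s = summit_ratio_score(_peak(), ko, wt, mode=mode)
        assert s.fc == pytest.approx(1.0)
        assert s.log2fc == pytest.approx(0.0)

    @pytest.mark.parametrize("mode", ["mean_of_ratios", "ratio_of_sums"])
    def test_constant_doubling_is_exact_without_pseudocount(self, mode):
        n = CHROM_LEN // BW
        wt = _track(np.full(n, 40.0))
        ko = _track(np.full(n, 80.0))
        s = summit_ratio_score(_peak(), ko, wt, pseudocount=0.0, mode=mode)
        assert abs(s.fc - 2.0) < 1e-9
        assert abs(s.log2fc - 1.0) < 1e-9

    def test_window_bin_count_and_boundary_clipping(self, flat_tracks):
        ko, wt = flat_tracks
        s = summit_ratio_score(_peak(100_000), ko, wt, window_bp=15_000)
        assert s.n_bins == 601  # bins covering the closed 30 kb window
        edge = Peak(GenomicInterval("chr1", 0, 1000), 100, 1.0, "edge")
        s_edge = summit_ratio_score(edge, ko, wt, window_bp=15_000)
        assert s_edge.n_bins == (100 + 15_000) // BW + 1

    def test_mean_of_ratios_matches_bin_loop_oracle(self):
        rng = np.random.default_rng(41)
        n = CHROM_LEN // BW
        ko = _track(rng.lognormal(2, 0.6, n))
        wt = _track(rng.lognormal(2, 0.6, n))
        for summit in (400, 57_123, 100_000, 199_600):
            peak = Peak(
                GenomicInterval("chr1", max(0, summit - 100), summit + 100),
                summit, 1.0, "p",
            )
            s = summit_ratio_score(peak, ko, wt, window_bp=15_000)
            # independent bin-by-bin loop over the closed window
            lo = max(0, summit - 15_000)
            hi = min(CHROM_LEN, summit + 15_000 + 1)
            total, count = 0.0, 0
            for b in range(lo // BW, (hi - 1) // BW + 1):
                total += (ko.values["chr1"][b] + 1.0) / (wt.values["chr1"][b] + 1.0)
                count += 1
            assert s.n_bins == count
            assert abs(s.fc - total / count) < 1e-9

    def test_swap_antisymmetry_in_ratio_of_sums(self):
        rng = np.random.default_rng(42)
        n = CHROM_LEN // BW
        ko = _track(rng.lognormal(2, 0.6, n))
        wt = _track(rng.lognormal(2, 0.6, n))
        fwd = summit_ratio_score(_peak(), ko, wt, pseudocount=0.0,
                                 mode="ratio_of_sums")
        rev = summit_ratio_score(_peak(), wt, ko, pseudocount=0.0,
                                 mode="ratio_of_sums")
        assert fwd.log2fc == pytest.approx(-rev.log2fc, abs=1e-9)

    def test_bins_outside_window_never_affect_score(self, flat_tracks):
        ko, wt = flat_tracks
        before = summit_ratio_score(_peak(100_000), ko, wt, window_bp=15_000)
        ko2 = ko.copy()
        ko2.values["chr1"][: (100_000 - 15_000) // BW] = 999.0
        ko2.values["chr1"][(100_000 + 15_000) // BW + 1 :] = 999.0
        after = summit_ratio_score(_peak(100_000), ko2, wt, window_bp=15_000)
        assert after.fc == before.fc

    def test_raising_a_ko_bin_inside_window_never_lowers_fc(self, flat_tracks):
        ko, wt = flat_tracks
        base = summit_ratio_score(_peak(100_000), ko, wt)
        for b in (100_000 // BW, (100_000 - 14_000) // BW):
            ko2 = ko.copy()
            ko2.values["chr1"][b] += 50.0
            bumped = summit_ratio_score(_peak(100_000), ko2, wt)
            assert bumped.fc > base.fc

    def test_missing_chromosome_and_narrow_window_errors(self, flat_tracks):
        ko, wt = flat_tracks
        other = Peak(GenomicInterval("chrX", 0, 100), 50, 1.0, "x")
        with pytest.raises(KeyError):
            summit_ratio_score(other, ko, wt)
        with pytest.raises(ValueError):
            summit_ratio_score(_peak(), ko, wt, window_bp=10)


class TestCallDifferentialRegions:
    def test_identical_tracks_call_nothing(self, flat_tracks):
        ko, wt = flat_tracks
        peaks = [_peak(20_000), _peak(100_000), _peak(180_000)]
        scores = call_differential_regions(peaks, ko, wt)
        assert all(s.call == "unchanged" for s in scores)

    def test_empty_peak_list_is_empty_result(self, flat_tracks):
        ko, wt = flat_tracks
        assert call_differential_regions([], ko, wt) == []

    def test_output_sorted_by_abs_log2fc_then_genomic_order(self):
        rng = np.random.default_rng(43)
        n = CHROM_LEN // BW
        ko = _track(rng.lognormal(2, 0.8, n))
        wt = _track(rng.lognormal(2, 0.8, n))
        peaks = [_peak(s) for s in range(20_000, 190_000, 10_000)]
        scores = call_differential_regions(peaks, ko, wt)
        keys = [(-abs(s.log2fc), s.peak.chrom, s.peak.start) for s in scores]
        assert keys == sorted(keys)

    def test_recovers_planted_regions_on_study_conditions(self, dataset):
        scores = call_differential_regions(
            dataset.peaks_ko, dataset.track_ko, dataset.track_wt, cutoff=1.0
        )
        planted = set(dataset.truth["differential"]["name"])
        up = {s.peak.name for s in scores if s.call == "up"}
        called = up | {s.peak.name for s in scores if s.call == "down"}
        sensitivity = len(up & planted) / len(planted)
        n_null = len(scores) - len(planted)
        false_rate = len(called - planted) / n_null
        assert sensitivity >= 0.95
        assert false_rate <= 0.05

    def test_down_calls_mirror_up_calls_under_track_swap(self, dataset):
        fwd = call_differential_regions(
            dataset.peaks_ko, dataset.track_ko, dataset.track_wt,
            pseudocount=0.0, mode="ratio_of_sums",
        )
        rev = call_differential_regions(
            dataset.peaks_ko, dataset.track_wt, dataset.track_ko,
            pseudocount=0.0, mode="ratio_of_sums",
        )
        up_fwd = {s.peak.name for s in fwd if s.call == "up"}
        down_rev = {s.peak.name for s in rev if s.call == "down"}
        assert up_fwd == down_rev

    def test_sensitivity_grows_with_planted_effect_size(self):
        sens = []
        for lfc in (0.5, 1.0, 1.5, 2.0):
            ds = generate(
                SimConfig(seed=17, n_peaks=100, n_chroms=1, n_genes=100,
                          n_enhancers=40, n_se_planted=4, n_sesm_atlas=5,
                          n_hdac4_extra=5, n_replicate_peaks=20,
                          n_ses_atlas=12, n_tes_atlas=10, n_deg_planted=10,
                          planted_log2fc=lfc)
            )
            scores = call_differential_regions(
                ds.peaks_ko, ds.track_ko, ds.track_wt
            )
            planted = set(ds.truth["differential"]["name"])
            up = {s.peak.name for s in scores if s.call == "up"}
            sens.append(len(up & planted) / len(planted))
        assert sens == sorted(sens)
        assert sens[-1] >= 0.95


class TestSplitByMark:
    def _scores(self, dataset):
        return call_differential_regions(
            dataset.peaks_ko, dataset.track_ko, dataset.track_wt
        )

    def test_unknown_mark_is_an_error(self, dataset):
        with pytest.raises(ValueError):
            split_by_mark(self._scores(dataset), "H3K9me3")

    def test_partition_of_non_unchanged_scores(self, dataset):
        scores = self._scores(dataset)
        up, down = split_by_mark(scores, "H3K27ac")
        n_changed = sum(s.call != "unchanged" for s in scores)
        assert len(up) + len(down) == n_changed
        assert all(s.call == "up" for s in up)
        assert all(s.call == "down" for s in down)

    def test_all_unchanged_gives_two_empty_sets(self, flat_tracks):
        ko, wt = flat_tracks
        scores = call_differential_regions([_peak()], ko, wt)
        assert split_by_mark(scores, "H3K27me3") == ([], [])
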