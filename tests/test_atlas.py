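"""Atlas union/resolution, element enrichment, closest-active-gene lookup."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from senesce_enh.atlas import (
    atlas_overlap_fraction,
    assign_regions,
    build_ses_atlas,
    closest_active_gene,
    element_enrichment,
    merge_intervals,
    promoter_intervals,
    resolve_classes,
    round_half_up_percent,
    subtract_interval_sets,
    total_bp,
)
from senesce_enh.core import GenomicInterval, Peak

CHR_LEN = 1_000_000
SIZES = {"chr1": CHR_LEN}


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def _random_ivs(rng, n, span=CHR_LEN, max_w=5_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - max_w))
        out.append(_iv(s, s + int(rng.integers(1, max_w))))
    return out


def _coverage_mask(intervals, length=CHR_LEN):
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


class TestUnionAndSubtraction:
    def test_single_set_is_merged(self):
        got = build_ses_atlas([[_iv(0, 10), _iv(5, 20), _iv(30, 40)]])
        assert got == [_iv(0, 20), _iv(30, 40)]

    def test_duplicate_sets_collapse(self):
        s = [_iv(100, 200), _iv(500, 900)]
        assert build_ses_atlas([s, s]) == build_ses_atlas([s])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_ses_atlas([])

    def test_union_coverage_matches_per_bp_oracle(self):
        rng = np.random.default_rng(51)
        sets = [_random_ivs(rng, 150), _random_ivs(rng, 150)]
        merged = build_ses_atlas(sets)
        oracle = _coverage_mask(sets[0]) | _coverage_mask(sets[1])
        assert total_bp(merged) == int(oracle.sum())
        assert np.array_equal(_coverage_mask(merged), oracle)

    def test_subtraction_matches_per_bp_oracle(self):
        rng = np.random.default_rng(52)
        a, b = _random_ivs(rng, 120), _random_ivs(rng, 120)
        got = subtract_interval_sets(a, b)
        oracle = _coverage_mask(a) & ~_coverage_mask(b)
        assert np.array_equal(_coverage_mask(got), oracle)

    def test_merge_matches_bedtools(self, tmp_path):
        """Cross-check interval merging against the bedtools CLI."""
        rng = np.random.default_rng(53)
        ivs = _random_ivs(rng, 200)
        bed = tmp_path / "in.bed"
        bed.write_text(
            "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in sorted(
                ivs, key=lambda x: (x.chrom, x.start)))
        )
        res = subprocess.run(
            ["bedtools", "merge", "-i", str(bed)],
            capture_output=True, text=True, check=True,
        )
        expected = [
            _iv(int(p[1]), int(p[2]), p[0])
            for p in (line.split("\t") for line in res.stdout.splitlines())
        ]
        # bedtools merge does not join book-ended intervals by default;
        # compare coverage, which both definitions agree on
        assert np.array_equal(
            _coverage_mask(merge_intervals(ivs)), _coverage_mask(expected)
        )


class TestResolveClasses:
    def test_disjoint_inputs_unchanged(self):
        raw = {"SES": [_iv(0, 100)], "TES": [_iv(200, 300)]}
        atlas = resolve_classes(raw, ("SES", "TES"), SIZES)
        assert atlas.classes["SES"] == [_iv(0, 100)]
        assert atlas.classes["TES"] == [_iv(200, 300)]
        assert atlas.coverage == {"SES": 100, "TES": 100}

    def test_lower_precedence_class_is_clipped(self):
        raw = {"SES": [_iv(1000, 9000)], "promoter": [_iv(2000, 3000)]}
        atlas = resolve_classes(raw, ("SES", "promoter"), SIZES)
        assert atlas.coverage["promoter"] == 0
        assert atlas.classes["promoter"] == []

    def test_duplicate_precedence_labels_error(self):
        with pytest.raises(ValueError):
            resolve_classes({"SES": []}, ("SES", "SES"), SIZES)

    def test_unlisted_class_error(self):
        with pytest.raises(ValueError):
            resolve_classes({"X": []}, ("SES",), SIZES)

    def test_resolution_matches_first_match_per_bp_oracle(self):
        rng = np.random.default_rng(54)
        labels = ("SES", "SESM", "TES", "promoter")
        raw = {lab: _random_ivs(rng, 60) for lab in labels}
        atlas = resolve_classes(raw, labels + ("intergenic",), SIZES)
        # per-bp first-match oracle
        claim = np.full(CHR_LEN, -1, dtype=np.int8)
        for rank, lab in enumerate(labels):
            mask = _coverage_mask(raw[lab])
            claim[mask & (claim == -1)] = rank
        for rank, lab in enumerate(labels):
            assert atlas.coverage[lab] == int((claim == rank).sum())
            assert np.array_equal(
                _coverage_mask(atlas.classes[lab]), claim == rank
            )
        assert atlas.coverage["intergenic"] == int((claim == -1).sum())

    def test_coverages_conserve_the_genome_with_intergenic(self):
        rng = np.random.default_rng(55)
        raw = {"SES": _random_ivs(rng, 40), "TES": _random_ivs(rng, 40)}
        atlas = resolve_classes(raw, ("SES", "TES", "intergenic"), SIZES)
        assert sum(atlas.coverage.values()) == CHR_LEN


class TestAssignAndEnrich:
    def _region(self, summit, chrom="chr1"):
        return Peak(
            GenomicInterval(chrom, max(0, summit - 50), summit + 50),
            summit, 1.0, f"r{summit}",
        )

    def test_summit_decides_the_class(self):
        atlas = resolve_classes(
            {"SES": [_iv(100, 200)], "TES": [_iv(300, 400)]},
            ("SES", "TES", "intergenic"), SIZES,
        )
        assigned = assign_regions(
            [self._region(150), self._region(350), self._region(500_000)], atlas
        )
        assert [p.summit for p in assigned["SES"]] == [150]
        assert [p.summit for p in assigned["TES"]] == [350]
        assert [p.summit for p in assigned["intergenic"]] == [500_000]

    def test_empty_atlas_sends_everything_intergenic(self):
        atlas = resolve_classes({}, ("SES", "intergenic"), SIZES)
        regions = [self._region(s) for s in (100, 5_000, 90_000)]
        assigned = assign_regions(regions, atlas)
        assert assigned["intergenic"] == regions

    def test_assignment_is_a_partition_matching_lookup_oracle(self):
        rng = np.random.default_rng(56)
        labels = ("SES", "TES")
        raw = {lab: _random_ivs(rng, 50) for lab in labels}
        atlas = resolve_classes(raw, labels + ("intergenic",), SIZES)
        regions = [self._region(int(rng.integers(100, CHR_LEN - 100)))
                   for _ in range(500)]
        assigned = assign_regions(regions, atlas)
        assert sum(len(v) for v in assigned.values()) == len(regions)
        masks = {lab: _coverage_mask(atlas.classes[lab]) for lab in labels}
        for r in regions:
            expected = next(
                (lab for lab in labels if masks[lab][r.summit]), "intergenic"
            )
            assert r in assigned[expected]

    def test_fold_arithmetic(self):
        atlas = resolve_classes(
            {"SES": [_iv(0, 100_000)], "TES": [_iv(200_000, 210_000)]},
            ("SES", "TES", "intergenic"), SIZES,
        )
        regions = (
            [self._region(s) for s in range(1_000, 11_000, 1_000)]  # 10 in SES
            + [self._region(s) for s in range(201_000, 209_000, 1_000)]  # 8 TES
            + [self._region(s) for s in range(300_000, 382_000, 1_000)]  # 82
        )
        rows = {r.label: r for r in element_enrichment(
            assign_regions(regions, atlas), atlas
        )}
        # SES covers 10% of the genome and holds 10% of regions -> fold 1
        assert rows["SES"].fold == pytest.approx(1.0)
        # TES covers 1% and holds 8% -> fold 8
        assert rows["TES"].fold == pytest.approx(8.0)

    def test_fold_identity_sums_to_one(self):
        rng = np.random.default_rng(57)
        raw = {"SES": _random_ivs(rng, 30), "TES": _random_ivs(rng, 30)}
        atlas = resolve_classes(raw, ("SES", "TES", "intergenic"), SIZES)
        regions = [self._region(int(rng.integers(100, CHR_LEN - 100)))
                   for _ in range(200)]
        rows = element_enrichment(assign_regions(regions, atlas), atlas)
        assert sum(
            r.fold * r.expected_frac for r in rows if np.isfinite(r.fold)
        ) == pytest.approx(1.0)

    def test_no_regions_is_an_error(self):
        atlas = resolve_classes({"SES": [_iv(0, 10)]}, ("SES",), SIZES)
        with pytest.raises(ValueError):
            element_enrichment({"SES": []}, atlas)


class TestClosestActiveGene:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "tss"])

    def test_single_active_gene_wins(self):
        genes = self._genes([("g1", "chr1", 5_000), ("g2", "chr1", 6_000)])
        gene, dist = closest_active_gene(_iv(100, 200), genes, {"g2"})
        assert gene == "g2" and dist == 6_000 - 199

    def test_tss_inside_se_beats_any_outside(self):
        genes = self._genes([("near", "chr1", 1_050), ("inside", "chr1", 2_500)])
        gene, dist = closest_active_gene(_iv(2_000, 3_000), genes,
                                         {"near", "inside"})
        assert gene == "inside" and dist == 0

    def test_no_active_gene_on_chromosome_is_unassigned(self):
        genes = self._genes([("g1", "chr2", 100)])
        assert closest_active_gene(_iv(0, 10), genes, {"g1"})[0] == "unassigned"

    def test_matches_exhaustive_oracle_and_is_permutation_stable(self):
        rng = np.random.default_rng(58)
        genes = self._genes(
            [
                (f"g{i:03d}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, CHR_LEN)))
                for i in range(500)
            ]
        )
        active = set(genes["gene"].sample(frac=0.5, random_state=3))
        ses = [
            _iv(s, s + 10_000, f"chr{rng.integers(1, 3)}")
            for s in rng.integers(0, CHR_LEN - 10_000, size=200)
        ]
        shuffled = genes.sample(frac=1.0, random_state=4)
        for se in ses:
            best = None
            for g, c, t in genes.itertuples(index=False):
                if c != se.chrom or g not in active:
                    continue
                if se.start <= t < se.end:
                    d = 0
                elif t < se.start:
                    d = se.start - t
                else:
                    d = t - (se.end - 1)
                if best is None or (d, t, g) < best:
                    best = (d, t, g)
            expected = ("unassigned", -1) if best is None else (best[2], best[0])
            assert closest_active_gene(se, genes, active) == expected
            assert closest_active_gene(se, shuffled, active) == expected


class TestPromotersAndOverlap:
    def test_promoter_window_and_clipping(self):
        genes = pd.DataFrame(
            {"gene": ["a", "b"], "chrom": ["chr1", "chr1"], "tss": [5_000, 500]}
        )
        ivs = promoter_intervals(genes, 2_000, SIZES)
        assert ivs[0] == _iv(3_000, 7_000)
        assert ivs[1] == _iv(0, 2_500)

    def test_merged_promoter_coverage_bound(self):
        rng = np.random.default_rng(59)
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "chrom": "chr1",
                "tss": rng.integers(0, CHR_LEN, 200),
            }
        )
        merged = merge_intervals(promoter_intervals(genes, 2_000, SIZES))
        assert total_bp(merged) <= 2 * 2_000 * len(genes)

    def test_overlap_fraction_bounds(self):
        query = [_iv(i * 1_000, i * 1_000 + 500) for i in range(10)]
        n, frac = atlas_overlap_fraction(query, [_iv(0, 20_000)])
        assert (n, frac) == (10, 1.0)
        n, frac = atlas_overlap_fraction(query, [_iv(500_000, 600_000)])
        assert (n, frac) == (0, 0.0)
        with pytest.raises(ValueError):
            atlas_overlap_fraction([], query)

    def test_published_overlap_percentages_reproduce(self):
        """382 of 980 SEs in the atlas -> 39%; 142 of 230 -> 62%."""
        assert round_half_up_percent(382, 980) == 39
        assert round_half_up_percent(142, 230) == 62
        assert round_half_up_percent(91, 1053) == 9
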