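import numpy as np
import pytest

from oracles import exact_mannwhitney_less
from thermosplice.as_events import enumerate_events
from thermosplice.chromatin import (
    GeneMarkAnnotation,
    OccupancyTrack,
    associate_regions,
    binned_track_correlation,
    compare_distance_distributions,
    compare_region_widths,
    event_region_distance,
    fraction_marked,
    metagene_profile,
)
from thermosplice.io_formats import GeneModel, MarkRegion, TranscriptModel


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    return GeneModel(gene_id, chrom, strand, start, end,
                     [TranscriptModel(gene_id + ".1", [(start, end)])])


class TestAssociation:
    def test_contained_region_is_associated(self):
        (ann,) = associate_regions([gene("g", 1000, 5000)],
                                   [MarkRegion("chr1", 1500, 2000)])
        assert ann.marked and len(ann.regions) == 1

    def test_boundary_overlap_not_contained(self):
        (ann,) = associate_regions([gene("g", 1000, 5000)],
                                   [MarkRegion("chr1", 900, 1100)])
        assert not ann.marked
        (ann_any,) = associate_regions([gene("g", 1000, 5000)],
                                       [MarkRegion("chr1", 900, 1100)],
                                       mode="any")
        assert ann_any.marked

    def test_midpoint_mode(self):
        (ann,) = associate_regions([gene("g", 1000, 5000)],
                                   [MarkRegion("chr1", 900, 1300)],
                                   mode="midpoint")
        assert ann.marked  # midpoint 1100 inside the gene

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(31)
        genes = []
        pos = 0
        for i in range(50):
            length = int(rng.integers(500, 3000))
            genes.append(gene(f"g{i}", pos, pos + length,
                              chrom=f"chr{i % 3 + 1}"))
            pos += length + int(rng.integers(100, 1000))
        regions = []
        for _ in range(200):
            s = int(rng.integers(0, pos))
            regions.append(MarkRegion(f"chr{int(rng.integers(1, 4))}", s,
                                      s + int(rng.integers(50, 800))))
        impl = associate_regions(genes, regions, mode="containment")
        for g, ann in zip(genes, impl):
            expect = [r for r in regions
                      if r.chrom == g.chrom and r.start >= g.start
                      and r.end <= g.end]
            assert sorted((r.start, r.end) for r in ann.regions) == \
                sorted((r.start, r.end) for r in expect)

    def test_adding_region_never_unmarks(self):
        genes = [gene("g", 100, 900)]
        regions = [MarkRegion("chr1", 200, 300)]
        before = associate_regions(genes, regions)[0].marked
        after = associate_regions(
            genes, regions + [MarkRegion("chr1", 400, 500)])[0].marked
        assert before and after


class TestFractionMarked:
    def test_extremes(self):
        anns = [GeneMarkAnnotation("a", [MarkRegion("chr1", 0, 10)]),
                GeneMarkAnnotation("b", [])]
        assert fraction_marked(["a"], anns) == 1.0
        assert fraction_marked(["b"], anns) == 0.0
        assert fraction_marked(["a", "b"], anns) == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            fraction_marked([], [])


def _flat_track(length=20000, value=2.0, step=10):
    return OccupancyTrack({"chr1": np.full(length // step, value)},
                          bin_size=step)


class TestMetagene:
    def test_constant_track_gives_flat_profile(self):
        track = _flat_track(value=3.5)
        genes = [gene("g1", 5000, 8000), gene("g2", 10000, 14000, strand="-")]
        profiles = metagene_profile(track, genes, anchor="TSS")
        np.testing.assert_allclose(profiles["all"].mean_signal, 3.5)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_gaussian_bump_downstream_of_tss(self, strand):
        step = 10
        arr = np.zeros(3000)
        g = gene("g", 10000, 20000, strand=strand)
        tss = 10000 if strand == "+" else 19999
        center = tss + 500 if strand == "+" else tss - 500
        coords = (np.arange(3000) + 0.5) * step
        arr += np.exp(-0.5 * ((coords - center) / 100) ** 2)
        track = OccupancyTrack({"chr1": arr}, bin_size=step)
        prof = metagene_profile(track, [g], anchor="TSS")["all"]
        assert abs(prof.peak_offset - 500) <= 50

    def test_minus_strand_profile_mirrors_plus(self):
        # mirror-symmetric track about the midpoint between the two anchors
        step = 10
        arr = np.zeros(4000)
        coords = (np.arange(4000) + 0.5) * step
        arr += np.exp(-0.5 * ((coords - 10500) / 80) ** 2)
        arr += np.exp(-0.5 * ((coords - 29500) / 80) ** 2)
        track = OccupancyTrack({"chr1": arr}, bin_size=step)
        gplus = gene("gp", 10000, 15000, strand="+")
        gminus = gene("gm", 25000, 30000, strand="-")
        pp = metagene_profile(track, [gplus], anchor="TSS")["all"]
        pm = metagene_profile(track, [gminus], anchor="TSS")["all"]
        np.testing.assert_allclose(pp.mean_signal, pm.mean_signal, atol=1e-9)

    def test_linearity_in_the_track(self):
        rng = np.random.default_rng(3)
        a1 = rng.gamma(2.0, 1.0, 4000)
        a2 = rng.gamma(2.0, 1.0, 4000)
        genes = [gene("g", 10000, 16000)]
        p1 = metagene_profile(OccupancyTrack({"chr1": a1}, 10), genes)["all"]
        p2 = metagene_profile(OccupancyTrack({"chr1": a2}, 10), genes)["all"]
        p12 = metagene_profile(OccupancyTrack({"chr1": a1 + a2}, 10),
                               genes)["all"]
        np.testing.assert_allclose(p12.mean_signal,
                                   p1.mean_signal + p2.mean_signal, rtol=1e-9)

    def test_out_of_bounds_gene_skipped(self):
        track = _flat_track(length=5000)
        with pytest.raises(KeyError):
            # the only gene is skipped, so no 'all' profile exists
            metagene_profile(track, [gene("g", 100, 1000)])["all"]

    def test_gene_classes_split_profiles(self):
        track = _flat_track(value=1.0)
        genes = [gene("g1", 5000, 9000), gene("g2", 10000, 15000)]
        profiles = metagene_profile(track, genes,
                                    classes={"g1": "hot", "g2": "cold"})
        assert set(profiles) == {"hot", "cold"}
        assert profiles["hot"].n_genes == 1


class TestEventDistances:
    def _event(self, alt=(100, 200)):
        t1 = TranscriptModel("t1", [(0, alt[1] + 300)])
        t2 = TranscriptModel("t2", [(0, alt[0]), (alt[1], alt[1] + 300)])
        g = GeneModel("g", "chr1", "+", 0, alt[1] + 300, [t1, t2])
        return enumerate_events(g)[0]

    def test_overlap_is_zero(self):
        ann = GeneMarkAnnotation("g", [MarkRegion("chr1", 150, 400)])
        assert event_region_distance(self._event(), ann) == 0

    def test_gap_arithmetic(self):
        ann = GeneMarkAnnotation("g", [MarkRegion("chr1", 500, 900)])
        assert event_region_distance(self._event(), ann) == 300

    def test_unmarked_gene_is_none(self):
        assert event_region_distance(self._event(),
                                     GeneMarkAnnotation("g", [])) is None

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError):
            event_region_distance(self._event(), GeneMarkAnnotation("h", []))

    def test_distance_zero_iff_overlap(self):
        rng = np.random.default_rng(4)
        ev = self._event()
        for _ in range(50):
            s = int(rng.integers(0, 400))
            e = s + int(rng.integers(1, 200))
            d = event_region_distance(
                ev, GeneMarkAnnotation("g", [MarkRegion("chr1", s, e)]))
            overlaps = s < ev.alt_region[1] and e > ev.alt_region[0]
            assert (d == 0) == overlaps


class TestDistanceComparison:
    def test_close_dependent_events_significant(self):
        u, p = compare_distance_distributions([0, 0, 10], [500, 600, 700])
        assert p < 0.05

    def test_identical_lists_near_half(self):
        _, p = compare_distance_distributions([5, 10, 20], [5, 10, 20])
        assert p == pytest.approx(0.5, abs=0.2)

    def test_matches_exact_enumeration_tie_free(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = rng.permutation(100)[:6]
            x, y = sorted(vals[:3]), sorted(vals[3:])
            _, p = compare_distance_distributions(list(x), list(y))
            assert p == pytest.approx(exact_mannwhitney_less(x, y), abs=1e-12)

    def test_swap_complements_p_under_normal_approximation(self):
        x, y = [1, 4, 9], [3, 7, 20]
        _, p = compare_distance_distributions(x, y, method="asymptotic")
        _, p_swapped = compare_distance_distributions(y, x,
                                                      method="asymptotic")
        assert p + p_swapped == pytest.approx(1.0, abs=0.15)

    def test_none_values_dropped(self):
        u, p = compare_distance_distributions([0, None, 5], [None, 40, 50])
        assert np.isfinite(p)
        with pytest.raises(ValueError):
            compare_distance_distributions([None], [1, 2])


class TestRegionWidths:
    def test_identical_sets(self):
        regions = [MarkRegion("chr1", 0, 300), MarkRegion("chr1", 50, 450)]
        s = compare_region_widths(regions, list(regions))
        assert s.median_a == s.median_b
        assert s.p_value == pytest.approx(1.0, abs=0.05)

    def test_doubled_widths(self):
        a = [MarkRegion("chr1", 0, w) for w in (100, 200, 300)]
        b = [MarkRegion("chr1", 0, 2 * w) for w in (100, 200, 300)]
        s = compare_region_widths(a, b)
        assert s.median_b == 2 * s.median_a
        assert s.ratio == 2.0


class TestTrackCorrelation:
    def test_scaled_track_perfectly_correlated(self):
        rng = np.random.default_rng(12)
        v = rng.gamma(2.0, 1.0, 5000)
        t1 = OccupancyTrack({"chr1": v}, 10)
        t2 = OccupancyTrack({"chr1": 2.0 * v}, 10)
        assert binned_track_correlation(t1, t2) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(13)
        t1 = OccupancyTrack({"chr1": rng.gamma(2.0, 1.0, 100_000)}, 10)
        t2 = OccupancyTrack({"chr1": rng.gamma(2.0, 1.0, 100_000)}, 10)
        assert abs(binned_track_correlation(t1, t2)) < 0.1

    def test_trimming_guards_against_extreme_bins(self):
        rng = np.random.default_rng(14)
        v1 = rng.gamma(2.0, 1.0, 100_000)
        v2 = rng.gamma(2.0, 1.0, 100_000)
        r_clean = binned_track_correlation(
            OccupancyTrack({"chr1": v1.copy()}, 10),
            OccupancyTrack({"chr1": v2.copy()}, 10))
        v1[5000:5100] += 1e5
        v2[5000:5100] += 1e5
        r_untrimmed = binned_track_correlation(
            OccupancyTrack({"chr1": v1}, 10),
            OccupancyTrack({"chr1": v2}, 10), trim_quantile=1.0)
        r_trimmed = binned_track_correlation(
            OccupancyTrack({"chr1": v1}, 10),
            OccupancyTrack({"chr1": v2}, 10))
        assert r_untrimmed > 0.9                      # outlier dominates
        assert r_trimmed == pytest.approx(r_clean, abs=0.02)

    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        track = OccupancyTrack({"chr1": rng.gamma(2.0, 1.0, 500)}, 10)
        path = tmp_path / "t.bedgraph"
        track.to_bedgraph(path)
        back = OccupancyTrack.from_bedgraph(path, bin_size=10)
        np.testing.assert_allclose(back.values["chr1"],
                                   track.values["chr1"], rtol=1e-4)
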