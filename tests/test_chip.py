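import numpy as np
import pytest

from parbseq.chip import (
    EnrichedRegion,
    ExtentUndefinedError,
    RatioUndefinedError,
    call_enriched_regions,
    enrichment_ratio,
    peak_asymmetry,
    peak_width,
    spreading_extent,
)
from parbseq.coverage import CoverageTrack, fragment_coverage
from parbseq.genome import GenomeSpec, PlantedSite, build_genome, make_palindromic_site
from parbseq.simulate import (
    OccupancyProfile,
    length_sampler,
    simulate_chip_fragments,
    simulate_occupancy,
)
from parbseq.workflows import nucleation_peak_width, wt_mutant_enrichment_ratio



def track(values, units="fold-enrichment"):
    return CoverageTrack(values=np.asarray(values, dtype=float), units=units)


class TestCallEnrichedRegions:
    def test_single_run(self):
        values = np.zeros(1000)
        values[100:300] = 10.0
        regions = call_enriched_regions(track(values), threshold=2.0, min_run=50, merge_gap=10)
        assert [(r.start, r.end) for r in regions] == [(100, 300)]
        assert regions[0].max_signal == 10.0

    def test_merge_across_small_gap(self):
        values = np.zeros(2000)
        values[100:300] = 5.0
        values[350:600] = 5.0
        regions = call_enriched_regions(track(values), 2.0, min_run=100, merge_gap=100)
        assert [(r.start, r.end) for r in regions] == [(100, 600)]

    def test_all_below_threshold(self):
        assert call_enriched_regions(track(np.ones(500)), 2.0) == []

    def test_wraps_across_origin(self):
        values = np.zeros(1000)
        values[950:] = 4.0
        values[:200] = 4.0
        regions = call_enriched_regions(track(values), 2.0, min_run=100, merge_gap=10)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (950, 1200)

    def test_idempotence_on_indicator_track(self):
        values = np.zeros(3000)
        values[200:700] = 3.0
        values[1500:2400] = 8.0
        regions = call_enriched_regions(track(values), 2.0, min_run=100, merge_gap=50)
        indicator = np.zeros(3000)
        for r in regions:
            indicator[np.arange(r.start, r.end) % 3000] = 1.0
        again = call_enriched_regions(track(indicator), 0.5, min_run=100, merge_gap=50)
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in regions]


class TestSpreadingExtent:
    def test_interval_length(self):
        region = EnrichedRegion(start=4000, end=6000, peak_summit=5000, max_signal=3.0, area=1.0)
        assert spreading_extent([region], 5000) == 2000

    def test_anchor_outside_all_regions(self):
        region = EnrichedRegion(start=4000, end=6000, peak_summit=5000, max_signal=3.0, area=1.0)
        with pytest.raises(ExtentUndefinedError):
            spreading_extent([region], 9000)

    def test_extent_scale_invariance(self):
        values = np.zeros(5000)
        values[1000:3000] = np.linspace(2.5, 4.5, 2000)
        for scale in (1.0, 7.0):
            regions = call_enriched_regions(track(values * scale), 2.0 * scale, 200, 100)
            assert spreading_extent(regions, 2000, 5000) == 2000

    def test_recovery_against_generator(self):
        """ChIP simulation around one site with per-side spreading s recovers
        an extent within 10% of 16 + 2s."""
        L, s = 50_000, 1200
        site = PlantedSite(
            start=25_000 - 8, sequence=make_palindromic_site("GTGAAA", "ACGT"), kd=30.0
        )
        genome = build_genome(GenomeSpec(length=L, circular=True), [site], seed=0)
        occ = simulate_occupancy(genome, genome.sites, s, [1.0], 0.0)
        frags = simulate_chip_fragments(occ, 60_000, seed=5)
        raw = fragment_coverage(frags, L, True)
        # uniform input expectation: total coverage / genome length
        input_level = raw.values.sum() / L
        fe = track(raw.values / input_level)
        regions = call_enriched_regions(fe, 2.0, min_run=200, merge_gap=500)
        extent = spreading_extent(regions, 25_000, L)
        assert extent == pytest.approx(16 + 2 * s, rel=0.10)

    def test_extent_monotone_in_spreading(self):
        """Recovered extent grows with the generator's spreading parameter."""
        L = 50_000
        site = PlantedSite(
            start=25_000 - 8, sequence=make_palindromic_site("GTGAAA", "ACGT"), kd=30.0
        )
        genome = build_genome(GenomeSpec(length=L, circular=True), [site], seed=0)
        extents = []
        for s in (200, 600, 1000, 1400, 1800):
            occ = simulate_occupancy(genome, genome.sites, s, [1.0], 0.0)
            frags = simulate_chip_fragments(occ, 20_000, seed=9)
            raw = fragment_coverage(frags, L, True)
            fe = track(raw.values / (raw.values.sum() / L))
            regions = call_enriched_regions(fe, 2.0, min_run=100, merge_gap=500)
            extents.append(spreading_extent(regions, 25_000, L))
        assert extents == sorted(extents)


class TestPeakWidth:
    def test_nucleation_fixture_2l_minus_w(self):
        """Fixed-length-208 fragments fully containing a 16-bp site give
        coverage support of exactly 2*208 - 16 = 400 bp."""
        assert nucleation_peak_width(fragment_length=208) == 400

    def test_triangular_support(self):
        values = np.zeros(300)
        values[:100] = np.concatenate([np.arange(1, 51), np.arange(50, 0, -1)])
        t = CoverageTrack(values=values)
        assert peak_width(t, summit=49, background=0.0, circular=False) == 100

    def test_background_above_signal_rejected(self):
        t = CoverageTrack(values=np.ones(10))
        with pytest.raises(ValueError):
            peak_width(t, 5, background=2.0)

    def test_width_scale_invariance(self):
        values = np.zeros(500)
        values[200:260] = np.random.default_rng(0).random(60) + 0.5
        for scale in (1.0, 11.0):
            t = CoverageTrack(values=values * scale)
            assert peak_width(t, 230, background=0.0) == 60


class TestPeakAsymmetry:
    def test_symmetric_generator_peak(self):
        """Symmetric occupancy yields asymmetry ~1 (within 5%)."""
        L = 30_000
        site = PlantedSite(
            start=15_000 - 8, sequence=make_palindromic_site("GTGAAA", "ACGT"), kd=30.0
        )
        genome = build_genome(GenomeSpec(length=L, circular=True), [site], seed=0)
        occ = simulate_occupancy(genome, genome.sites, 992, [1.0], 0.0)
        frags = simulate_chip_fragments(occ, 100_000, seed=6)
        raw = fragment_coverage(frags, L, True)
        ratio = peak_asymmetry(raw, (site.start, site.end), flank=2000)
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_doubled_left_occupancy_doubles_ratio(self):
        """Expected coverage is linear in occupancy, so doubling the
        left-flank occupancy doubles the area ratio."""
        L = 20_000
        values = np.zeros(L)
        values[9000:10_000] = 0.8   # left flank
        values[10_000:10_016] = 1.0
        values[10_016:11_016] = 0.4  # right flank
        frags = simulate_chip_fragments(
            OccupancyProfile(values), 80_000, length_sampler("fixed", length=100), seed=7
        )
        raw = fragment_coverage(frags, L, True)
        ratio = peak_asymmetry(raw, (10_000, 10_016), flank=900)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_zero_right_area_flagged(self):
        values = np.zeros(1000)
        values[100:200] = 5.0
        t = CoverageTrack(values=values)
        with pytest.raises(RatioUndefinedError):
            peak_asymmetry(t, (400, 416), flank=100)


class TestEnrichmentRatio:
    def test_scale_factor(self):
        b = track(np.arange(1.0, 11.0), units="RPBPM")
        a = track(5 * b.values, units="RPBPM")
        assert enrichment_ratio(a, b, (0, 10), circular=False) == pytest.approx(5.0)

    def test_identity(self):
        a = track(np.arange(1.0, 11.0), units="RPBPM")
        assert enrichment_ratio(a, a, (2, 8), circular=False) == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        a = track(np.ones(10), units="RPBPM")
        b = track(np.zeros(10), units="RPBPM")
        with pytest.raises(RatioUndefinedError):
            enrichment_ratio(a, b, (0, 10), circular=False)

    def test_units_must_match(self):
        a = track(np.ones(10), units="RPBPM")
        b = track(np.ones(10), units="raw")
        with pytest.raises(ValueError, match="normalised"):
            enrichment_ratio(a, b, (0, 10))

    def test_generator_amplitude_recovery(self):
        """A wild-type (spreading, amplitude 1.0) versus nucleation-only
        mutant (amplitude 0.2) comparison recovers ~5-fold."""
        ratio = wt_mutant_enrichment_ratio(n=25_000, seed=15)
        assert ratio == pytest.approx(5.0, rel=0.15)
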