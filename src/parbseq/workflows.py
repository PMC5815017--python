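"""End-to-end analysis workflows on generator-defined data sets.

Each function wires the synthetic-data generator to the corresponding
analysis pipeline under the study conditions the package emulates and
returns the headline quantity: the called site length from the exhaustive
fragment fixture, the recovered spreading extents, the wild-type versus
spreading-deficient-mutant enrichment ratio, the permissive-zone width
and the fitted equilibrium Kd values. They double as worked examples of
how the modules compose.

Genome sizes are scaled to desk-top problem sizes (tens to hundreds of
kb for fragment-level workflows, 4 Mb for the binned Tn-seq workflow):
the analyses are local to the parS neighbourhood, so shrinking the
uninvolved genomic background only deepens per-base coverage without
changing the measured quantities.
"""

from __future__ import annotations

import numpy as np

from parbseq import chip, coverage, idap, spr, tnseq
from parbseq.genome import (
    Genome,
    GenomeSpec,
    PlantedSite,
    build_genome,
    default_genome,
    default_sites,
    make_palindromic_site,
)
from parbseq.simulate import (
    FitnessLandscape,
    FragmentRecord,
    OccupancyProfile,
    length_sampler,
    simulate_chip_fragments,
    simulate_idap_fragments,
    simulate_occupancy,
    simulate_spr_titration,
    simulate_tn_library,
)

#: per-side spreading (bp) reproducing a 2-kb single-site occupied span
SINGLE_SITE_SPREADING = 992
#: per-side spreading (bp) that makes the five-strong-site union span 10 kb
CLUSTER_SPREADING = 2992


def exhaustive_site_fragments(
    genome_length: int = 10_000,
    site_start: int = 5_000,
    min_length: int = 50,
    max_length: int = 200,
) -> tuple[Genome, list[FragmentRecord]]:
    """A noiseless affinity-capture fixture: every possible retained fragment.

    Enumerates ALL fragments with lengths ``min_length..max_length`` and
    every start position that fully contains the planted 16-bp site --
    the deterministic limit of the capture experiment.
    """
    site = PlantedSite(
        start=site_start, sequence=make_palindromic_site("GTGAAA", "ACGT"), kd=30.0, label="parS"
    )
    genome = build_genome(GenomeSpec(length=genome_length, circular=True), [site], seed=0)
    fragments = [
        FragmentRecord(start, length, "idap")
        for length in range(min_length, max_length + 1)
        for start in range(site.start + site.width - length, site.start + 1)
        if 0 <= start
    ]
    return genome, fragments


def exhaustive_call(genome_length: int = 10_000, site_start: int = 5_000) -> idap.BindingCall:
    """Call the planted site from the exhaustive fragment fixture.

    Summit pairing with rightmost-max upper / leftmost-max lower
    tie-breaking recovers the site at exact nucleotide resolution; the
    call's inclusive length equals the planted 16 bp.
    """
    genome, fragments = exhaustive_site_fragments(genome_length, site_start)
    calls = idap.call_sites(fragments, None, genome, min_height=1.0)
    assert len(calls) == 1
    return calls[0]


def seven_site_calls(n: int = 200_000, seed: int = 7) -> tuple[Genome, list[idap.BindingCall]]:
    """Affinity-capture site calling on the default seven-site genome.

    Simulates ``n`` retained fragments at 320 nM protein with a small
    nonspecific background retention and calls sites with default
    parameters.
    """
    genome = default_genome(seed=seed)
    fragments = simulate_idap_fragments(
        genome, protein_conc=320.0, n=n, seed=seed, background_prob=0.001
    )
    return genome, idap.call_sites(fragments, None, genome)


def nucleation_peak_width(fragment_length: int = 208, site_start: int = 5_000) -> int:
    """Support width of a pure nucleation peak built from fixed-length fragments.

    All fragments of length L fully containing a site of width w produce a
    coverage support of exactly 2L - w bp (400 bp for L = 208, w = 16).
    """
    genome, fragments = exhaustive_site_fragments(
        site_start=site_start, min_length=fragment_length, max_length=fragment_length
    )
    track = coverage.fragment_coverage(fragments, genome.length, genome.circular)
    return chip.peak_width(track, summit=site_start + 8, background=0.0)


def _chip_fold_enrichment(
    genome_length: int,
    occupancy: OccupancyProfile,
    n: int,
    seed: int,
) -> coverage.CoverageTrack:
    chip_frags = simulate_chip_fragments(occupancy, n, seed=seed)
    input_frags = simulate_chip_fragments(
        OccupancyProfile(np.ones(genome_length)), n, seed=seed + 1, source="input"
    )
    chip_track = coverage.normalize_rpbpm(
        coverage.fragment_coverage(chip_frags, genome_length, True), len(chip_frags)
    )
    input_track = coverage.normalize_rpbpm(
        coverage.fragment_coverage(input_frags, genome_length, True), len(input_frags)
    )
    return coverage.fold_enrichment(chip_track, input_track)


def single_site_extent(
    n: int = 100_000,
    seed: int = 11,
    genome_length: int = 100_000,
    spreading: int = SINGLE_SITE_SPREADING,
) -> int:
    """Recovered spreading extent (bp) around one isolated strong site.

    Simulates ChIP plus input libraries under the single-site occupancy
    model (per-side spreading chosen so the occupied span is 2 kb), calls
    regions at >= 2-fold enrichment and measures the extent at the site.
    """
    center = genome_length // 2
    site = PlantedSite(
        start=center - 8, sequence=make_palindromic_site("GTGAAA", "CCGT"), kd=30.0, label="parS3"
    )
    genome = build_genome(GenomeSpec(length=genome_length, circular=True), [site], seed=0)
    occ = simulate_occupancy(genome, genome.sites, spreading, [1.0], 0.0)
    fe = _chip_fold_enrichment(genome_length, occ, n, seed)
    regions = chip.call_enriched_regions(fe, threshold=2.0, min_run=200, merge_gap=500)
    return chip.spreading_extent(regions, center, genome_length)


def cluster_extent(
    n: int = 200_000,
    seed: int = 21,
    genome_length: int = 300_000,
    spreading: int = CLUSTER_SPREADING,
) -> int:
    """Recovered extent (bp) of the enriched region around the five-site cluster.

    The five strong sites sit at 1-kb spacing inside a 5-kb window; with
    per-side spreading of ~3 kb their occupied spans merge into a single
    10-kb region, mirroring the extended ori-proximal enrichment domain.
    """
    center = genome_length // 2
    sites = default_sites(cluster_center=center, strong_only=True)
    genome = build_genome(GenomeSpec(length=genome_length, circular=True), sites, seed=0)
    occ = simulate_occupancy(genome, sites, spreading, [1.0] * len(sites), 0.0)
    fe = _chip_fold_enrichment(genome_length, occ, n, seed)
    regions = chip.call_enriched_regions(fe, threshold=2.0, min_run=200, merge_gap=500)
    return chip.spreading_extent(regions, center, genome_length)


def wt_mutant_enrichment_ratio(
    n: int = 100_000,
    seed: int = 31,
    genome_length: int = 50_000,
    mutant_amplitude: float = 0.2,
) -> float:
    """Fold-ratio of ChIP signal at the parS cluster: wild type vs mutant.

    The wild type follows the spreading occupancy model at amplitude 1.0
    with mean-occupancy fragment retention. The spreading-deficient,
    less-stable mutant nucleates only (occupancy ``mutant_amplitude`` on
    the site intervals, zero elsewhere) and is captured crosslink-style:
    any fragment overlapping a nucleation footprint is retained with
    probability equal to the site occupancy (max-occupancy retention).
    Both libraries use 150-bp fragments, are drawn from equal input
    material and are normalised per proposed template (yield-preserving
    RPBPM); the ratio of mean signal over the parS site intervals then
    recovers the occupancy amplitude ratio.
    """
    center = genome_length // 2
    sites = default_sites(cluster_center=center, strong_only=True)
    genome = build_genome(GenomeSpec(length=genome_length, circular=True), sites, seed=0)
    lengths = length_sampler("fixed", length=150)
    occ = simulate_occupancy(genome, sites, CLUSTER_SPREADING, [1.0] * len(sites), 0.0)
    wt = simulate_chip_fragments(occ, n, frag_length_sampler=lengths, seed=seed)
    mut_occ = simulate_occupancy(genome, sites, 0, [mutant_amplitude] * len(sites), 0.0)
    mut = simulate_chip_fragments(
        mut_occ, n, frag_length_sampler=lengths, seed=seed + 1, retention="max"
    )
    wt_track = coverage.normalize_rpbpm(
        coverage.fragment_coverage(wt, genome_length, True), wt.n_proposed
    )
    mut_track = coverage.normalize_rpbpm(
        coverage.fragment_coverage(mut, genome_length, True), mut.n_proposed
    )
    # equal-width site intervals: the pooled ratio is the ratio of mean signals
    per_site_wt = np.array(
        [wt_track.values[s.start : s.start + s.width].mean() for s in sites]
    )
    per_site_mut = np.array(
        [mut_track.values[s.start : s.start + s.width].mean() for s in sites]
    )
    return float(per_site_wt.mean() / per_site_mut.mean())


def permissive_zone_width(
    n: int = 200_000,
    seed: int = 41,
    genome_length: int = 4_000_000,
    plateau_width: int = 500_000,
    plateau_level: float = 10.0,
    cluster_center: int = 8_000,
    bin: int = 10_000,
) -> int:
    """Width (bp) of the widest permissive zone recovered by the Tn-seq pipeline.

    The parS+ library is drawn from a plateau fitness landscape (10x
    baseline) centred on the native cluster; the parS- control from a
    uniform landscape. Frequencies are binned at 10 kb, compared as a
    log10 ratio and thresholded at 0.
    """
    weights = np.ones(genome_length)
    idx = (
        np.arange(cluster_center - plateau_width // 2, cluster_center + plateau_width - plateau_width // 2)
        % genome_length
    )
    weights[idx] = plateau_level
    plus = simulate_tn_library(FitnessLandscape(weights), n, seed=seed, label="parS_plus")
    minus = simulate_tn_library(
        FitnessLandscape(np.ones(genome_length)), n, seed=seed + 1, label="parS_minus"
    )
    track = tnseq.log10_ratio_track(
        tnseq.bin_insertions(plus, genome_length, bin),
        tnseq.bin_insertions(minus, genome_length, bin),
        plus.total_insertions,
        minus.total_insertions,
        bin=bin,
        genome_length=genome_length,
    )
    zones = [z for z in tnseq.call_zones(track) if z.kind == tnseq.PERMISSIVE]
    return max(z.length for z in zones)


def reference_kd_fit(kd: float, rmax: float = 100.0) -> spr.KdFit:
    """Fit the 1:1 isotherm to a noise-free titration at the nine-point grid."""
    series = simulate_spr_titration(kd=kd, rmax=rmax, noise_sd=0.0)
    return spr.fit_kd(series)
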