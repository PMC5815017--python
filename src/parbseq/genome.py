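"""Toy genomes with planted palindromic parS sites.

Coordinates are 0-based, half-open everywhere. Genomes may be circular,
in which case all interval arithmetic wraps modulo the genome length.
The default configuration mirrors a small bacterial chromosome with the
centromeric parS cluster a few kb from the origin of replication: a 1-Mb
circular genome, ori at position 0 and a cluster of seven 16-bp parS
sites centred ~7.5 kb from ori (five strong sites within a 5-kb window
flanked by two weak ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")

PARS_WIDTH = 16
#: conserved second half of the parS palindrome
PARS_HALF_SITE = "GTGAAA"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    _validate_nt(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_nt(seq: str) -> None:
    if not seq or not set(seq) <= _ALPHABET:
        raise ValueError(f"sequence must be a nonempty string over A/C/G/T, got {seq!r}")


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of a toy (possibly circular) genome.

    Parameters
    ----------
    length:
        Genome length in bp.
    circular:
        Whether interval arithmetic wraps modulo ``length``.
    origin_position:
        Coordinate of the replication origin (ori).
    native_cluster_position:
        Coordinate of the centre of the native parS cluster.
    sequence:
        Optional explicit nucleotide sequence of exactly ``length`` bases.
    """

    length: int
    circular: bool = True
    origin_position: int = 0
    native_cluster_position: int = 0
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be >= 1")
        if not 0 <= self.origin_position < self.length:
            raise ValueError("origin_position must lie in [0, length)")
        if not 0 <= self.native_cluster_position < self.length:
            raise ValueError("native_cluster_position must lie in [0, length)")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != genome length {self.length}"
            )


@dataclass(frozen=True)
class PlantedSite:
    """A planted protein-binding site (by default a 16-bp parS palindrome).

    ``kd`` is the equilibrium dissociation constant of the site for the
    binding protein, in nM; it parameterises the retention probability of
    site-containing fragments in the affinity-capture simulator.
    """

    start: int
    sequence: str
    kd: float
    width: int = PARS_WIDTH
    label: str = ""

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("site width must be >= 1")
        if self.kd <= 0:
            raise ValueError("site kd must be > 0 nM")
        _validate_nt(self.sequence)
        if len(self.sequence) != self.width:
            raise ValueError(
                f"site sequence length {len(self.sequence)} != width {self.width}"
            )

    @property
    def end(self) -> int:
        """Exclusive end coordinate (may exceed genome length before wrapping)."""
        return self.start + self.width


@dataclass(frozen=True)
class Genome:
    """A realised genome: spec (with sequence filled in) plus planted sites."""

    spec: GenomeSpec
    sites: tuple[PlantedSite, ...] = ()

    @property
    def length(self) -> int:
        return self.spec.length

    @property
    def circular(self) -> bool:
        return self.spec.circular

    @property
    def sequence(self) -> str:
        assert self.spec.sequence is not None
        return self.spec.sequence

    def fetch(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``, wrapping on circular genomes."""
        if end < start:
            raise ValueError("end must be >= start")
        n = self.length
        span = end - start
        if span > n:
            raise ValueError("requested span exceeds genome length")
        if self.circular:
            start %= n
            return (self.sequence + self.sequence)[start : start + span]
        if start < 0 or end > n:
            raise ValueError(f"interval [{start}, {end}) outside linear genome of length {n}")
        return self.sequence[start:end]


def make_palindromic_site(half_site: str, spacer: str) -> str:
    """Assemble a 16-bp palindromic site from a conserved 6-bp half-site.

    The site is ``revcomp(half_site) + spacer + half_site`` so that its
    outer 6-mers are reverse complements of one another and the last six
    bases equal ``half_site`` (the conserved half of the palindrome).
    """
    _validate_nt(half_site)
    _validate_nt(spacer)
    if len(half_site) != 6:
        raise ValueError(f"half_site must be a 6-mer, got length {len(half_site)}")
    if len(spacer) != 4:
        raise ValueError(f"spacer must be a 4-mer, got length {len(spacer)}")
    return reverse_complement(half_site) + spacer + half_site


def _unwrapped_intervals(site: PlantedSite, length: int, circular: bool) -> list[tuple[int, int]]:
    """Concrete [start, end) pieces a site occupies on the base coordinate line."""
    s, e = site.start % length, site.start % length + site.width
    if e <= length:
        return [(s, e)]
    if not circular:
        raise ValueError(
            f"site {site.label or site.start} [{site.start}, {site.end}) extends past "
            f"the end of a linear genome of length {length}"
        )
    return [(s, length), (0, e - length)]


def _sites_overlap(a: PlantedSite, b: PlantedSite, length: int, circular: bool) -> bool:
    for sa, ea in _unwrapped_intervals(a, length, circular):
        for sb, eb in _unwrapped_intervals(b, length, circular):
            if sa < eb and sb < ea:
                return True
    return False


def build_genome(
    spec: GenomeSpec, sites: Sequence[PlantedSite], seed: int
) -> Genome:
    """Construct a genome sequence with each site's 16-mer planted at its start.

    Bases outside planted sites are drawn i.i.d. uniform over A/C/G/T from
    ``seed`` (unless ``spec.sequence`` is given, in which case sites are
    planted into that sequence). Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If two sites overlap (both are named in the message) or a site
        extends past the end of a linear genome.
    """
    sites = tuple(sites)
    n = spec.length
    for site in sites:
        if not 0 <= site.start < n:
            raise ValueError(f"site start {site.start} outside genome of length {n}")
        _unwrapped_intervals(site, n, spec.circular)  # raises for linear overhang
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            if _sites_overlap(a, b, n, spec.circular):
                raise ValueError(
                    f"planted sites overlap: {a.label or a.start} "
                    f"[{a.start}, {a.end}) and {b.label or b.start} [{b.start}, {b.end})"
                )
    if spec.sequence is not None:
        seq = np.frombuffer(spec.sequence.encode(), dtype="S1").copy()
    else:
        rng = np.random.default_rng(seed)
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)
    for site in sites:
        planted = np.frombuffer(site.sequence.encode(), dtype="S1")
        off = 0
        for s, e in _unwrapped_intervals(site, n, spec.circular):
            seq[s:e] = planted[off : off + (e - s)]
            off += e - s
    realised = replace(spec, sequence=seq.tobytes().decode())
    return Genome(spec=realised, sites=sites)


# ---------------------------------------------------------------------------
# Default study-like configuration
# ---------------------------------------------------------------------------

#: (label, offset of site start from cluster window origin, spacer 4-mer, kd in nM)
#: Five strong sites (tens of nM, within a 5-kb window) flanked by two weak
#: sites (>= 1 uM). The strong/weak split mirrors SPR affinities measured for
#: the seven candidate sites; the 16-mers themselves are synthetic palindromes
#: built around the conserved GTGAAA half-site.
_DEFAULT_SITE_TABLE = (
    ("parS1", -3500, "ACTA", 2000.0),
    ("parS2", -2000, "ACGT", 50.0),
    ("parS3", -1000, "CCGT", 30.0),
    ("parS4", 0, "AGGT", 30.0),
    ("parS5", 1000, "ACGG", 40.0),
    ("parS6", 3500, "TCTA", 1000.0),
    ("parS7", 2000, "TCGT", 60.0),
)

STRONG_SITE_LABELS = ("parS2", "parS3", "parS4", "parS5", "parS7")


def default_sites(cluster_center: int = 7500, strong_only: bool = False) -> tuple[PlantedSite, ...]:
    """Seven default parS sites arranged around ``cluster_center``.

    Strong sites sit at 1-kb spacing spanning a ~4-kb window (first start to
    last end = 4016 bp), weak sites 1.5 kb outside on either flank.
    """
    sites = []
    for label, offset, spacer, kd in _DEFAULT_SITE_TABLE:
        if strong_only and label not in STRONG_SITE_LABELS:
            continue
        # each site interval is centred at cluster_center + offset
        sites.append(
            PlantedSite(
                start=(cluster_center + offset - PARS_WIDTH // 2),
                sequence=make_palindromic_site(PARS_HALF_SITE, spacer),
                kd=kd,
                label=label,
            )
        )
    return tuple(sorted(sites, key=lambda s: s.start))


def default_genome(
    length: int = 1_000_000,
    cluster_center: int = 7500,
    seed: int = 0,
    strong_only: bool = False,
) -> Genome:
    """The default 1-Mb circular toy genome with the seven-site parS cluster.

    ori is at position 0 and the native cluster centre ~7.5 kb away,
    mirroring the ori-proximal clustering of natural parS sites. A larger
    chromosome-scale configuration is obtained by passing e.g.
    ``length=4_040_000``.
    """
    spec = GenomeSpec(
        length=length,
        circular=True,
        origin_position=0,
        native_cluster_position=cluster_center,
    )
    return build_genome(spec, default_sites(cluster_center, strong_only=strong_only), seed=seed)
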