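"""Generators for synthetic ChIP, affinity-capture, Tn5 and SPR data.

The generators emulate the statistical structure of the corresponding
wet-lab assays on a toy genome with planted parS sites:

* ChIP fragments are sheared DNA sampled uniformly and retained with
  probability equal to the mean protein occupancy over the fragment, so
  libraries reflect a nucleation-plus-spreading occupancy profile.
* Affinity-capture (IDAP) fragments are retained only when they fully
  contain a planted site, with retention probability given by the 1:1
  binding isotherm theta = [P] / (Kd + [P]) of the strongest contained
  site.
* Tn5 insertion positions are drawn proportionally to a positional
  fitness landscape (insertions surviving selection).
* SPR responses follow a hyperbolic 1:1 binding curve with additive
  Gaussian noise.

Every generator is deterministic given its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from parbseq.genome import Genome, PlantedSite
from parbseq.spr import TitrationSeries

#: the nine-point protein concentration grid (nM) used for Kd titrations
DEFAULT_SPR_CONCENTRATIONS_NM = (6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0)

_MAX_BATCH = 4_000_000


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentRecord:
    """A double-stranded DNA fragment: 0-based start, length in bp."""

    start: int
    length: int
    source: str = "chip"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fragment length must be >= 1")
        if self.start < 0:
            raise ValueError("fragment start must be >= 0")


class FragmentSample(list):
    """A list of :class:`FragmentRecord` annotated with sampling effort.

    ``n_proposed`` is the number of uniformly proposed template fragments
    the rejection sampler consumed to retain the records; it measures
    pull-down yield (retained / proposed) and supports yield-preserving
    depth normalisation across libraries made from equal input material.
    """

    def __init__(self, records=(), n_proposed: int = 0):
        super().__init__(records)
        self.n_proposed = int(n_proposed)


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-base relative protein occupancy in [0, 1]."""

    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("occupancy must be a 1-D array with >= 1 entry")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("occupancy values must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FitnessLandscape:
    """Per-base multiplicative insertion-survival weight (>= 0)."""

    relative_fitness: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.relative_fitness, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("landscape must be a 1-D array with >= 1 entry")
        if np.any(w < 0):
            raise ValueError("fitness weights must be >= 0")
        object.__setattr__(self, "relative_fitness", w)

    def __len__(self) -> int:
        return self.relative_fitness.size


@dataclass(frozen=True)
class InsertionLibrary:
    """Aggregated Tn5 insertion positions with per-position read counts."""

    positions: np.ndarray
    counts: np.ndarray
    label: str = "parS_plus"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        cnt = np.asarray(self.counts, dtype=np.int64)
        if pos.shape != cnt.shape or pos.ndim != 1:
            raise ValueError("positions and counts must be 1-D arrays of equal length")
        if np.any(cnt < 1):
            raise ValueError("per-position counts must be >= 1")
        if np.any(pos < 0):
            raise ValueError("positions must be >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "counts", cnt)

    @property
    def total_insertions(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Fragment length samplers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthSampler:
    """A named fragment-length distribution with a vectorised ``sample``."""

    kind: str
    params: tuple
    _draw: Callable = field(repr=False, compare=False, default=None)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self._draw(rng, size)


def length_sampler(kind: str, **params) -> LengthSampler:
    """Build a fragment-length sampler.

    Supported kinds (lengths in bp, always >= 1):

    * ``fixed``: ``length``
    * ``uniform``: integer-uniform on ``[low, high]`` inclusive
    * ``truncnorm``: normal(``mean``, ``sd``) truncated to ``[low, high]``
      and rounded to integers
    """
    if kind == "fixed":
        length = int(params["length"])
        if length < 1:
            raise ValueError("fixed length must be >= 1")
        draw = lambda rng, size: np.full(size, length, dtype=np.int64)
        return LengthSampler("fixed", (length,), draw)
    if kind == "uniform":
        low, high = int(params["low"]), int(params["high"])
        if not 1 <= low <= high:
            raise ValueError("need 1 <= low <= high")
        draw = lambda rng, size: rng.integers(low, high + 1, size=size, dtype=np.int64)
        return LengthSampler("uniform", (low, high), draw)
    if kind == "truncnorm":
        mean, sd = float(params["mean"]), float(params["sd"])
        low = int(params.get("low", 1))
        high = int(params.get("high", round(mean + 6 * sd)))
        if not 1 <= low <= high or sd <= 0:
            raise ValueError("need 1 <= low <= high and sd > 0")

        def draw(rng, size):
            # rejection against the truncation window; vectorised refills
            out = np.empty(size, dtype=np.int64)
            filled = 0
            while filled < size:
                cand = np.rint(rng.normal(mean, sd, size=2 * (size - filled) + 16))
                cand = cand[(cand >= low) & (cand <= high)].astype(np.int64)
                take = min(cand.size, size - filled)
                out[filled : filled + take] = cand[:take]
                filled += take
            return out

        return LengthSampler("truncnorm", (mean, sd, low, high), draw)
    raise ValueError(f"unknown length sampler kind {kind!r}")


def chip_default_lengths() -> LengthSampler:
    """Sheared-chromatin default: ~150 bp mean, all below 1 kb."""
    return length_sampler("truncnorm", mean=150, sd=50, low=50, high=900)


def idap_default_lengths() -> LengthSampler:
    """Size-selected sonication default: uniform 200-500 bp."""
    return length_sampler("uniform", low=200, high=500)


# ---------------------------------------------------------------------------
# Occupancy model
# ---------------------------------------------------------------------------


def simulate_occupancy(
    genome: Union[Genome, int],
    sites: Sequence[PlantedSite],
    spreading_extent_per_side: int,
    site_amplitudes: Sequence[float],
    background: float = 0.0,
    circular: Optional[bool] = None,
) -> OccupancyProfile:
    """Nucleation-plus-spreading occupancy profile.

    Occupancy equals the site amplitude over each site interval and decays
    linearly toward ``background`` over ``spreading_extent_per_side`` bases
    on each flank, reaching background one base beyond the extent, so the
    above-background support of an isolated site is exactly
    ``width + 2 * spreading_extent_per_side`` bases. Overlapping
    contributions combine by maximum. ``spreading_extent_per_side = 0``
    gives the nucleation-only limit.

    ``genome`` may be a :class:`~parbseq.genome.Genome` or a plain length
    (then ``circular`` controls wrapping; default circular).
    """
    if isinstance(genome, Genome):
        n, circ = genome.length, genome.circular
    else:
        n, circ = int(genome), True if circular is None else bool(circular)
    sites = list(sites)
    amplitudes = [float(a) for a in site_amplitudes]
    if len(amplitudes) != len(sites):
        raise ValueError("need one amplitude per site")
    if any(not 0 <= a <= 1 for a in amplitudes):
        raise ValueError("amplitudes must lie in [0, 1]")
    if sites and background >= min(amplitudes):
        raise ValueError("background must be below the smallest site amplitude")
    if not 0 <= background <= 1:
        raise ValueError("background must lie in [0, 1]")
    extent = int(spreading_extent_per_side)
    if extent < 0:
        raise ValueError("spreading extent must be >= 0")

    values = np.full(n, float(background))
    for site, amp in zip(sites, amplitudes):
        w = site.width
        # single-site footprint: [flank ramp][site plateau][flank ramp]
        ramp = background + (amp - background) * (1.0 - np.arange(extent, 0, -1) / (extent + 1.0))
        footprint = np.concatenate([ramp, np.full(w, amp), ramp[::-1]])
        idx = np.arange(site.start - extent, site.start + w + extent)
        if circ:
            idx %= n
        else:
            keep = (idx >= 0) & (idx < n)
            idx, footprint = idx[keep], footprint[keep]
        np.maximum.at(values, idx, footprint)
    desc = (
        f"{len(sites)} site(s), per-side spreading {extent} bp, "
        f"amplitudes {amplitudes}, background {background}"
    )
    return OccupancyProfile(values=values, description=desc)


# ---------------------------------------------------------------------------
# Fragment library samplers
# ---------------------------------------------------------------------------


def _collect(
    records: list,
    starts: np.ndarray,
    lengths: np.ndarray,
    accept: np.ndarray,
    n: int,
    n_proposed: int,
    batch: int,
    L: int,
    source: str,
) -> tuple[int, int]:
    """Append accepted proposals to ``records`` up to the n-th retained fragment.

    Proposals are counted exactly up to (and including) the one that yields
    the n-th retained fragment, so retained/proposed is an unbiased
    pull-down yield. Returns the updated ``(n_proposed, next_batch_size)``.
    """
    hits = np.nonzero(accept)[0]
    if not records and not hits.size and n_proposed >= 20_000_000:
        raise RuntimeError(
            "no proposal retained after 20M attempts: the acceptance "
            "probability appears to be zero under these parameters"
        )
    needed = n - len(records)
    if hits.size >= needed:
        hits = hits[:needed]
        n_proposed += int(hits[-1]) + 1
    else:
        n_proposed += batch
    for i in hits:
        records.append(FragmentRecord(int(starts[i] % L), int(lengths[i]), source))
    if hits.size == 0:
        nxt = min(batch * 2, _MAX_BATCH)
    else:
        remaining = n - len(records)
        nxt = min(max(int(1.2 * remaining * batch / hits.size) + 64, 1024), _MAX_BATCH)
    return n_proposed, nxt


def _propose_starts(
    rng: np.random.Generator, lengths: np.ndarray, n: int, circular: bool
) -> np.ndarray:
    if circular:
        return rng.integers(0, n, size=lengths.size, dtype=np.int64)
    # uniform over the valid start range for each proposed length
    u = rng.random(lengths.size)
    return np.floor(u * (n - lengths + 1)).astype(np.int64)


def _window_max(doubled: np.ndarray, starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Exact max occupancy over each proposed window, grouped by length."""
    out = np.empty(starts.size)
    for ell in np.unique(lengths):
        sel = lengths == ell
        windows = np.lib.stride_tricks.sliding_window_view(doubled, int(ell))
        out[sel] = windows.max(axis=1)[starts[sel]]
    return out


def simulate_chip_fragments(
    occupancy: OccupancyProfile,
    n: int,
    frag_length_sampler: Optional[LengthSampler] = None,
    seed: int = 0,
    circular: bool = True,
    source: str = "chip",
    retention: str = "mean",
) -> FragmentSample:
    """Draw ``n`` immunoprecipitated fragments from an occupancy profile.

    Template fragments are proposed with uniform start and sampled length
    and retained with probability given by the occupancy over the fragment;
    proposing repeats until ``n`` fragments are retained. The returned
    sample records the total number of proposals (``n_proposed``), an
    unbiased measure of pull-down yield.

    ``retention`` selects how a fragment's occupancy summarises:

    * ``"mean"`` (default) -- mean occupancy over the fragment; appropriate
      for proteins spread over spans comparable to or larger than the
      fragment length.
    * ``"max"`` -- maximum occupancy over the fragment; appropriate for
      crosslink-then-shear capture of a point-like nucleation complex,
      where the complex travels with any fragment overlapping its
      footprint rather than being diluted by fragment length. Window
      maxima are recomputed per distinct fragment length, so this mode is
      intended for fixed or few-valued length samplers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if retention not in ("mean", "max"):
        raise ValueError("retention must be 'mean' or 'max'")
    values = occupancy.values
    if values.max() == 0:
        raise ValueError("occupancy is identically zero: acceptance probability is 0 everywhere")
    sampler = frag_length_sampler or chip_default_lengths()
    L = values.size
    # prefix sums over the doubled profile make circular window means O(1)
    doubled = np.concatenate([values, values]) if circular else values
    csum = np.concatenate([[0.0], np.cumsum(doubled)])
    rng = np.random.default_rng(seed)
    records: list[FragmentRecord] = []
    n_proposed = 0
    batch = min(max(4 * n, 10_000), _MAX_BATCH)
    while len(records) < n:
        lengths = np.clip(sampler.sample(rng, batch), 1, L)
        starts = _propose_starts(rng, lengths, L, circular)
        if retention == "mean":
            prob = (csum[starts + lengths] - csum[starts]) / lengths
        else:
            prob = _window_max(doubled, starts, lengths)
        accept = rng.random(batch) < prob
        n_proposed, batch = _collect(
            records, starts, lengths, accept, n, n_proposed, batch, L, source
        )
    return FragmentSample(records, n_proposed)


def isotherm_retention(kd: float, protein_conc: float) -> float:
    """Fraction of site-containing fragments retained: [P] / (Kd + [P])."""
    if kd <= 0 or protein_conc <= 0:
        raise ValueError("kd and protein concentration must be > 0")
    return protein_conc / (kd + protein_conc)


def simulate_idap_fragments(
    genome: Genome,
    sites: Optional[Sequence[PlantedSite]] = None,
    protein_conc: float = 320.0,
    n: int = 10_000,
    frag_length_sampler: Optional[LengthSampler] = None,
    seed: int = 0,
    background_prob: float = 0.0,
    source: str = "idap",
) -> FragmentSample:
    """Draw ``n`` affinity-captured fragments.

    A proposed fragment is retained only if it fully contains at least one
    planted site, with retention probability ``[P] / (Kd + [P])`` for the
    strongest (lowest-Kd) contained site; site-free fragments are retained
    with ``background_prob`` (default 0, i.e. perfect washing). The default
    protein concentration of 320 nM matches the capture conditions the
    downstream summit-pairing analysis was designed for.
    """
    if protein_conc <= 0:
        raise ValueError("protein_conc must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= background_prob <= 1:
        raise ValueError("background_prob must lie in [0, 1]")
    sites = list(genome.sites if sites is None else sites)
    if not sites and background_prob == 0:
        raise ValueError("no sites and zero background probability: nothing can be retained")
    sampler = frag_length_sampler or idap_default_lengths()
    L = genome.length
    circular = genome.circular
    thetas = np.array([isotherm_retention(s.kd, protein_conc) for s in sites])
    site_starts = np.array([s.start % L for s in sites], dtype=np.int64)
    site_widths = np.array([s.width for s in sites], dtype=np.int64)

    rng = np.random.default_rng(seed)
    records: list[FragmentRecord] = []
    n_proposed = 0
    batch = min(max(4 * n, 10_000), _MAX_BATCH)
    while len(records) < n:
        lengths = np.clip(sampler.sample(rng, batch), 1, L)
        starts = _propose_starts(rng, lengths, L, circular)
        theta = np.full(batch, float(background_prob))
        for b, w, th in zip(site_starts, site_widths, thetas):
            if circular:
                contained = ((b - starts) % L) + w <= lengths
            else:
                contained = (starts <= b) & (starts + lengths >= b + w)
            np.maximum.at(theta, np.nonzero(contained)[0], th)
        accept = rng.random(batch) < theta
        n_proposed, batch = _collect(
            records, starts, lengths, accept, n, n_proposed, batch, L, source
        )
    return FragmentSample(records, n_proposed)


def simulate_tn_library(
    landscape: FitnessLandscape,
    n: int,
    seed: int = 0,
    label: str = "parS_plus",
) -> InsertionLibrary:
    """Draw ``n`` surviving Tn5 insertions proportional to positional fitness."""
    if n < 1:
        raise ValueError("n must be >= 1")
    w = landscape.relative_fitness
    total = w.sum()
    if total == 0:
        raise ValueError("fitness landscape is identically zero")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling over the per-base categorical distribution
    cdf = np.cumsum(w)
    u = rng.random(n) * total
    draws = np.searchsorted(cdf, u, side="right")
    positions, counts = np.unique(draws, return_counts=True)
    return InsertionLibrary(positions=positions, counts=counts, label=label)


def simulate_spr_titration(
    kd: float,
    rmax: float,
    concentrations: Sequence[float] = DEFAULT_SPR_CONCENTRATIONS_NM,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> TitrationSeries:
    """Equilibrium SPR responses from a 1:1 isotherm with Gaussian noise.

    Response at concentration ``c`` is ``rmax * c / (kd + c)`` plus
    zero-mean Gaussian noise of standard deviation ``noise_sd`` (response
    units). Concentrations default to the nine-point nM grid used for Kd
    estimation.
    """
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    responses = rmax * conc / (kd + conc)
    if noise_sd > 0:
        responses = responses + np.random.default_rng(seed).normal(0.0, noise_sd, conc.size)
    return TitrationSeries(concentrations=conc, responses=responses, label=label)
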