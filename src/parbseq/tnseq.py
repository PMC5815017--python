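"""Transposon insertion-frequency ratio tracks and permissive-zone calling.

A parS-carrying transposon and an empty control transposon are used to
mutagenise the same strain; comparing their insertion frequencies along
the chromosome maps where an ectopic parS cluster is tolerated. Insertion
counts are binned (10 kb by default), converted to frequencies
(count / library total, so unequal sequencing depths cancel) and compared
as ``log10(parS+ frequency / parS- frequency)``. Contiguous runs of bins
at or above a log-ratio threshold form permissive zones; runs at or below
the negated threshold form disfavoured zones; outlier bins far above the
genome-wide typical ratio are insertion hotspots. Coordinates can be
remapped across engineered chromosomal inversions ("Flip" strains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from parbseq.simulate import InsertionLibrary

PERMISSIVE = "permissive"
DISFAVOURED = "disfavoured"
HOTSPOT = "hotspot"


@dataclass(frozen=True)
class RatioTrack:
    """Binned log10 insertion-frequency ratio (parS+ over parS-)."""

    bin_starts: np.ndarray
    log10_ratio: np.ndarray
    bin: int
    plus_total: int
    minus_total: int
    genome_length: Optional[int] = None

    def __post_init__(self) -> None:
        starts = np.asarray(self.bin_starts, dtype=np.int64)
        ratio = np.asarray(self.log10_ratio, dtype=float)
        if starts.shape != ratio.shape or starts.ndim != 1:
            raise ValueError("bin_starts and log10_ratio must be 1-D arrays of equal length")
        if self.bin < 1:
            raise ValueError("bin size must be > 0")
        if np.any(starts % self.bin != 0):
            raise ValueError("bin starts must be multiples of the bin size")
        object.__setattr__(self, "bin_starts", starts)
        object.__setattr__(self, "log10_ratio", ratio)

    def __len__(self) -> int:
        return self.bin_starts.size


@dataclass(frozen=True)
class Zone:
    """A contiguous genomic zone (bp coordinates, half-open, unwrapped)."""

    start: int
    end: int
    kind: str
    mean_log10_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("zone end must exceed start (after circular unwrap)")
        if self.kind not in (PERMISSIVE, DISFAVOURED, HOTSPOT):
            raise ValueError(f"unknown zone kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InversionSpec:
    """A chromosomal segment ``[left_endpoint, right_endpoint)`` that was inverted."""

    left_endpoint: int
    right_endpoint: int

    def __post_init__(self) -> None:
        if not 0 <= self.left_endpoint < self.right_endpoint:
            raise ValueError("need 0 <= left_endpoint < right_endpoint")


def bin_insertions(
    library: InsertionLibrary, genome_length: int, bin: int = 10_000
) -> np.ndarray:
    """Per-bin insertion read counts on half-open bins tiling the genome.

    The final bin may be partial when ``genome_length`` is not a multiple
    of ``bin``. The bins conserve the library total exactly.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if library.positions.size and library.positions.max() >= genome_length:
        raise ValueError("insertion position outside genome")
    nbins = -(-genome_length // bin)
    return np.bincount(library.positions // bin, weights=library.counts, minlength=nbins).astype(
        np.int64
    )


def log10_ratio_track(
    plus_bins: np.ndarray,
    minus_bins: np.ndarray,
    plus_total: int,
    minus_total: int,
    bin: int = 10_000,
    pseudocount: float = 1.0,
    genome_length: Optional[int] = None,
) -> RatioTrack:
    """log10 of binned insertion FREQUENCIES, parS+ over parS-.

    Per bin: ``log10(((plus + pc) / plus_total) / ((minus + pc) / minus_total))``.
    Comparing frequencies rather than raw counts makes the track invariant
    to overall library depth; the pseudocount (default 1 insertion)
    avoids log of zero. The track is exactly antisymmetric under swapping
    the two libraries.
    """
    plus = np.asarray(plus_bins, dtype=float)
    minus = np.asarray(minus_bins, dtype=float)
    if plus.shape != minus.shape:
        raise ValueError(f"bin grids differ: {plus.shape} vs {minus.shape}")
    if plus_total < 1 or minus_total < 1:
        raise ValueError("library totals must be >= 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ratio = np.log10(((plus + pseudocount) / plus_total) / ((minus + pseudocount) / minus_total))
    return RatioTrack(
        bin_starts=np.arange(plus.size, dtype=np.int64) * bin,
        log10_ratio=ratio,
        bin=bin,
        plus_total=plus_total,
        minus_total=minus_total,
        genome_length=genome_length,
    )


def _bin_runs(mask: np.ndarray, merge_gap_bins: int, min_bins: int, circular: bool):
    """Maximal True runs, merged across gaps <= merge_gap_bins, >= min_bins long.

    Returns (first_bin, n_bins) pairs; on circular tracks a run may wrap
    (first_bin + n_bins > number of bins).
    """
    n = mask.size
    if not mask.any():
        return []
    if mask.all():
        return [(0, n)]
    idx = np.nonzero(mask)[0]
    runs = [[int(idx[0]), 1]]
    for i in idx[1:]:
        if i - (runs[-1][0] + runs[-1][1]) <= merge_gap_bins:
            runs[-1][1] = int(i) - runs[-1][0] + 1
        else:
            runs.append([int(i), 1])
    if circular and len(runs) > 1:
        first, last = runs[0], runs[-1]
        if (n - (last[0] + last[1])) + first[0] <= merge_gap_bins:
            runs.pop()
            runs[0] = [last[0], first[0] + first[1] + (n - last[0])]
    return [(s, w) for s, w in runs if w >= min_bins]


def _zone_from_run(track: RatioTrack, first_bin: int, n_bins: int, kind: str) -> Zone:
    n = len(track)
    glen = track.genome_length if track.genome_length is not None else n * track.bin
    bins = np.arange(first_bin, first_bin + n_bins) % n
    last = int(bins[-1])
    start = int(track.bin_starts[first_bin % n])
    end = min(int(track.bin_starts[last]) + track.bin, glen)  # cap the partial final bin
    if first_bin + n_bins > n:  # run wraps past the origin: report unwrapped
        end += glen
    return Zone(
        start=start,
        end=end,
        kind=kind,
        mean_log10_ratio=float(track.log10_ratio[bins].mean()),
    )


def call_zones(
    track: RatioTrack,
    permissive_threshold: float = 0.0,
    min_bins: int = 3,
    merge_gap_bins: int = 1,
    circular: bool = True,
) -> list[Zone]:
    """Permissive and disfavoured zones from a log10 ratio track.

    Permissive zones are maximal runs of bins with
    ``log10_ratio >= permissive_threshold`` (the parS+ transposon inserts
    at least as frequently as the control), merged across up to
    ``merge_gap_bins`` below-threshold bins and discarded when shorter
    than ``min_bins``; disfavoured zones analogously with
    ``log10_ratio <= -permissive_threshold``. Circular-aware.
    """
    if not np.isfinite(permissive_threshold):
        raise ValueError("threshold must be finite")
    zones = []
    for kind, mask in (
        (PERMISSIVE, track.log10_ratio >= permissive_threshold),
        (DISFAVOURED, track.log10_ratio <= -permissive_threshold),
    ):
        for first, width in _bin_runs(mask, merge_gap_bins, min_bins, circular):
            zones.append(_zone_from_run(track, first, width, kind))
    zones.sort(key=lambda z: (z.kind, z.start))
    return zones


def call_hotspots(track: RatioTrack, z_threshold: float = 4.0, circular: bool = True) -> list[Zone]:
    """Outlier bins far above the typical ratio (robust z-score test).

    A bin is a hotspot when its log10 ratio exceeds
    ``median + z_threshold * 1.4826 * MAD``; adjacent hotspot bins are
    merged. A constant track has zero MAD and a degenerate scale: no
    hotspots are called and a warning flags the degeneracy.
    """
    ratio = track.log10_ratio
    if ratio.size == 0:
        raise ValueError("empty ratio track")
    med = float(np.median(ratio))
    mad = float(np.median(np.abs(ratio - med)))
    if mad == 0:
        warnings.warn("constant ratio track: robust scale is degenerate, no hotspots called")
        return []
    cutoff = med + z_threshold * 1.4826 * mad
    mask = ratio > cutoff
    return [
        _zone_from_run(track, first, width, HOTSPOT)
        for first, width in _bin_runs(mask, merge_gap_bins=0, min_bins=1, circular=circular)
    ]


def remap_inversion(
    position: Union[int, np.ndarray], inv: InversionSpec
) -> Union[int, np.ndarray]:
    """Map coordinates through a chromosomal inversion.

    Positions inside ``[left, right)`` reflect to
    ``left + right - 1 - position``; positions outside are unchanged.
    The map is an involution (applying it twice is the identity) and
    preserves adjacency within the inverted segment.
    """
    pos = np.asarray(position)
    inside = (pos >= inv.left_endpoint) & (pos < inv.right_endpoint)
    out = np.where(inside, inv.left_endpoint + inv.right_endpoint - 1 - pos, pos)
    if np.isscalar(position) or np.ndim(position) == 0:
        return int(out)
    return out
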