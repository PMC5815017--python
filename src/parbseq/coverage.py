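"""Per-base coverage tracks, depth normalisation and strand-specific end counts.

Coverage is computed over whole double-stranded *fragments* (the inferred
template molecules), not individual sequencing reads: single-end reads are
treated as an upstream detail folded into the fragment abstraction. Tracks
are normalised to RPBPM (reads per base pair per million mapped reads,
``raw / (total_mapped / 1e6)``) at single-base resolution, or to a binned
per-kb variant (RPKPM) for whole-genome views. Fragment 5' ends are counted
per strand: a fragment ``[s, s+L)`` leaves its upper-strand 5' end at ``s``
and its lower-strand 5' end at the rightmost base ``s+L-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from parbseq.simulate import FragmentRecord

RAW = "raw"
RPBPM = "RPBPM"
RPKPM = "RPKPM"
FOLD = "fold-enrichment"


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base (or per-bin) nonnegative signal with a units tag."""

    values: np.ndarray
    units: str = RAW
    total_mapped: int = 0
    bin_size: int = 1  #: bp per entry (1 for per-base tracks)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("track values must be 1-D")
        if np.any(values < 0):
            raise ValueError("track values must be >= 0")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StrandEndCounts:
    """Per-base counts of fragment 5' ends on the upper and lower strand."""

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        upper = np.asarray(self.upper)
        lower = np.asarray(self.lower)
        if upper.shape != lower.shape or upper.ndim != 1:
            raise ValueError("upper and lower must be 1-D arrays of equal length")
        if np.any(upper < 0) or np.any(lower < 0):
            raise ValueError("end counts must be >= 0")
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "lower", lower)

    def __len__(self) -> int:
        return self.upper.size


def _check_fragments(
    fragments: Sequence[FragmentRecord], genome_length: int, circular: bool
) -> tuple[np.ndarray, np.ndarray]:
    starts = np.fromiter((f.start for f in fragments), dtype=np.int64, count=len(fragments))
    lengths = np.fromiter((f.length for f in fragments), dtype=np.int64, count=len(fragments))
    if starts.size:
        bad = (starts < 0) | (starts >= genome_length)
        if not circular:
            bad |= starts + lengths > genome_length
        if np.any(bad):
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"fragment {fragments[i]} lies outside the "
                f"{'circular' if circular else 'linear'} genome of length {genome_length}"
            )
        if np.any(lengths > genome_length):
            i = int(np.nonzero(lengths > genome_length)[0][0])
            raise ValueError(f"fragment {fragments[i]} is longer than the genome")
    return starts, lengths


def fragment_coverage(
    fragments: Sequence[FragmentRecord], genome_length: int, circular: bool = True
) -> CoverageTrack:
    """Raw per-base coverage: values[i] = number of fragments covering base i.

    The sum over the track equals the sum of fragment lengths exactly
    (coverage conservation), including across the circular wrap.
    """
    starts, lengths = _check_fragments(fragments, genome_length, circular)
    delta = np.zeros(genome_length + 1, dtype=np.int64)
    ends = starts + lengths
    np.add.at(delta, starts, 1)
    if circular:
        np.add.at(delta, np.minimum(ends, genome_length), -1)
        over = ends - genome_length
        over = over[over > 0]  # wrapped tails re-enter at position 0
        delta[0] += over.size
        np.add.at(delta, over, -1)
    else:
        np.add.at(delta, ends, -1)
    values = np.cumsum(delta[:-1])
    return CoverageTrack(values=values.astype(float), units=RAW, total_mapped=len(fragments))


def normalize_rpbpm(track: CoverageTrack, total_mapped: int) -> CoverageTrack:
    """Reads per base pair per million mapped reads: ``raw / (total_mapped / 1e6)``."""
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return CoverageTrack(
        values=track.values / (total_mapped / 1e6),
        units=RPBPM,
        total_mapped=total_mapped,
        bin_size=track.bin_size,
    )


def bin_rpkpm(track: CoverageTrack, total_mapped: int, bin: int = 1000) -> CoverageTrack:
    """Per-bin depth-normalised signal: sum of raw values per bin / (total/1e6).

    The final partial bin (when the genome length is not a multiple of
    ``bin``) is kept; its width is recoverable from the genome length.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    n = len(track)
    nbins = -(-n // bin)
    padded = np.zeros(nbins * bin)
    padded[:n] = track.values
    sums = padded.reshape(nbins, bin).sum(axis=1)
    return CoverageTrack(
        values=sums / (total_mapped / 1e6),
        units=RPKPM,
        total_mapped=total_mapped,
        bin_size=bin,
    )


def strand_end_counts(
    fragments: Sequence[FragmentRecord], genome_length: int, circular: bool = True
) -> StrandEndCounts:
    """Count fragment 5' ends per base and strand.

    For a fragment ``[s, s+L)``: ``upper[s] += 1`` and
    ``lower[(s+L-1) mod genome_length] += 1`` (the 5' end of the
    lower-strand read sits on the fragment's rightmost base). Each fragment
    contributes exactly one end to each strand, so both arrays sum to the
    number of fragments.
    """
    starts, lengths = _check_fragments(fragments, genome_length, circular)
    upper = np.bincount(starts, minlength=genome_length)
    lower = np.bincount((starts + lengths - 1) % genome_length, minlength=genome_length)
    return StrandEndCounts(upper=upper.astype(np.int64), lower=lower.astype(np.int64))


def fold_enrichment(
    chip: CoverageTrack, control: CoverageTrack, pseudocount: float = 0.1
) -> CoverageTrack:
    """Pseudocount-stabilised ratio track ``(chip + pc) / (control + pc)``.

    Both tracks must be equally normalised (typically RPBPM) and of equal
    length; the default pseudocount of 0.1 RPBPM stabilises zero-control
    bases.
    """
    if len(chip) != len(control):
        raise ValueError(f"track length mismatch: {len(chip)} vs {len(control)}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return CoverageTrack(
        values=(chip.values + pseudocount) / (control.values + pseudocount),
        units=FOLD,
        total_mapped=chip.total_mapped,
        bin_size=chip.bin_size,
    )


def fragment_size_stats(
    fragments: Sequence[FragmentRecord], bin_width: int = 10
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Mean, median and histogram of fragment lengths.

    Returns ``(mean, median, (bin_edges, counts))`` with histogram bins of
    ``bin_width`` bp starting at 0.
    """
    if not fragments:
        raise ValueError("fragment list is empty")
    lengths = np.fromiter((f.length for f in fragments), dtype=np.int64, count=len(fragments))
    edges = np.arange(0, lengths.max() + bin_width + 1, bin_width)
    counts, edges = np.histogram(lengths, bins=edges)
    return float(lengths.mean()), float(np.median(lengths)), (edges, counts)
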