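"""Coverage construction and normalization.

Implements the standard ATAC-seq preprocessing chain downstream of
alignment: the +4/-5 transposase insertion-offset shift, fragment
pile-up coverage, scaling to a common sequencing depth, through-origin
linear-regression normalization of half-embryo samples to a whole-embryo
reference over genome-tiling bins, and signal extraction over bins and
arbitrary regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tracks_io import CoverageTrack, FragmentSet, GenomeTable, Interval

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationFit",
    "shift_fragments",
    "coverage_from_fragments",
    "scale_to_depth",
    "fit_no_intercept",
    "apply_normalization",
    "tile_signal",
    "region_signal",
]

#: Tn5 inserts in a 9-bp staggered duplication; reads are conventionally
#: shifted +4 (plus strand) / -5 (minus strand) to centre on the insertion.
PLUS_SHIFT = 4
MINUS_SHIFT = -5


@dataclass(frozen=True)
class NormalizationFit:
    """Through-origin regression of sample bin sums on reference bin sums.

    slope is the no-intercept least-squares coefficient
    ``sum(x*y) / sum(x**2)`` over bins; dividing the sample by it brings
    it onto the reference scale.
    """

    slope: float
    n_bins: int
    bin_size: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"need at least 2 bins, got {self.n_bins}")


def shift_fragments(fragments: FragmentSet, genome: GenomeTable) -> FragmentSet:
    """Apply the +4/-5 insertion-offset shift to whole fragment intervals.

    Plus-strand fragments move +4 bp, minus-strand fragments -5 bp; both
    endpoints move so fragment length is preserved except where clipping
    at chromosome bounds truncates. Fragments emptied by clipping are
    dropped (count logged).
    """
    if len(fragments) == 0:
        return fragments
    shift = np.where(fragments.strands == "+", PLUS_SHIFT, MINUS_SHIFT)
    starts = fragments.starts + shift
    ends = fragments.ends + shift
    lengths = genome.lengths
    chrom_len = np.array([lengths[c] for c in fragments.chroms], dtype=np.int64)
    starts = np.clip(starts, 0, chrom_len)
    ends = np.clip(ends, 0, chrom_len)
    keep = starts < ends
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("shift_fragments: dropped %d fragment(s) emptied by clipping", n_dropped)
    return FragmentSet(
        chroms=fragments.chroms[keep],
        starts=starts[keep],
        ends=ends[keep],
        strands=fragments.strands[keep],
    )


def coverage_from_fragments(
    fragments: FragmentSet, genome: GenomeTable, label: str = ""
) -> CoverageTrack:
    """Per-base fragment pile-up: signal(b) = number of fragments covering b."""
    track = CoverageTrack(genome, label=label)
    lengths = genome.lengths
    if len(fragments) == 0:
        return track
    for chrom in np.unique(fragments.chroms.astype(str)):
        if chrom not in lengths:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        mask = fragments.chroms == chrom
        n = lengths[chrom]
        # difference-array pile-up: O(n_fragments + chrom_length)
        diff = np.zeros(n + 1, dtype=np.float64)
        np.add.at(diff, fragments.starts[mask], 1.0)
        np.add.at(diff, fragments.ends[mask], -1.0)
        track.data[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(genome, track.data, label=label)


def scale_to_depth(
    track: CoverageTrack, mapped_reads: int, target_reads: int = 10_000_000
) -> CoverageTrack:
    """Rescale signal to a common sequencing depth (default 10 M mapped reads)."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    if target_reads <= 0:
        raise ValueError("target_reads must be positive")
    return track.scaled(target_reads / mapped_reads)


def _bin_sums(track: CoverageTrack, bin_size: int) -> np.ndarray:
    """Concatenated per-chromosome bin sums (last partial bin kept)."""
    parts = []
    for chrom, length in track.genome.entries:
        edges = np.arange(0, length, bin_size)
        parts.append(np.add.reduceat(track.data[chrom], edges))
    return np.concatenate(parts) if parts else np.empty(0)


def fit_no_intercept(
    sample: CoverageTrack,
    reference: CoverageTrack,
    bin_size: int = 1000,
    min_reference: float = 0.0,
) -> NormalizationFit:
    """Fit ``sample ~ slope * reference`` (no intercept) over tiling bins.

    Bins with reference sum <= ``min_reference`` are excluded so that the
    zero-inflated empty fraction of the genome does not pull the fit.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if sample.genome.entries != reference.genome.entries:
        raise ValueError("sample and reference must share a genome")
    x = _bin_sums(reference, bin_size)
    y = _bin_sums(sample, bin_size)
    if x.sum() <= 0:
        raise ValueError("reference track has zero total signal")
    keep = x > min_reference
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("fewer than 2 usable bins")
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))  # through-origin total sum of squares
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return NormalizationFit(slope=slope, n_bins=int(x.size), bin_size=bin_size, r_squared=r_squared)


def apply_normalization(sample: CoverageTrack, fit: NormalizationFit) -> CoverageTrack:
    """Divide every base by the fitted slope, putting the sample on the
    reference scale; refitting afterwards gives slope 1."""
    if fit.slope <= 0:
        raise ValueError(f"non-positive slope {fit.slope}")
    return sample.scaled(1.0 / fit.slope)


def tile_signal(track: CoverageTrack, bin_size: int) -> list[tuple[Interval, float]]:
    """Adjacent non-overlapping bins from 0 per chromosome with total signal.

    The final partial bin is kept, so bin totals sum to the track total.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out: list[tuple[Interval, float]] = []
    for chrom, length in track.genome.entries:
        edges = np.arange(0, length, bin_size)
        sums = np.add.reduceat(track.data[chrom], edges)
        for s, total in zip(edges, sums):
            out.append((Interval(chrom, int(s), int(min(s + bin_size, length))), float(total)))
    return out


def region_signal(track: CoverageTrack, region: Interval, aggregate: str = "sum") -> float:
    """Total (default) or mean per-base signal over ``[start, end)``."""
    lengths = track.genome.lengths
    if region.chrom not in lengths:
        raise ValueError(f"unknown chromosome {region.chrom!r}")
    if region.start < 0 or region.end > lengths[region.chrom]:
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} out of range")
    total = track.interval_total(region.chrom, region.start, region.end)
    if aggregate == "sum":
        return total
    if aggregate == "mean":
        return total / len(region)
    raise ValueError(f"unknown aggregate {aggregate!r}")
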