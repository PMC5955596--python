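"""Synthetic paired-half ATAC-seq data with known ground truth.

Generates anterior/posterior/whole coverage tracks (and fragment-level
BED output) over a small genome with planted accessibility peaks of
known amplitude and known positional skew. A peak with amplitude ``A``
(expected fragment count summed over both halves) and true skew ``s``
contributes an expected ``A (1 + s) / 2`` fragments to the anterior
sample and ``A (1 - s) / 2`` to the posterior sample, so the positional
skew of the expectations is exactly ``s``. Fragment counts are Poisson,
fragment midpoints are Gaussian around the peak centre, background is a
homogeneous Poisson process, and fragment lengths are log-normal with
everything above 500 bp discarded (mimicking size selection of the
sequencing libraries). The whole-embryo sample is an independent draw
at the combined anterior + posterior rates, emulating a separately
sequenced whole sample.

Every draw flows from a single seed: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import coverage_from_fragments
from .regions import Region, RegionCatalog
from .tracks_io import CoverageTrack, FragmentSet, GenomeTable, Interval

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "plant_peaks",
    "simulate_fragments",
    "simulate_tracks",
    "truth_catalog",
    "truth_peak_intervals",
]

SAMPLES = ("anterior", "posterior", "whole")
#: library size selection removes fragments longer than this
FRAGMENT_CAP = 500


def _default_genome() -> GenomeTable:
    return GenomeTable((("chrSim", 2_000_000),))


@dataclass(frozen=True)
class SyntheticSpec:
    """World description for the simulator.

    amplitude_range is in expected fragments per peak (both halves
    combined) at depth_factor 1; background_rate is expected fragments
    per kb per half-sample. skews may be a scalar (all peaks) or a
    sequence of length n_peaks.
    """

    genome: GenomeTable = field(default_factory=_default_genome)
    n_peaks: int = 200
    n_decoy_peaks: int = 0
    peak_width_sd: int = 150
    amplitude_range: tuple[float, float] = (100.0, 1000.0)
    skews: float | tuple[float, ...] = 0.0
    background_rate: float = 5.0
    fragment_length_median: float = 120.0
    fragment_length_sigma: float = 0.45
    replicate_factor: float = 0.15
    depth_factor: float = 1.0
    whole_as_sum: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        skews = np.atleast_1d(np.asarray(self.skews, dtype=np.float64))
        if np.any(np.abs(skews) > 1):
            raise ValueError("skews must lie in [-1, 1]")
        if skews.size not in (1, self.n_peaks) and self.n_peaks > 0:
            raise ValueError(f"need 1 or n_peaks={self.n_peaks} skews, got {skews.size}")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[1] < self.amplitude_range[0]:
            raise ValueError("amplitude_range must be positive and ordered")
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be positive")

    def peak_skews(self) -> np.ndarray:
        skews = np.atleast_1d(np.asarray(self.skews, dtype=np.float64))
        if skews.size == 1:
            return np.full(self.n_peaks, float(skews[0]))
        return skews.copy()


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted peaks: footprint interval, amplitude, true skew.

    ``cataloged`` marks which peaks stand for annotated patterning
    regions; the rest are decoys emulating the genome's many
    unannotated accessible sites (always zero skew), which is what makes
    signal-matched random draws outside the annotation possible.
    """

    peaks: tuple[tuple[Interval, float, float], ...]
    background_rate: float
    seed: int
    cataloged: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.cataloged and len(self.cataloged) != len(self.peaks):
            raise ValueError("cataloged flags must match peak count")

    def __len__(self) -> int:
        return len(self.peaks)

    def is_cataloged(self, i: int) -> bool:
        return self.cataloged[i] if self.cataloged else True

    def cataloged_peaks(self) -> list[tuple[Interval, float, float]]:
        return [p for i, p in enumerate(self.peaks) if self.is_cataloged(i)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv, _, _ in self.peaks],
                "start": [iv.start for iv, _, _ in self.peaks],
                "end": [iv.end for iv, _, _ in self.peaks],
                "name": [iv.name for iv, _, _ in self.peaks],
                "amplitude": [a for _, a, _ in self.peaks],
                "true_skew": [s for _, _, s in self.peaks],
                "cataloged": [self.is_cataloged(i) for i in range(len(self.peaks))],
            }
        )


def plant_peaks(spec: SyntheticSpec) -> SyntheticTruth:
    """Place non-overlapping peaks and assign amplitudes and skews.

    A peak footprint spans 6 peak-width standard deviations (+-3 SD
    around the centre). Footprints are drawn uniformly among all
    non-overlapping placements per chromosome (positions are spread
    proportionally to chromosome length).
    """
    rng = np.random.default_rng(spec.seed)
    width = 6 * spec.peak_width_sd
    total = spec.n_peaks + spec.n_decoy_peaks
    if total == 0:
        return SyntheticTruth((), spec.background_rate, spec.seed)
    lengths = np.array([l for _, l in spec.genome.entries], dtype=np.float64)
    counts = rng.multinomial(total, lengths / lengths.sum())
    peaks: list[tuple[Interval, float, float]] = []
    starts_all: list[tuple[str, int]] = []
    for (chrom, length), n in zip(spec.genome.entries, counts):
        if n == 0:
            continue
        free = length - n * width
        if free < 0:
            raise ValueError(
                f"genome too small: {n} peaks of footprint {width} bp do not fit in "
                f"{chrom} ({length} bp)"
            )
        # classic non-overlapping placement: sorted uniforms + stacking
        gaps = np.sort(rng.integers(0, free + 1, size=n))
        starts = gaps + width * np.arange(n)
        starts_all.extend((chrom, int(s)) for s in starts)
    amplitudes = rng.uniform(*spec.amplitude_range, size=total) * spec.depth_factor
    cataloged = np.zeros(total, dtype=bool)
    cataloged[rng.permutation(total)[: spec.n_peaks]] = True
    skews = np.zeros(total)
    skews[cataloged] = spec.peak_skews()
    for i, (chrom, s) in enumerate(starts_all):
        iv = Interval(chrom, s, s + width, name=f"peak{i:04d}")
        peaks.append((iv, float(amplitudes[i]), float(skews[i])))
    return SyntheticTruth(
        tuple(peaks),
        spec.background_rate * spec.depth_factor,
        spec.seed,
        cataloged=tuple(bool(c) for c in cataloged),
    )


def _sample_fragments(
    truth: SyntheticTruth, spec: SyntheticSpec, rng: np.random.Generator, sample: str
) -> FragmentSet:
    """One Poisson realisation of a sample's fragments (peaks + background)."""
    jitter = float(rng.lognormal(0.0, spec.replicate_factor)) if spec.replicate_factor > 0 else 1.0
    lengths_by_chrom = spec.genome.lengths
    chroms: list[np.ndarray] = []
    mids: list[np.ndarray] = []
    chrom_names: list[str] = []
    for iv, amplitude, s in truth.peaks:
        if sample == "anterior":
            rate = amplitude * (1.0 + s) / 2.0
        elif sample == "posterior":
            rate = amplitude * (1.0 - s) / 2.0
        else:  # whole: combined rate
            rate = amplitude
        n = rng.poisson(rate * jitter)
        if n == 0:
            continue
        centre = (iv.start + iv.end) / 2.0
        mids.append(rng.normal(centre, spec.peak_width_sd, n))
        chrom_names.extend([iv.chrom] * n)
    bg_rate = truth.background_rate * (2.0 if sample == "whole" else 1.0)
    for chrom, length in spec.genome.entries:
        n_bg = rng.poisson(bg_rate * jitter * length / 1000.0)
        if n_bg:
            mids.append(rng.uniform(0, length, n_bg))
            chrom_names.extend([chrom] * n_bg)
    if not mids:
        return FragmentSet.empty()
    mid = np.concatenate(mids)
    chrom_arr = np.array(chrom_names, dtype=object)
    lengths = rng.lognormal(
        np.log(spec.fragment_length_median), spec.fragment_length_sigma, mid.size
    )
    lengths = np.maximum(lengths.astype(np.int64), 1)
    keep = lengths <= FRAGMENT_CAP
    mid, chrom_arr, lengths = mid[keep], chrom_arr[keep], lengths[keep]
    starts = np.round(mid - lengths / 2.0).astype(np.int64)
    ends = starts + lengths
    chrom_len = np.array([lengths_by_chrom[c] for c in chrom_arr], dtype=np.int64)
    starts = np.clip(starts, 0, chrom_len)
    ends = np.clip(ends, 0, chrom_len)
    ok = starts < ends
    strands = np.where(rng.random(mid.size) < 0.5, "+", "-").astype("U1")
    return FragmentSet(
        chroms=chrom_arr[ok], starts=starts[ok], ends=ends[ok], strands=strands[ok]
    )


def simulate_fragments(
    truth: SyntheticTruth, spec: SyntheticSpec
) -> dict[str, FragmentSet]:
    """Fragment sets for the anterior, posterior and whole samples."""
    rng = np.random.default_rng(spec.seed + 1)
    out = {sample: _sample_fragments(truth, spec, rng, sample) for sample in SAMPLES}
    if spec.whole_as_sum:
        ant, post = out["anterior"], out["posterior"]
        out["whole"] = FragmentSet(
            chroms=np.concatenate([ant.chroms, post.chroms]),
            starts=np.concatenate([ant.starts, post.starts]),
            ends=np.concatenate([ant.ends, post.ends]),
            strands=np.concatenate([ant.strands, post.strands]),
        )
    return out


def simulate_tracks(
    truth: SyntheticTruth, spec: SyntheticSpec
) -> tuple[CoverageTrack, CoverageTrack, CoverageTrack]:
    """Anterior, posterior and whole coverage tracks (fragment pile-ups)."""
    frags = simulate_fragments(truth, spec)
    return tuple(
        coverage_from_fragments(frags[sample], spec.genome, label=sample)
        for sample in SAMPLES
    )


def truth_catalog(truth: SyntheticTruth) -> RegionCatalog:
    """Region catalog over the planted peaks.

    Only cataloged peaks appear (decoys emulate unannotated sites).
    Peaks with positive true skew are labelled anterior, negative
    posterior; zero-skew peaks alternate dorsal/ventral so that they
    populate the axis-control classes.
    """
    regions: list[Region] = []
    n_zero = 0
    for iv, _, s in truth.cataloged_peaks():
        if s > 0:
            half = "anterior"
        elif s < 0:
            half = "posterior"
        else:
            half = "dorsal" if n_zero % 2 == 0 else "ventral"
            n_zero += 1
        regions.append(
            Region(
                interval=iv,
                kind="enhancer",
                expected_active_half=half,
                zygotic_class="zygotic",
                source="synthetic",
            )
        )
    return RegionCatalog(tuple(regions), provenance="synthetic truth")


def truth_peak_intervals(
    truth: SyntheticTruth,
    rng: np.random.Generator | int | None = None,
    jitter_bp: int = 0,
    drop_fraction: float = 0.0,
) -> list[Interval]:
    """Peak footprints as a called-peak stand-in, optionally perturbed.

    ``jitter_bp`` shifts both edges by independent uniform offsets and
    ``drop_fraction`` removes peaks at random, emulating imperfect peak
    calls in a single replicate.
    """
    rng = np.random.default_rng(rng)
    out: list[Interval] = []
    lengths = {}
    for iv, _, _ in truth.peaks:
        if drop_fraction > 0 and rng.random() < drop_fraction:
            continue
        s, e = iv.start, iv.end
        if jitter_bp > 0:
            s = max(0, s + int(rng.integers(-jitter_bp, jitter_bp + 1)))
            e = e + int(rng.integers(-jitter_bp, jitter_bp + 1))
            if e <= s:
                e = s + 1
        out.append(Interval(iv.chrom, s, e, name=iv.name))
    return out
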