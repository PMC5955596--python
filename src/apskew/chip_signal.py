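"""ChIP-seq signal matrices over skew-ordered regions.

Builds the heat-map substrate: each ChIP track is normalized by its
genome-wide mean (putting different experiments on a common
"deviation from background" scale), aggregated over fixed windows
centred on region midpoints (default 3 kb), min-max scaled to [0, 1]
per factor, and ordered by positional skew.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import Region
from .tracks_io import CoverageTrack

__all__ = [
    "SignalMatrix",
    "mean_normalize",
    "window_matrix",
    "scale01_per_factor",
    "order_by_skew",
]


@dataclass(frozen=True)
class SignalMatrix:
    """Regions x factors signal matrix (rows ordered, index = region name)."""

    values: pd.DataFrame
    scaling: str  # raw | mean_normalized | minmax01
    window: int

    def __post_init__(self) -> None:
        if self.scaling not in ("raw", "mean_normalized", "minmax01"):
            raise ValueError(f"unknown scaling {self.scaling!r}")

    @property
    def factors(self) -> list[str]:
        return list(self.values.columns)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="region", float_format="%.6g")


def mean_normalize(track: CoverageTrack) -> CoverageTrack:
    """Divide every base by the genome-wide mean signal (new mean = 1)."""
    mean = track.mean()
    if mean <= 0:
        raise ValueError("cannot mean-normalize a zero-signal track")
    return track.scaled(1.0 / mean)


def window_matrix(
    tracks: dict[str, CoverageTrack],
    regions: list[Region],
    window: int = 3000,
    aggregate: str = "mean",
    scaling: str = "raw",
) -> SignalMatrix:
    """Aggregate each track over a window centred on each region midpoint.

    The window is ``[mid - window//2, mid + window - window//2)`` with
    ``mid = (start + end) // 2``, clipped at chromosome ends (the mean
    is then taken over the clipped extent).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if not tracks:
        raise ValueError("need at least one track")
    names = [r.name or f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}" for r in regions]
    data: dict[str, list[float]] = {}
    for factor, track in tracks.items():
        lengths = track.genome.lengths
        col: list[float] = []
        for r in regions:
            iv = r.interval
            if iv.chrom not in lengths:
                raise ValueError(f"region {r.name!r} on unknown chromosome {iv.chrom!r}")
            mid = (iv.start + iv.end) // 2
            if not (0 <= mid < lengths[iv.chrom]):
                raise ValueError(f"region {r.name!r} midpoint off genome")
            lo = max(0, mid - window // 2)
            hi = min(lengths[iv.chrom], mid - window // 2 + window)
            total = track.interval_total(iv.chrom, lo, hi)
            col.append(total if aggregate == "sum" else total / (hi - lo))
        data[factor] = col
    return SignalMatrix(pd.DataFrame(data, index=names), scaling=scaling, window=window)


def scale01_per_factor(matrix: SignalMatrix) -> SignalMatrix:
    """Min-max scale each factor column to [0, 1].

    Constant columns carry no contrast and map to all-zero with a
    warning.
    """
    if len(matrix.values) < 2:
        raise ValueError("need at least 2 regions to scale")
    df = matrix.values.copy()
    for col in df.columns:
        lo, hi = df[col].min(), df[col].max()
        if hi == lo:
            warnings.warn(f"factor {col!r} has constant signal; scaled to all zeros")
            df[col] = 0.0
        else:
            df[col] = (df[col] - lo) / (hi - lo)
    return SignalMatrix(df, scaling="minmax01", window=matrix.window)


def order_by_skew(matrix: SignalMatrix, skews: dict[str, float]) -> SignalMatrix:
    """Sort rows by descending positional skew; ties break by region name."""
    missing = [n for n in matrix.region_names if n not in skews]
    if missing:
        raise ValueError(f"no skew for region(s): {', '.join(missing[:5])}")
    order = sorted(matrix.region_names, key=lambda n: (-skews[n], n))
    return SignalMatrix(matrix.values.loc[order], scaling=matrix.scaling, window=matrix.window)
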