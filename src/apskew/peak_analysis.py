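"""Peak-level skew classification and transcription-factor overlap tests.

Peaks called on the whole-embryo sample are reduced to a reproducible
set (merged-sample peaks supported by both biological replicates), each
peak's positional skew is scored against the random-region null, and
the resulting AntSig / PostSig / NotSig classes are tested for
enrichment or depletion of transcription-factor ChIP peaks with
one-tailed Fisher's exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import _IntervalIndex
from .skew import ALPHA, NullModel, RegionSignalPair, score_region
from .tracks_io import CoverageTrack, Interval

__all__ = [
    "PeakClassTable",
    "ContingencyTable",
    "EnrichmentResult",
    "reproducible_peaks",
    "classify_peaks",
    "overlap_contingency",
    "fisher_one_tailed",
]

CLASSES = ("AntSig", "PostSig", "NotSig")


@dataclass(frozen=True)
class PeakClassTable:
    """Per-peak skew scores and classes; classes partition the peak set.

    AntSig: skew > 0 and p < 0.05; PostSig: skew < 0 and p < 0.05;
    NotSig: everything else (including degenerate zero-signal peaks).
    """

    table: pd.DataFrame  # chrom start end name positional_skew z p class degenerate

    def peaks_in_class(self, cls: str) -> list[Interval]:
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        sub = self.table[self.table["class"] == cls]
        return [
            Interval(r.chrom, int(r.start), int(r.end), name=str(r.name))
            for r in sub.itertuples(index=False)
        ]

    def counts(self) -> dict[str, int]:
        c = self.table["class"].value_counts().to_dict()
        return {cls: int(c.get(cls, 0)) for cls in CLASSES}

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table over a peak universe.

    a: class peaks overlapping >= 1 TF peak; b: class peaks without TF
    overlap; c: non-class universe peaks with TF overlap; d: the rest.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_one_tailed: float
    direction: str  # "enrichment" or "depletion"


def reproducible_peaks(
    rep1: list[Interval], rep2: list[Interval], merged: list[Interval]
) -> list[Interval]:
    """Merged-sample peaks supported by both replicates.

    A merged peak is kept iff it overlaps (>= 1 bp) a peak in rep1 AND
    one in rep2; the retained coordinates are the merged-set ones.
    """
    ix1, ix2 = _IntervalIndex(rep1), _IntervalIndex(rep2)
    return [
        pk
        for pk in merged
        if ix1.overlaps(pk.chrom, pk.start, pk.end) and ix2.overlaps(pk.chrom, pk.start, pk.end)
    ]


def classify_peaks(
    peaks: list[Interval],
    anterior: CoverageTrack,
    posterior: CoverageTrack,
    null: NullModel,
) -> PeakClassTable:
    """Score every peak against the null and label AntSig/PostSig/NotSig."""
    rows = []
    for pk in peaks:
        pair = RegionSignalPair(
            region=None,
            x_anterior=anterior.interval_total(pk.chrom, pk.start, pk.end),
            x_posterior=posterior.interval_total(pk.chrom, pk.start, pk.end),
        )
        res = score_region(pair, null)
        if res.degenerate or res.p >= ALPHA:
            cls = "NotSig"
        elif res.positional_skew > 0:
            cls = "AntSig"
        elif res.positional_skew < 0:
            cls = "PostSig"
        else:
            cls = "NotSig"  # skew exactly 0 cannot be directionally skewed
        rows.append(
            {
                "chrom": pk.chrom,
                "start": pk.start,
                "end": pk.end,
                "name": pk.name,
                "x_anterior": pair.x_anterior,
                "x_posterior": pair.x_posterior,
                "positional_skew": res.positional_skew,
                "z": res.z,
                "p": res.p,
                "class": cls,
                "degenerate": res.degenerate,
            }
        )
    return PeakClassTable(pd.DataFrame(rows))


def overlap_contingency(
    class_peaks: list[Interval], tf_peaks: list[Interval], universe: list[Interval]
) -> ContingencyTable:
    """Count TF-peak overlaps for class peaks vs the rest of the universe.

    Class membership is by exact coordinates: every class peak must be
    present in the universe.
    """
    class_keys = {(p.chrom, p.start, p.end) for p in class_peaks}
    universe_keys = {(p.chrom, p.start, p.end) for p in universe}
    missing = class_keys - universe_keys
    if missing:
        ex = sorted(missing)[0]
        raise ValueError(f"class peak {ex[0]}:{ex[1]}-{ex[2]} not in universe")
    ix = _IntervalIndex(tf_peaks)
    a = b = c = d = 0
    for pk in universe:
        in_class = (pk.chrom, pk.start, pk.end) in class_keys
        hit = ix.overlaps(pk.chrom, pk.start, pk.end)
        if in_class and hit:
            a += 1
        elif in_class:
            b += 1
        elif hit:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_one_tailed(table: ContingencyTable, direction: str = "enrichment") -> EnrichmentResult:
    """One-tailed Fisher's exact test on the 2x2 overlap table.

    The odds ratio is the sample cross-product ratio (a*d)/(b*c); when
    b*c = 0 it is +inf if a*d > 0 and NaN for the all-empty margin. The
    p-value is the exact hypergeometric tail in the stated direction:
    enrichment sums tables with >= a class/TF overlaps, depletion <= a.
    """
    if direction not in ("enrichment", "depletion"):
        raise ValueError(f"direction must be enrichment or depletion, got {direction!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    n_universe = table.universe_size
    n_tf = a + c
    n_class = a + b
    hg = stats.hypergeom(n_universe, n_tf, n_class)
    if direction == "enrichment":
        p = float(hg.sf(a - 1))  # P[X >= a]
    else:
        p = float(hg.cdf(a))  # P[X <= a]
    return EnrichmentResult(odds_ratio=odds, p_one_tailed=min(p, 1.0), direction=direction)
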