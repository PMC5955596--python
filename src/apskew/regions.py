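"""Patterning-region catalogs.

A catalog row is a genomic interval (enhancer or promoter) annotated
with the embryo half in which curated in situ data show it to be
active: anterior/posterior (A-P axis) or dorsal/ventral (D-V axis,
carried as the spatial control set).  The catalog is filtered to
regions that overlap a called accessibility peak in at least one sample
and carry at least a moderate amount of accessibility signal before any
skew statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import region_signal
from .tracks_io import CoverageTrack, GenomeTable, Interval

__all__ = [
    "Region",
    "RegionCatalog",
    "load_catalog",
    "filter_by_peaks",
    "filter_by_signal",
    "overlaps_any",
]

_CLASS_AXIS = {
    "anterior": "AP",
    "posterior": "AP",
    "dorsal": "DV",
    "ventral": "DV",
}
_KINDS = ("enhancer", "promoter")
_ZYGOTIC = ("maternal", "maternal-zygotic", "zygotic", "unknown")


@dataclass(frozen=True)
class Region:
    """A patterning region: interval plus activity annotations."""

    interval: Interval
    kind: str
    expected_active_half: str
    zygotic_class: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"invalid kind {self.kind!r}")
        if self.expected_active_half not in _CLASS_AXIS:
            raise ValueError(f"invalid class {self.expected_active_half!r}")
        if self.zygotic_class not in _ZYGOTIC:
            raise ValueError(f"invalid zygotic class {self.zygotic_class!r}")

    @property
    def axis(self) -> str:
        """"AP" for anterior/posterior regions, "DV" for dorsal/ventral."""
        return _CLASS_AXIS[self.expected_active_half]

    @property
    def name(self) -> str:
        return self.interval.name


@dataclass(frozen=True)
class RegionCatalog:
    regions: tuple[Region, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [
            (r.interval.chrom, r.interval.start, r.interval.end, r.kind)
            for r in self.regions
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (interval, kind) pair in catalog")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def subset(self, keep, note: str) -> "RegionCatalog":
        return RegionCatalog(
            tuple(r for r, k in zip(self.regions, keep) if k),
            provenance=(self.provenance + "; " + note).lstrip("; "),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.interval.chrom for r in self.regions],
                "start": [r.interval.start for r in self.regions],
                "end": [r.interval.end for r in self.regions],
                "name": [r.interval.name for r in self.regions],
                "kind": [r.kind for r in self.regions],
                "class": [r.expected_active_half for r in self.regions],
                "zygotic": [r.zygotic_class for r in self.regions],
            }
        )


_REQUIRED = ("chrom", "start", "end", "name", "kind", "class", "zygotic")


def load_catalog(path, genome: GenomeTable | None = None) -> RegionCatalog:
    """Load a tab-separated region catalog.

    Required columns: chrom, start, end, name, kind, class, zygotic.
    Unrecognised zygotic values map to "unknown"; an unrecognised class
    is an error. An optional boolean ``exclude_midline`` column marks
    regions curated away because their expression straddles the slice
    plane at ~50% egg length; true rows are dropped here.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    lengths = genome.lengths if genome is not None else None
    regions: list[Region] = []
    for idx, row in df.iterrows():
        zyg = str(row["zygotic"]).strip().lower()
        if zyg not in _ZYGOTIC:
            zyg = "unknown"
        cls = str(row["class"]).strip().lower()
        if cls not in _CLASS_AXIS:
            raise ValueError(f"{path}: row {idx}: invalid class {row['class']!r}")
        kind = str(row["kind"]).strip().lower()
        start, end = int(row["start"]), int(row["end"])
        if lengths is not None:
            if row["chrom"] not in lengths:
                raise ValueError(f"{path}: row {idx}: unknown chromosome {row['chrom']!r}")
            if start < 0 or end > lengths[row["chrom"]]:
                raise ValueError(f"{path}: row {idx}: interval out of range")
        if "exclude_midline" in df.columns and bool(row["exclude_midline"]):
            continue
        regions.append(
            Region(
                interval=Interval(str(row["chrom"]), start, end, name=str(row["name"])),
                kind=kind,
                expected_active_half=cls,
                zygotic_class=zyg,
                source=str(row.get("source", "")) if "source" in df.columns else "",
            )
        )
    return RegionCatalog(tuple(regions), provenance=str(path))


class _IntervalIndex:
    """Sorted, merged intervals per chromosome for overlap-any queries."""

    def __init__(self, intervals) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and self._ends[chrom][i - 1] > start

    def overlaps_batch(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        ex_starts = self._starts.get(chrom)
        if ex_starts is None:
            return np.zeros(len(starts), dtype=bool)
        idx = np.searchsorted(ex_starts, ends, side="left")
        hit = idx > 0
        hit[hit] = self._ends[chrom][idx[hit] - 1] > starts[hit]
        return hit


def overlaps_any(query: Interval, intervals) -> bool:
    """True if ``query`` shares >= 1 base with any interval in the set."""
    return _IntervalIndex(intervals).overlaps(query.chrom, query.start, query.end)


def filter_by_peaks(catalog: RegionCatalog, peak_sets: list[list[Interval]]) -> RegionCatalog:
    """Keep regions overlapping (>= 1 bp) a peak in at least one set."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    indexes = [_IntervalIndex(ps) for ps in peak_sets]
    keep = [
        any(ix.overlaps(r.interval.chrom, r.interval.start, r.interval.end) for ix in indexes)
        for r in catalog
    ]
    return catalog.subset(keep, note="filter_by_peaks")


def filter_by_signal(
    catalog: RegionCatalog, track: CoverageTrack, min_signal: float = 200.0
) -> RegionCatalog:
    """Keep regions with total track signal strictly above ``min_signal``."""
    if min_signal < 0:
        raise ValueError("min_signal must be >= 0")
    keep = [region_signal(track, r.interval, "sum") > min_signal for r in catalog]
    return catalog.subset(keep, note=f"filter_by_signal>{min_signal:g}")
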