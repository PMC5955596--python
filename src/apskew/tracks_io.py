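"""Genomic track and interval I/O.

Readers and writers for the plain-text formats the pipeline consumes:
two-column chromosome size tables, wiggle (fixedStep and variableStep,
with optional ``span``), bedGraph, and BED3/BED6 intervals.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open ``[start, end)``.
Wiggle positions are 1-based inclusive on disk and are converted at the
I/O boundary; BED and bedGraph are already 0-based half-open.  Bases not
covered by any wiggle/bedGraph record have signal 0 (uncovered means "no
signal", not "missing").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomeTable",
    "CoverageTrack",
    "Interval",
    "FragmentSet",
    "TrackParseError",
    "read_genome_table",
    "read_wiggle",
    "write_wiggle",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
]


class TrackParseError(ValueError):
    """Raised on malformed input files; message names the offending line."""


@dataclass(frozen=True)
class GenomeTable:
    """Ordered table of chromosome names and lengths (bp)."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for name, length in self.entries:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally stranded/named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class CoverageTrack:
    """Per-base non-negative signal over the chromosomes of a genome.

    Parameters
    ----------
    genome
        The genome the track is defined over; every chromosome gets an
        array of exactly its length.
    data
        Optional mapping of chromosome name to per-base signal.  Missing
        chromosomes are initialised to zeros.
    label
        Free-text sample name carried through the pipeline.
    """

    def __init__(
        self,
        genome: GenomeTable,
        data: dict[str, np.ndarray] | None = None,
        label: str = "",
    ) -> None:
        self.genome = genome
        self.label = label
        self.data: dict[str, np.ndarray] = {}
        lengths = genome.lengths
        data = data or {}
        for name, length in genome.entries:
            if name in data:
                arr = np.asarray(data[name], dtype=np.float64)
                if arr.shape != (length,):
                    raise ValueError(
                        f"array for {name} has length {arr.shape}, expected {length}"
                    )
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"non-finite signal on {name}")
                if arr.min(initial=0.0) < 0:
                    raise ValueError(f"negative signal on {name}")
                self.data[name] = arr
            else:
                self.data[name] = np.zeros(length, dtype=np.float64)
        unknown = set(data) - set(lengths)
        if unknown:
            raise ValueError(f"chromosomes not in genome: {sorted(unknown)}")
        # per-chromosome prefix sums, built lazily for fast interval totals
        self._cumsums: dict[str, np.ndarray] = {}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self) -> float:
        """Genome-wide total signal."""
        return float(sum(arr.sum() for arr in self.data.values()))

    def mean(self) -> float:
        """Genome-wide per-base mean signal."""
        return self.total() / self.genome.total_length

    def cumsum(self, chrom: str) -> np.ndarray:
        """Prefix-sum array (length+1) for O(1) interval totals.

        The track is treated as immutable once built; mutating ``data``
        in place after calling this gives stale results.
        """
        cs = self._cumsums.get(chrom)
        if cs is None:
            cs = np.concatenate([[0.0], np.cumsum(self.data[chrom])])
            self._cumsums[chrom] = cs
        return cs

    def interval_total(self, chrom: str, start: int, end: int) -> float:
        cs = self.cumsum(chrom)
        return float(cs[end] - cs[start])

    def scaled(self, factor: float, label: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            {c: a * factor for c, a in self.data.items()},
            label=self.label if label is None else label,
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.genome, {c: a.copy() for c, a in self.data.items()}, label=self.label
        )


@dataclass
class FragmentSet:
    """Columnar set of stranded sequencing fragments.

    Strand is mandatory (``+`` or ``-``): downstream transposase-offset
    shifting is strand-dependent and undefined for unstranded records.
    """

    chroms: np.ndarray  # object dtype
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    strands: np.ndarray  # "U1"

    def __post_init__(self) -> None:
        n = len(self.chroms)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="U1")
        if not (len(self.starts) == len(self.ends) == len(self.strands) == n):
            raise ValueError("column lengths differ")
        if n and not np.all((self.strands == "+") | (self.strands == "-")):
            raise ValueError("fragments must be stranded (+ or -)")
        if n and not np.all(self.starts < self.ends):
            raise ValueError("fragment with start >= end")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval]) -> "FragmentSet":
        ivs = list(intervals)
        return cls(
            chroms=np.array([iv.chrom for iv in ivs], dtype=object),
            starts=np.array([iv.start for iv in ivs], dtype=np.int64),
            ends=np.array([iv.end for iv in ivs], dtype=np.int64),
            strands=np.array([iv.strand for iv in ivs], dtype="U1"),
        )

    def to_intervals(self) -> list[Interval]:
        return [
            Interval(c, int(s), int(e), strand=t)
            for c, s, e, t in zip(self.chroms, self.starts, self.ends, self.strands)
        ]

    @classmethod
    def empty(cls) -> "FragmentSet":
        return cls(
            chroms=np.empty(0, dtype=object),
            starts=np.empty(0, dtype=np.int64),
            ends=np.empty(0, dtype=np.int64),
            strands=np.empty(0, dtype="U1"),
        )


# ---------------------------------------------------------------------------
# chrom.sizes


def read_genome_table(path) -> GenomeTable:
    """Read a two-column tab-separated chromosome size table."""
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise TrackParseError(f"{path}:{lineno}: expected two columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise TrackParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
            if name in seen:
                raise TrackParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise TrackParseError(f"{path}:{lineno}: non-positive length {length}")
            seen.add(name)
            entries.append((name, length))
    return GenomeTable(tuple(entries))


# ---------------------------------------------------------------------------
# wiggle


def _parse_wig_header(fields: list[str], lineno: int, path) -> dict[str, str]:
    out: dict[str, str] = {}
    for f in fields[1:]:
        if "=" not in f:
            raise TrackParseError(f"{path}:{lineno}: malformed attribute {f!r}")
        k, v = f.split("=", 1)
        out[k] = v
    return out


def read_wiggle(path, genome: GenomeTable, label: str = "") -> CoverageTrack:
    """Read a wiggle file (fixedStep and/or variableStep blocks).

    Wiggle positions are 1-based inclusive; ``span`` bases are filled per
    record.  Bases under no record are 0.
    """
    track = CoverageTrack(genome, label=label or str(path))
    lengths = genome.lengths
    mode: str | None = None
    chrom = ""
    pos = 0  # next 0-based start for fixedStep
    step = 1
    span = 1
    arr: np.ndarray | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            if fields[0] in ("fixedStep", "variableStep"):
                attrs = _parse_wig_header(fields, lineno, path)
                chrom = attrs.get("chrom", "")
                if chrom not in lengths:
                    raise TrackParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                arr = track.data[chrom]
                span = int(attrs.get("span", 1))
                if span < 1:
                    raise TrackParseError(f"{path}:{lineno}: span must be >= 1")
                mode = fields[0]
                if mode == "fixedStep":
                    if "start" not in attrs:
                        raise TrackParseError(f"{path}:{lineno}: fixedStep needs start=")
                    pos = int(attrs["start"]) - 1  # to 0-based
                    step = int(attrs.get("step", 1))
                    if pos < 0:
                        raise TrackParseError(f"{path}:{lineno}: start must be >= 1")
                continue
            if mode is None:
                raise TrackParseError(f"{path}:{lineno}: data before any step declaration")
            assert arr is not None
            if mode == "fixedStep":
                try:
                    value = float(fields[0])
                except ValueError as exc:
                    raise TrackParseError(f"{path}:{lineno}: bad value {fields[0]!r}") from exc
                if value < 0:
                    raise TrackParseError(f"{path}:{lineno}: negative value {value}")
                if pos + span > lengths[chrom]:
                    raise TrackParseError(
                        f"{path}:{lineno}: position beyond end of {chrom}"
                    )
                arr[pos : pos + span] = value
                pos += step
            else:  # variableStep
                if len(fields) < 2:
                    raise TrackParseError(f"{path}:{lineno}: variableStep needs 'pos value'")
                try:
                    start1 = int(fields[0])
                    value = float(fields[1])
                except ValueError as exc:
                    raise TrackParseError(f"{path}:{lineno}: bad record {line!r}") from exc
                if start1 < 1:
                    raise TrackParseError(f"{path}:{lineno}: position must be >= 1")
                if value < 0:
                    raise TrackParseError(f"{path}:{lineno}: negative value {value}")
                s = start1 - 1
                if s + span > lengths[chrom]:
                    raise TrackParseError(
                        f"{path}:{lineno}: position beyond end of {chrom}"
                    )
                arr[s : s + span] = value
    return track


def _value_runs(arr: np.ndarray) -> Iterator[tuple[int, int, float]]:
    """Yield maximal (start, end, value) runs of constant nonzero signal."""
    n = arr.size
    if n == 0:
        return
    change = np.nonzero(np.diff(arr))[0] + 1
    bounds = np.concatenate([[0], change, [n]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = arr[s]
        if v != 0.0:
            yield int(s), int(e), float(v)


def write_wiggle(track: CoverageTrack, path) -> None:
    """Write a track as fixedStep wiggle, omitting zero runs.

    Values are emitted with 6 significant digits; re-reading reproduces
    per-base values to that precision.
    """
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            arr = track.data[chrom]
            for s, e, v in _value_runs(arr):
                fh.write(f"fixedStep chrom={chrom} start={s + 1} step=1 span=1\n")
                text = f"{v:.6g}\n"
                fh.writelines([text] * (e - s))


# ---------------------------------------------------------------------------
# BED


def read_bed(path, genome: GenomeTable | None = None) -> list[Interval]:
    """Read BED3/BED6 intervals (extra columns beyond 6 are ignored)."""
    lengths = genome.lengths if genome is not None else None
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise TrackParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TrackParseError(f"{path}:{lineno}: bad coordinates") from exc
            name = parts[3] if len(parts) > 3 else ""
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError:
                score = 0.0
            strand = parts[5] if len(parts) > 5 else "."
            if start >= end:
                raise TrackParseError(
                    f"{path}:{lineno}: empty or inverted interval {start}-{end}"
                )
            if lengths is not None:
                if chrom not in lengths:
                    raise TrackParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if start < 0 or end > lengths[chrom]:
                    raise TrackParseError(f"{path}:{lineno}: interval out of range")
            try:
                out.append(Interval(chrom, start, end, strand=strand, name=name, score=score))
            except ValueError as exc:
                raise TrackParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:.6g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, genome: GenomeTable, label: str = "") -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open).

    Overlapping records are an error: a base assigned twice is ambiguous.
    """
    track = CoverageTrack(genome, label=label or str(path))
    lengths = genome.lengths
    seen = {name: np.zeros(length, dtype=bool) for name, length in genome.entries}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                parts = line.split()
            if len(parts) < 4:
                raise TrackParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            if chrom not in lengths:
                raise TrackParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise TrackParseError(f"{path}:{lineno}: bad record") from exc
            if not (0 <= start < end <= lengths[chrom]):
                raise TrackParseError(f"{path}:{lineno}: interval out of range")
            if value < 0:
                raise TrackParseError(f"{path}:{lineno}: negative value {value}")
            if seen[chrom][start:end].any():
                raise TrackParseError(f"{path}:{lineno}: overlapping bedGraph records")
            seen[chrom][start:end] = True
            track.data[chrom][start:end] = value
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write constant-value nonzero runs as bedGraph records."""
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            for s, e, v in _value_runs(track.data[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
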