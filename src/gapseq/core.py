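"""Genomic-interval data model, coordinate conventions, and BED plumbing.

Every stage of the palindrome caller works on three kinds of objects:
plain genomic intervals, uniquely mapped reads (an interval plus an
identifier), and a repeat-mask track (sorted, merged intervals per
chromosome).  Internal coordinates are 0-based half-open throughout --
the native convention of BED files, which are the I/O currency of the
pipeline.  Report output (candidate tables) uses 1-based inclusive
coordinates, the convention of the published candidate lists; the
conversion lives here and nowhere else.

Interval lengths are ``end - start`` (half-open), fixed project-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("gapseq")

__all__ = [
    "GenomicInterval",
    "MappedRead",
    "MaskTrack",
    "masked_bp",
    "to_report_coords",
    "read_bed",
    "read_reads_bed",
    "write_bed",
    "write_reads_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    Invariants: ``end > start`` (length >= 1) and a non-empty chromosome
    name.  Ordering is lexicographic by (chrom, start, end), which gives
    deterministic sort orders everywhere downstream.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Exact midpoint; used for read-to-bin and read-to-span assignment."""
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: float) -> bool:
        return self.start <= pos < self.end

    # -- reporting convention -------------------------------------------------

    def to_report_coords(self) -> tuple[str, int, int]:
        """Return (chrom, start, end) in 1-based inclusive coordinates."""
        return (self.chrom, self.start + 1, self.end)

    @classmethod
    def from_report_coords(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (round-trips losslessly)."""
        return cls(chrom, start - 1, end)


def to_report_coords(iv: GenomicInterval) -> tuple[str, int, int]:
    """Functional alias for :meth:`GenomicInterval.to_report_coords`."""
    return iv.to_report_coords()


@dataclass(frozen=True, order=True)
class MappedRead:
    """A uniquely mapped read: its genomic footprint plus an opaque id.

    Strand is deliberately absent -- read-pileup enrichment is
    strand-agnostic; strand only matters in junction sequence
    construction, which works on explicit strings.
    """

    interval: GenomicInterval
    read_id: str = ""

    @property
    def length(self) -> int:
        return self.interval.length


class MaskTrack:
    """Per-chromosome sorted, merged repeat-mask intervals.

    Overlapping or abutting input intervals are merged at construction,
    so ``masked_bp`` queries are simple clipped-intersection sums over a
    sorted array (binary search, no tree needed).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:  # overlap or abutment
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)
        self._warned_chroms: set[str] = set()

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskTrack":
        return cls(read_bed(path))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield GenomicInterval(chrom, int(s), int(e))

    def total_masked(self, chrom: str | None = None) -> int:
        if chrom is not None:
            if chrom not in self._starts:
                return 0
            return int((self._ends[chrom] - self._starts[chrom]).sum())
        return sum(self.total_masked(c) for c in self._starts)

    def masked_bp(self, region: GenomicInterval) -> int:
        """Total masked bases overlapping ``region`` (0 <= result <= length).

        Unknown chromosomes contribute 0 masked bp; a warning is logged
        once per chromosome.
        """
        if region.chrom not in self._starts:
            if self._starts and region.chrom not in self._warned_chroms:
                logger.warning(
                    "mask track has no chromosome %r; treating as unmasked",
                    region.chrom,
                )
                self._warned_chroms.add(region.chrom)
            return 0
        starts = self._starts[region.chrom]
        ends = self._ends[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if hi <= lo:
            return 0
        clipped = np.minimum(ends[lo:hi], region.end) - np.maximum(
            starts[lo:hi], region.start
        )
        return int(clipped.sum())

    def masked_bp_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized masked-bp for many query intervals on one chromosome."""
        out = np.zeros(len(starts), dtype=np.int64)
        if chrom not in self._starts:
            return out
        ms, me = self._starts[chrom], self._ends[chrom]
        lo = np.searchsorted(me, starts, side="right")
        hi = np.searchsorted(ms, ends, side="left")
        for i, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                out[i] = (
                    np.minimum(me[a:b], ends[i]) - np.maximum(ms[a:b], starts[i])
                ).sum()
        return out

    def overlaps(self, iv: GenomicInterval) -> bool:
        return self.masked_bp(iv) > 0


def masked_bp(track: MaskTrack, region: GenomicInterval) -> int:
    """Functional alias for :meth:`MaskTrack.masked_bp`."""
    return track.masked_bp(region)


# -- BED I/O ------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _bed_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_interval(path: str | Path, lineno: int, fields: Sequence[str]) -> GenomicInterval:
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated BED fields")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    try:
        return GenomicInterval(fields[0], start, end)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file as plain intervals (extra columns ignored)."""
    return [_parse_interval(path, n, f) for n, f in _bed_lines(path)]


def read_reads_bed(path: str | Path) -> list[MappedRead]:
    """Read a BED4 file of mapped reads; column 4 is the read id.

    Files lacking a name column get synthetic ids ``read1, read2, ...``
    in file order.
    """
    reads = []
    for n, f in _bed_lines(path):
        iv = _parse_interval(path, n, f)
        read_id = f[3] if len(f) > 3 and f[3] else f"read{len(reads) + 1}"
        reads.append(MappedRead(iv, read_id))
    return reads


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_reads_bed(path: str | Path, reads: Iterable[MappedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.read_id}\n")
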