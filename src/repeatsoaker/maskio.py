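"""Mask construction and interval I/O.

Low-complexity masks are sets of genomic intervals, held internally in the
BED convention (0-based, half-open). They can be built from RepeatMasker
``.out`` annotation files (1-based inclusive coordinates, converted on
parse), from BED files, or programmatically. Overlapping and abutting
intervals are merged into one canonical geometry so that per-read overlap
counts are never double-counted and the zero-threshold adjacency test is
well defined.
"""

from __future__ import annotations

import sys
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "RepeatMaskerRecord",
    "MaskSet",
    "MaskFormatError",
    "parse_repeatmasker",
    "read_bed",
    "write_bed",
    "merge_intervals",
]


class MaskFormatError(ValueError):
    """Raised for malformed RepeatMasker or BED input; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open reference interval [start, end).

    Coordinates are 0-based; ``end`` is exclusive, matching BED.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) shares at least one base with this interval."""
        return self.start < end and start < self.end

    def abuts(self, start: int, end: int) -> bool:
        """True iff [start, end) touches this interval with zero shared bases."""
        return self.end == start or self.start == end


@dataclass(frozen=True)
class RepeatMaskerRecord:
    """One annotation row of a RepeatMasker ``.out`` file (1-based inclusive)."""

    sw_score: int
    perc_div: float
    perc_del: float
    perc_ins: float
    query_chrom: str
    query_begin: int
    query_end: int
    strand: str
    repeat_name: str
    repeat_class: str

    def __post_init__(self) -> None:
        if self.query_begin < 1 or self.query_end < self.query_begin:
            raise ValueError(
                f"invalid RepeatMasker coordinates {self.query_begin}-{self.query_end}"
            )

    def to_interval(self) -> GenomicInterval:
        """Convert to a 0-based half-open interval named ``repeat/class``."""
        return GenomicInterval(
            self.query_chrom,
            self.query_begin - 1,
            self.query_end,
            name=f"{self.repeat_name}/{self.repeat_class}",
        )


class MaskSet:
    """Per-chromosome sorted, merged, queryable collection of mask intervals.

    Construct via :func:`merge_intervals` (or ``MaskSet.from_intervals``);
    the constructor itself assumes the input is already canonical per
    chromosome (sorted, with a gap of at least one base between neighbours).

    Queries run in O(log n + k) per call using binary search over the
    per-chromosome start/end coordinate arrays.
    """

    def __init__(self, by_chrom: dict[str, list[GenomicInterval]]):
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            for a, b in zip(ivs, ivs[1:]):
                if not a.end < b.start:
                    raise ValueError(
                        f"mask intervals on {chrom} not merged/sorted: {a} vs {b}"
                    )
            self._by_chrom[chrom] = list(ivs)
            self._starts[chrom] = [iv.start for iv in ivs]
            self._ends[chrom] = [iv.end for iv in ivs]

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "MaskSet":
        return merge_intervals(intervals)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    @property
    def n_regions(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    @property
    def total_masked_bases(self) -> int:
        return sum(len(iv) for iv in self)

    def intervals(self, chrom: str) -> list[GenomicInterval]:
        return list(self._by_chrom.get(chrom, ()))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return self.n_regions

    def query(
        self, chrom: str, start: int, end: int, include_abutting: bool = False
    ) -> list[GenomicInterval]:
        """Mask intervals overlapping [start, end) on ``chrom``.

        With ``include_abutting`` also returns intervals touching the window
        endpoint-to-endpoint with zero shared bases (the geometry behind the
        0 % threshold rule). An unknown chromosome yields an empty list.
        """
        if start >= end:
            raise ValueError(f"query window requires start < end, got {start},{end}")
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return []
        starts, ends = self._starts[chrom], self._ends[chrom]
        if include_abutting:
            # widen by one base each side: touching then becomes overlapping
            lo = bisect_right(ends, start - 1)
            hi = bisect_left(starts, end + 1)
        else:
            lo = bisect_right(ends, start)
            hi = bisect_left(starts, end)
        return ivs[lo:hi]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> MaskSet:
    """Merge intervals into a canonical :class:`MaskSet`.

    Per chromosome the result is the minimal sorted set of intervals
    covering exactly the union of the inputs; abutting intervals
    (``end_i == start_{i+1}``) are merged as well.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: dict[str, list[GenomicInterval]] = {}
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        out: list[GenomicInterval] = []
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
        merged[chrom] = out
    return MaskSet(merged)


# --- RepeatMasker .out parsing --------------------------------------------

_RM_N_HEADER_LINES = 3  # two column-header lines + one blank line


def parse_repeatmasker(stream: IO[str] | Iterable[str]) -> list[GenomicInterval]:
    """Parse RepeatMasker ``.out`` text into 0-based half-open intervals.

    The first three lines (header) are skipped. Each subsequent non-blank
    line must carry at least 11 whitespace-separated fields
    (score, div, del, ins, query, begin, end, left, strand, repeat, class).
    Record order is preserved; no merging is performed here.
    """
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(stream, start=1):
        if lineno <= _RM_N_HEADER_LINES:
            continue
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise MaskFormatError(
                f"expected >= 11 fields in RepeatMasker record, got {len(fields)}",
                lineno,
            )
        try:
            rec = RepeatMaskerRecord(
                sw_score=int(fields[0]),
                perc_div=float(fields[1]),
                perc_del=float(fields[2]),
                perc_ins=float(fields[3]),
                query_chrom=fields[4],
                query_begin=int(fields[5]),
                query_end=int(fields[6]),
                strand=fields[8],
                repeat_name=fields[9],
                repeat_class=fields[10],
            )
        except ValueError as exc:
            raise MaskFormatError(f"bad RepeatMasker record ({exc})", lineno) from exc
        out.append(rec.to_interval())
    return out


# --- BED I/O ---------------------------------------------------------------

_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(stream: IO[str] | Iterable[str]) -> list[GenomicInterval]:
    """Read BED3+ into intervals; track/browser/comment lines are skipped.

    Column 4, when present, becomes the interval name; further columns are
    ignored. Both tab- and space-delimited input are accepted.
    """
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(_BED_SKIP_PREFIXES):
            continue
        fields = stripped.split()
        if len(fields) < 3:
            raise MaskFormatError("BED line needs >= 3 columns", lineno)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise MaskFormatError(f"non-integer BED coordinates ({exc})", lineno)
        name = fields[3] if len(fields) > 3 else None
        try:
            out.append(GenomicInterval(fields[0], start, end, name=name))
        except ValueError as exc:
            raise MaskFormatError(str(exc), lineno) from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], stream: IO[str] = sys.stdout) -> None:
    """Write BED3 (+ name column when set), tab-delimited, no header."""
    for iv in intervals:
        if iv.name is not None:
            stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
        else:
            stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
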