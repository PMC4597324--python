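"""Per-read mask overlap and the percent-overlap threshold rule.

A read's footprint on the reference is derived from its CIGAR string:
aligned (M/=/X) stretches contribute reference positions, deletions (D)
and splice gaps (N) advance the reference without contributing, and
insertions/clips/padding (I/S/H/P) contribute nothing. The filter removes
a read when the fraction of its aligned bases lying inside the mask meets
the threshold tau (non-strict: fraction >= tau/100). At tau = 0 the rule is
special: a read is removed if it overlaps the mask by at least one base
*or* sits immediately proximal to (touching) a mask interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

from .maskio import MaskSet

if TYPE_CHECKING:  # pragma: no cover
    from .bamfilter import ReadRecord

__all__ = [
    "AlignedBlocks",
    "FilterDecision",
    "Verdict",
    "CigarError",
    "reference_blocks",
    "query_length",
    "overlap_bases",
    "is_adjacent",
    "decide",
]

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_AND_QUERY = frozenset("M=X")  # ops that consume both reference and query
_REF_ONLY = frozenset("DN")  # advance reference, emit no aligned positions
_QUERY_CONSUMING = frozenset("MIS=X")  # ops that consume query bases (SAM spec)


class CigarError(ValueError):
    """Raised for a malformed CIGAR string, naming the offending token."""


class Verdict(str, Enum):
    KEEP = "keep"
    REMOVE = "remove"


@dataclass(frozen=True)
class AlignedBlocks:
    """Sorted, non-overlapping reference intervals covered by aligned bases.

    ``aligned_length`` counts query bases in M/=/X operations, which equals
    the summed block lengths because only reference-and-query-consuming
    operations emit positions.
    """

    blocks: tuple[tuple[int, int], ...]
    aligned_length: int


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the threshold rule for one alignment record."""

    overlap_bases: int
    denominator: int
    fraction: float
    adjacent: bool
    verdict: Verdict
    threshold_pct: float


def _tokenize_cigar(cigar: str) -> list[tuple[int, str]]:
    if not cigar or cigar == "*":
        return []
    ops: list[tuple[int, str]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR {cigar!r} at {cigar[pos:]!r}")
        n = int(m.group(1))
        if n <= 0:
            raise CigarError(f"non-positive length in CIGAR token {m.group(0)!r}")
        ops.append((n, m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise CigarError(f"malformed CIGAR {cigar!r} at {cigar[pos:]!r}")
    return ops


def reference_blocks(pos: int, cigar: str) -> AlignedBlocks:
    """Reference intervals covered by the aligned bases of one record.

    ``pos`` is the 0-based leftmost reference coordinate. D and N advance
    the reference and therefore split blocks; I/S/H/P neither advance the
    reference nor split (an inserted stretch leaves the reference footprint
    contiguous, matching pysam's ``get_blocks``).
    """
    if pos < 0:
        raise ValueError(f"reference position must be >= 0, got {pos}")
    blocks: list[tuple[int, int]] = []
    aligned = 0
    ref = pos
    block_start: int | None = None
    for n, op in _tokenize_cigar(cigar):
        if op in _REF_AND_QUERY:
            if block_start is None:
                block_start = ref
            ref += n
            aligned += n
        elif op in _REF_ONLY:
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            ref += n
        # I/S/H/P: no reference movement, block stays open
    if block_start is not None:
        blocks.append((block_start, ref))
    return AlignedBlocks(blocks=tuple(blocks), aligned_length=aligned)


def query_length(cigar: str) -> int:
    """Full query sequence length implied by the CIGAR (M/I/S/=/X bases)."""
    return sum(n for n, op in _tokenize_cigar(cigar) if op in _QUERY_CONSUMING)


def overlap_bases(blocks: AlignedBlocks, maskset: MaskSet, chrom: str) -> int:
    """Number of aligned reference positions falling inside the mask.

    The mask must be merged; summing per-interval overlaps then equals the
    exact size of the position-set intersection.
    """
    total = 0
    for s, e in blocks.blocks:
        for iv in maskset.query(chrom, s, e):
            total += min(e, iv.end) - max(s, iv.start)
    return total


def is_adjacent(blocks: AlignedBlocks, maskset: MaskSet, chrom: str) -> bool:
    """True iff some aligned block touches a mask interval with zero shared bases."""
    for s, e in blocks.blocks:
        for iv in maskset.query(chrom, s, e, include_abutting=True):
            if iv.abuts(s, e):
                return True
    return False


def decide(
    read: "ReadRecord",
    maskset: MaskSet,
    threshold_pct: float,
    denominator: str = "aligned",
) -> FilterDecision:
    """Apply the percent-overlap threshold rule to one alignment record.

    Parameters
    ----------
    read
        Any object exposing ``unmapped`` (bool), ``chrom`` (str), ``pos``
        (0-based int) and ``cigar`` (str), e.g. a
        :class:`~repeatsoaker.bamfilter.ReadRecord`.
    maskset
        Merged low-complexity mask.
    threshold_pct
        tau in [0, 100]. For tau > 0 the verdict is remove iff
        overlap / denominator >= tau/100. tau == 0 removes any record
        overlapping the mask by >= 1 base or exactly abutting an interval.
    denominator
        ``"aligned"`` (M/=/X bases; default) or ``"read"`` (full query
        length including soft clips and insertions).
    """
    if not (0 <= threshold_pct <= 100):
        raise ValueError(f"threshold must be in [0, 100], got {threshold_pct}")
    if denominator not in ("aligned", "read"):
        raise ValueError(f"denominator must be 'aligned' or 'read', got {denominator!r}")

    if read.unmapped:
        return FilterDecision(0, 0, 0.0, False, Verdict.KEEP, threshold_pct)

    blocks = reference_blocks(read.pos, read.cigar)
    ov = overlap_bases(blocks, maskset, read.chrom)
    denom = (
        blocks.aligned_length if denominator == "aligned" else query_length(read.cigar)
    )
    fraction = ov / denom if denom > 0 else 0.0

    if threshold_pct == 0:
        adjacent = is_adjacent(blocks, maskset, read.chrom)
        remove = ov >= 1 or adjacent
    else:
        adjacent = False
        # exact comparison ov/denom >= tau/100 in integer-ish arithmetic,
        # avoiding float boundary fuzz at e.g. 50/100 vs tau=50
        remove = denom > 0 and ov * 100 >= threshold_pct * denom
    return FilterDecision(
        overlap_bases=ov,
        denominator=denom,
        fraction=fraction,
        adjacent=adjacent,
        verdict=Verdict.REMOVE if remove else Verdict.KEEP,
        threshold_pct=threshold_pct,
    )
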