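"""Synthetic masks and aligned reads with per-read ground truth.

Everything the filter consumes can be generated here on a toy genome:
a random mask (uniformly placed regions, then merged) and a SAM file of
single- or paired-end reads, optionally spliced, soft-clipped, unmapped,
or engineered with the mate on a different chromosome. Each record comes
with ground truth — overlap bases, aligned length, fraction, adjacency and
the verdict at each requested threshold — computed from explicit per-base
position sets. That oracle deliberately shares no code with the interval
arithmetic it validates: positions are materialized base by base and
blocks are re-derived as maximal runs of consecutive integers.

Also provided is the closed-form removal probability for uniform unspliced
reads over a single mask interval, for analytic checks of empirical
removal rates.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .maskio import GenomicInterval, MaskSet, merge_intervals

__all__ = [
    "GenomeSpec",
    "TruthEntry",
    "GroundTruth",
    "generate_mask",
    "generate_reads",
    "expected_removal_probability",
    "DEFAULT_GENOME",
]

DEFAULT_THRESHOLDS = (0.0, 25.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of a (toy) reference genome."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names: {names}")
        if any(length < 1 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be >= 1")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


# two 100 kb chromosomes: big enough for splice gaps, small enough that the
# per-base oracle stays cheap
DEFAULT_GENOME = GenomeSpec((("chr1", 100_000), ("chr2", 100_000)))


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one SAM record, keyed by (qname, mate)."""

    qname: str
    mate: int  # 0 = unpaired, 1 = first in pair, 2 = second
    chrom: str | None
    overlap_bases: int
    aligned_length: int
    fraction: float
    adjacent: bool
    verdicts: dict[float, str]  # threshold -> "keep" | "remove"


@dataclass
class GroundTruth:
    """Per-record truth table for one generated read set."""

    thresholds: tuple[float, ...]
    entries: list[TruthEntry] = field(default_factory=list)

    def by_key(self) -> dict[tuple[str, int], TruthEntry]:
        return {(e.qname, e.mate): e for e in self.entries}

    def removed_keys(self, threshold_pct: float) -> set[tuple[str, int]]:
        return {
            (e.qname, e.mate)
            for e in self.entries
            if e.verdicts[threshold_pct] == "remove"
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {
                "qname": e.qname,
                "mate": e.mate,
                "chrom": e.chrom if e.chrom is not None else "*",
                "overlap_bases": e.overlap_bases,
                "aligned_length": e.aligned_length,
                "fraction": e.fraction,
                "adjacent": int(e.adjacent),
            }
            for t in self.thresholds:
                row[f"verdict_{t:g}"] = e.verdicts[t]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path_or_stream) -> None:
        self.to_dataframe().to_csv(path_or_stream, sep="\t", index=False)


def generate_mask(
    seed: int,
    genome: GenomeSpec = DEFAULT_GENOME,
    n_regions: int = 40,
    min_len: int = 100,
    max_len: int = 500,
) -> MaskSet:
    """Place ``n_regions`` mask regions uniformly on the genome and merge.

    Region lengths are uniform in [min_len, max_len]; chromosomes are
    chosen proportionally to their length. Reproducible for a fixed seed.
    """
    if n_regions < 0:
        raise ValueError("n_regions must be >= 0")
    shortest = min(length for _, length in genome.chromosomes)
    if not (1 <= min_len <= max_len <= shortest):
        raise ValueError(
            f"need 1 <= min_len <= max_len <= shortest chromosome "
            f"({min_len}, {max_len}, {shortest})"
        )
    rng = random.Random(seed)
    intervals: list[GenomicInterval] = []
    weights = [length for _, length in genome.chromosomes]
    for i in range(n_regions):
        chrom, clen = rng.choices(genome.chromosomes, weights=weights)[0]
        rlen = rng.randint(min_len, max_len)
        start = rng.randint(0, clen - rlen)
        intervals.append(GenomicInterval(chrom, start, start + rlen, name=f"synth_{i}"))
    if not intervals:
        return MaskSet({})
    return merge_intervals(intervals)


# --- independent per-base oracle ------------------------------------------


def _oracle_positions(pos: int, cigar: str) -> tuple[set[int], int]:
    """Reference positions of aligned bases, materialized base by base.

    A deliberately naive CIGAR walk (one step per base) kept independent of
    the production interval code. Returns (position set, aligned length).
    """
    positions: set[int] = set()
    aligned = 0
    ref = pos
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "M=X":
            for _ in range(n):
                positions.add(ref)
                ref += 1
                aligned += 1
        elif ch in "DN":
            for _ in range(n):
                ref += 1
        # I, S, H, P: nothing on the reference
    return positions, aligned


def _runs(positions: set[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers, as half-open intervals."""
    runs: list[tuple[int, int]] = []
    for p in sorted(positions):
        if runs and p == runs[-1][1]:
            runs[-1] = (runs[-1][0], p + 1)
        else:
            runs.append((p, p + 1))
    return runs


def _mask_positions(maskset: MaskSet) -> dict[str, set[int]]:
    by_chrom: dict[str, set[int]] = {}
    for iv in maskset:
        by_chrom.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return by_chrom


def _oracle_truth(
    qname: str,
    mate: int,
    chrom: str | None,
    pos: int,
    cigar: str,
    unmapped: bool,
    mask_pos: dict[str, set[int]],
    thresholds: Sequence[float],
) -> TruthEntry:
    if unmapped:
        return TruthEntry(
            qname, mate, None, 0, 0, 0.0, False, {t: "keep" for t in thresholds}
        )
    read_pos, aligned = _oracle_positions(pos, cigar)
    mpos = mask_pos.get(chrom, set())
    overlap = len(read_pos & mpos)
    fraction = overlap / aligned if aligned else 0.0
    # adjacency: a read block touching a mask block endpoint-to-endpoint
    adjacent = False
    mask_runs = _runs(mpos) if mpos else []
    for s, e in _runs(read_pos):
        for a, b in mask_runs:
            if e == a or s == b:
                adjacent = True
    verdicts: dict[float, str] = {}
    for t in thresholds:
        if t == 0:
            remove = overlap >= 1 or adjacent
        else:
            remove = aligned > 0 and overlap * 100 >= t * aligned
        verdicts[t] = "remove" if remove else "keep"
    return TruthEntry(qname, mate, chrom, overlap, aligned, fraction, adjacent, verdicts)


# --- read generation -------------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@dataclass
class _Placement:
    chrom: str | None
    pos: int  # 0-based; -1 if unmapped
    cigar: str
    unmapped: bool
    seq_len: int


def _place_read(
    rng: random.Random,
    genome: GenomeSpec,
    read_len: int,
    spliced: bool,
    clipped: bool,
    unmapped: bool,
    chrom: str | None = None,
) -> _Placement:
    if unmapped:
        return _Placement(None, -1, "*", True, read_len)
    weights = [length for _, length in genome.chromosomes]
    if chrom is None:
        chrom, clen = rng.choices(genome.chromosomes, weights=weights)[0]
    else:
        clen = genome.length(chrom)
    clip = rng.randint(1, max(1, read_len // 3)) if clipped else 0
    m_total = read_len - clip
    if spliced and m_total >= 2:
        m1 = rng.randint(1, m_total - 1)
        m2 = m_total - m1
        gap = rng.randint(20, 2000)
        span = m1 + gap + m2
        if span > clen:
            gap = max(1, clen - m1 - m2 - 1)
            span = m1 + gap + m2
        cigar = (f"{clip}S" if clip else "") + f"{m1}M{gap}N{m2}M"
    else:
        span = m_total
        cigar = (f"{clip}S" if clip else "") + f"{m_total}M"
    if span > clen:
        raise ValueError(f"read span {span} exceeds chromosome {chrom} ({clen} bp)")
    start = rng.randint(0, clen - span)
    return _Placement(chrom, start, cigar, False, read_len)


def generate_reads(
    seed: int,
    genome: GenomeSpec = DEFAULT_GENOME,
    maskset: MaskSet | None = None,
    n_reads: int = 1000,
    read_len: int = 50,
    paired: bool = False,
    frac_spliced: float = 0.0,
    frac_unmapped: float = 0.0,
    frac_mate_diff_chr: float = 0.0,
    frac_clipped: float = 0.0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[str, GroundTruth]:
    """Generate a SAM file (as text) plus per-record ground truth.

    ``n_reads`` counts fragments: unpaired mode emits one record each,
    paired mode two. Placements are uniform over valid start positions
    (chromosomes weighted by length). ``frac_spliced`` reads get an
    N-split CIGAR, ``frac_clipped`` a leading soft clip, ``frac_unmapped``
    applies per record, and ``frac_mate_diff_chr`` per pair engineers the
    mate onto a different chromosome (never properly paired).

    Output is byte-identical for identical arguments.
    """
    for name, val in (
        ("frac_spliced", frac_spliced),
        ("frac_unmapped", frac_unmapped),
        ("frac_mate_diff_chr", frac_mate_diff_chr),
        ("frac_clipped", frac_clipped),
    ):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if read_len > min(length for _, length in genome.chromosomes):
        raise ValueError("read_len exceeds the shortest chromosome")
    if maskset is None:
        maskset = MaskSet({})
    rng = random.Random(seed)
    mask_pos = _mask_positions(maskset)
    truth = GroundTruth(thresholds=tuple(float(t) for t in thresholds))

    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom, length in genome.chromosomes:
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")

    def emit(qname: str, flag: int, p: _Placement, rnext: str, pnext: int, tlen: int):
        seq = _random_seq(rng, p.seq_len)
        rname = p.chrom if p.chrom is not None else "*"
        pos_field = p.pos + 1 if not p.unmapped else 0
        mapq = 0 if p.unmapped else 60
        lines.append(
            f"{qname}\t{flag}\t{rname}\t{pos_field}\t{mapq}\t{p.cigar}\t"
            f"{rnext}\t{pnext}\t{tlen}\t{seq}\t{'I' * p.seq_len}"
        )

    for i in range(n_reads):
        qname = f"synth{i:06d}"
        if not paired:
            unmapped = rng.random() < frac_unmapped
            spliced = rng.random() < frac_spliced
            clipped = rng.random() < frac_clipped
            p = _place_read(rng, genome, read_len, spliced, clipped, unmapped)
            flag = _FLAG_UNMAPPED if p.unmapped else 0
            emit(qname, flag, p, "*", 0, 0)
            truth.entries.append(
                _oracle_truth(
                    qname, 0, p.chrom, p.pos, p.cigar, p.unmapped, mask_pos, thresholds
                )
            )
            continue

        diff_chr = rng.random() < frac_mate_diff_chr and len(genome.chromosomes) > 1
        un1 = rng.random() < frac_unmapped
        un2 = rng.random() < frac_unmapped
        sp1 = rng.random() < frac_spliced
        sp2 = rng.random() < frac_spliced
        cl1 = rng.random() < frac_clipped
        cl2 = rng.random() < frac_clipped
        p1 = _place_read(rng, genome, read_len, sp1, cl1, un1)
        if diff_chr and not un1 and not un2:
            other = [c for c in genome.names if c != p1.chrom]
            p2 = _place_read(rng, genome, read_len, sp2, cl2, False, chrom=rng.choice(other))
        elif not un2:
            # mate downstream on the same chromosome when possible
            mate_chrom = p1.chrom if not un1 else None
            p2 = _place_read(rng, genome, read_len, sp2, cl2, False, chrom=mate_chrom)
        else:
            p2 = _place_read(rng, genome, read_len, sp2, cl2, True)
        proper = (
            not un1 and not un2 and not diff_chr and p1.chrom == p2.chrom
        )
        for mate, mine, theirs in ((1, p1, p2), (2, p2, p1)):
            flag = _FLAG_PAIRED
            flag |= _FLAG_READ1 if mate == 1 else _FLAG_READ2
            if proper:
                flag |= _FLAG_PROPER
            if mine.unmapped:
                flag |= _FLAG_UNMAPPED
            if theirs.unmapped:
                flag |= _FLAG_MATE_UNMAPPED
            if mate == 2 and not mine.unmapped:
                flag |= _FLAG_REVERSE
            if mate == 1 and not theirs.unmapped:
                flag |= _FLAG_MATE_REVERSE
            if theirs.unmapped or theirs.chrom is None:
                rnext, pnext = "*", 0
            elif theirs.chrom == mine.chrom:
                rnext, pnext = "=", theirs.pos + 1
            else:
                rnext, pnext = theirs.chrom, theirs.pos + 1
            tlen = 0
            if proper:
                lo = min(p1.pos, p2.pos)
                hi = max(p1.pos + read_len, p2.pos + read_len)
                tlen = (hi - lo) if mine.pos == lo else -(hi - lo)
            emit(qname, flag, mine, rnext, pnext, tlen)
            truth.entries.append(
                _oracle_truth(
                    qname,
                    mate,
                    mine.chrom,
                    mine.pos,
                    mine.cigar,
                    mine.unmapped,
                    mask_pos,
                    thresholds,
                )
            )
    return "\n".join(lines) + "\n", truth


# --- analytic removal probability -----------------------------------------


def expected_removal_probability(
    mask_len: int, read_len: int, n_valid_starts: int, threshold_pct: float
) -> float:
    """Removal probability for uniform unspliced reads over one mask interval.

    For a single mask interval of ``mask_len`` bases well inside a linear
    chromosome, reads of length L placed uniformly over ``n_valid_starts``
    start positions, and threshold tau: a read is removed when its overlap
    reaches k = ceil(tau/100 * L) bases, giving
    ``count = mask_len + L - 2k + 1`` qualifying starts (0 when the mask is
    shorter than k). At tau = 0 removal needs overlap >= 1 or abutment, so
    ``count = mask_len + L + 1``. Returns count / n_valid_starts, with
    count clamped to the number of feasible placements.
    """
    if mask_len < 1 or read_len < 1 or n_valid_starts < 1:
        raise ValueError("mask_len, read_len and n_valid_starts must be >= 1")
    if not 0 <= threshold_pct <= 100:
        raise ValueError(f"threshold must be in [0, 100], got {threshold_pct}")
    if threshold_pct == 0:
        count = mask_len + read_len + 1
    else:
        k = math.ceil(threshold_pct * read_len / 100)
        count = mask_len + read_len - 2 * k + 1 if mask_len >= k else 0
    count = max(0, min(count, n_valid_starts))
    return count / n_valid_starts
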