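"""Flagstat-style alignment summary statistics and condition comparison tables.

Counts are computed purely from flag bits and reference fields, following
samtools-flagstat conventions: secondary and supplementary records are
excluded from the pairing counts, and the three tabulated percentages
(properly paired, singletons, mate mapped to a different chromosome) all
use the number of paired-in-sequencing records as denominator. A percentage
with a zero denominator is reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .bamfilter import ReadRecord

__all__ = ["AlignmentStats", "flagstat", "flagstat_file", "compare_stats"]


def _pct(num: int, denom: int) -> float:
    return 100.0 * num / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one SAM/BAM file's flag fields."""

    total: int = 0
    secondary: int = 0
    supplementary: int = 0
    duplicates: int = 0
    mapped: int = 0
    paired_in_sequencing: int = 0
    properly_paired: int = 0
    singletons: int = 0
    mate_diff_chr: int = 0

    @property
    def mapped_pct(self) -> float:
        return _pct(self.mapped, self.total)

    @property
    def properly_paired_pct(self) -> float:
        return _pct(self.properly_paired, self.paired_in_sequencing)

    @property
    def singletons_pct(self) -> float:
        return _pct(self.singletons, self.paired_in_sequencing)

    @property
    def mate_diff_chr_pct(self) -> float:
        return _pct(self.mate_diff_chr, self.paired_in_sequencing)


def flagstat(records: Iterable[ReadRecord]) -> AlignmentStats:
    """Compute flagstat-style counts from a sequence of records.

    Pairing categories are restricted to primary, non-supplementary
    records: properly paired = paired and proper-pair flag and mapped;
    singleton = paired, mapped, mate unmapped; mate-different-chromosome =
    paired, both mates mapped, references differ.
    """
    total = secondary = supplementary = duplicates = mapped = 0
    paired = proper = singles = diff_chr = 0
    for rec in records:
        total += 1
        if rec.secondary:
            secondary += 1
        if rec.supplementary:
            supplementary += 1
        if rec.duplicate:
            duplicates += 1
        if not rec.unmapped:
            mapped += 1
        if rec.secondary or rec.supplementary or not rec.paired:
            continue
        paired += 1
        if rec.proper_pair and not rec.unmapped:
            proper += 1
        if not rec.unmapped and rec.mate_unmapped:
            singles += 1
        if (
            not rec.unmapped
            and not rec.mate_unmapped
            and rec.mate_chrom is not None
            and rec.mate_chrom != rec.chrom
        ):
            diff_chr += 1
    return AlignmentStats(
        total=total,
        secondary=secondary,
        supplementary=supplementary,
        duplicates=duplicates,
        mapped=mapped,
        paired_in_sequencing=paired,
        properly_paired=proper,
        singletons=singles,
        mate_diff_chr=diff_chr,
    )


def flagstat_file(path: str | Path) -> AlignmentStats:
    """Flagstat over a SAM/BAM file on disk."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as reader:
        return flagstat(ReadRecord.from_pysam(aln) for aln in reader)


def compare_stats(conditions: Sequence[tuple[str, AlignmentStats]]) -> pd.DataFrame:
    """Tabulate stats for several processing conditions, one row each.

    Columns mirror the conventional QC table: total reads and the three
    pairing percentages, plus deltas of each percentage relative to the
    first condition (empty for the first row and for a single condition).
    Row order follows the input order; duplicate labels are an error.
    """
    if not conditions:
        raise ValueError("at least one condition is required")
    labels = [label for label, _ in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels: {labels}")
    rows = []
    base = conditions[0][1]
    for i, (label, st) in enumerate(conditions):
        row = {
            "condition": label,
            "total_reads": st.total,
            "properly_paired_pct": round(st.properly_paired_pct, 2),
            "singletons_pct": round(st.singletons_pct, 2),
            "mate_diff_chr_pct": round(st.mate_diff_chr_pct, 2),
        }
        if i == 0:
            row["delta_properly_paired_pct"] = float("nan")
            row["delta_singletons_pct"] = float("nan")
            row["delta_mate_diff_chr_pct"] = float("nan")
        else:
            row["delta_properly_paired_pct"] = round(
                st.properly_paired_pct - base.properly_paired_pct, 2
            )
            row["delta_singletons_pct"] = round(
                st.singletons_pct - base.singletons_pct, 2
            )
            row["delta_mate_diff_chr_pct"] = round(
                st.mate_diff_chr_pct - base.mate_diff_chr_pct, 2
            )
        rows.append(row)
    return pd.DataFrame(rows)
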