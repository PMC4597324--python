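"""Stream a SAM/BAM file through the threshold rule and report what was removed.

The filter copies the input header (plus one program-group line recording
the parameters), preserves record order, and writes every kept record
unmodified — unless flag repair is requested, in which case a kept record
whose mate was removed gets its mate-unmapped bit set and its proper-pair
bit cleared.

Pair handling is explicit because mate semantics are genuinely a policy
choice: ``independent`` judges every record alone (single pass, the
default); ``drop_pair`` removes every record whose read name had any
failing record (two passes over the file). Unmapped records are kept by
default — they have no reference footprint to test — with ``drop_unmapped``
as an opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import pysam

from .maskio import MaskSet
from .overlapcore import FilterDecision, Verdict, decide

__all__ = ["ReadRecord", "FilterReport", "filter_alignments", "filter_file"]

logger = logging.getLogger("repeatsoaker")

_PG_ID = "repeatsoaker"


@dataclass(frozen=True)
class ReadRecord:
    """Aligner-independent view of one SAM/BAM record.

    ``mate_chrom`` has the SAM "=" convention already resolved to the
    record's own reference name.
    """

    qname: str
    paired: bool = False
    proper_pair: bool = False
    unmapped: bool = False
    mate_unmapped: bool = False
    reverse: bool = False
    mate_reverse: bool = False
    first_in_pair: bool = False
    second_in_pair: bool = False
    secondary: bool = False
    qcfail: bool = False
    duplicate: bool = False
    supplementary: bool = False
    chrom: str | None = None
    pos: int = -1
    mapq: int = 0
    cigar: str = "*"
    mate_chrom: str | None = None
    mate_pos: int = -1
    tlen: int = 0

    def __post_init__(self) -> None:
        if self.first_in_pair and self.second_in_pair:
            raise ValueError(f"{self.qname}: read flagged as both mates")

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "ReadRecord":
        return cls(
            qname=aln.query_name or "",
            paired=aln.is_paired,
            proper_pair=aln.is_proper_pair,
            unmapped=aln.is_unmapped,
            mate_unmapped=aln.is_paired and aln.mate_is_unmapped,
            reverse=aln.is_reverse,
            mate_reverse=aln.is_paired and aln.mate_is_reverse,
            first_in_pair=aln.is_paired and aln.is_read1,
            second_in_pair=aln.is_paired and aln.is_read2,
            secondary=aln.is_secondary,
            qcfail=aln.is_qcfail,
            duplicate=aln.is_duplicate,
            supplementary=aln.is_supplementary,
            chrom=None if aln.is_unmapped else aln.reference_name,
            pos=-1 if aln.is_unmapped else aln.reference_start,
            mapq=aln.mapping_quality,
            cigar=aln.cigarstring or "*",
            mate_chrom=None
            if (not aln.is_paired or aln.mate_is_unmapped)
            else aln.next_reference_name,
            mate_pos=aln.next_reference_start,
            tlen=aln.template_length,
        )


@dataclass
class FilterReport:
    """Aggregate counts for one filtering run.

    Invariant: ``kept + removed_overlap + removed_adjacent + removed_mate +
    removed_unmapped == total_in`` (the last term is nonzero only with the
    opt-in ``drop_unmapped``); ``removed_adjacent`` can be nonzero only at
    threshold 0.
    """

    threshold_pct: float
    pair_mode: str
    total_in: int = 0
    kept: int = 0
    removed_overlap: int = 0
    removed_adjacent: int = 0
    removed_mate: int = 0
    removed_unmapped: int = 0
    removed_by_chrom: dict[str, int] = field(default_factory=dict)

    @property
    def removed(self) -> int:
        return (
            self.removed_overlap
            + self.removed_adjacent
            + self.removed_mate
            + self.removed_unmapped
        )

    @property
    def percent_removed(self) -> float:
        if self.total_in == 0:
            return 0.0
        return 100.0 * (self.total_in - self.kept) / self.total_in

    def write_tsv(self, stream: TextIO) -> None:
        for key in (
            "threshold_pct",
            "pair_mode",
            "total_in",
            "kept",
            "removed_overlap",
            "removed_adjacent",
            "removed_mate",
            "removed_unmapped",
        ):
            stream.write(f"{key}\t{getattr(self, key)}\n")
        stream.write(f"percent_removed\t{self.percent_removed:.4f}\n")
        for chrom in sorted(self.removed_by_chrom):
            stream.write(f"removed_on\t{chrom}\t{self.removed_by_chrom[chrom]}\n")


def _record_key(rec: ReadRecord) -> tuple[str, bool]:
    return (rec.qname, rec.first_in_pair)


def _mate_key(rec: ReadRecord) -> tuple[str, bool]:
    return (rec.qname, not rec.first_in_pair)


def _count_removal(report: FilterReport, decision: FilterDecision, chrom: str | None) -> None:
    if decision.overlap_bases >= 1:
        report.removed_overlap += 1
    else:
        report.removed_adjacent += 1
    if chrom is not None:
        report.removed_by_chrom[chrom] = report.removed_by_chrom.get(chrom, 0) + 1


def _count_mate_removal(report: FilterReport, chrom: str | None) -> None:
    report.removed_mate += 1
    if chrom is not None:
        report.removed_by_chrom[chrom] = report.removed_by_chrom.get(chrom, 0) + 1


def filter_alignments(
    records: Iterable[ReadRecord],
    maskset: MaskSet,
    threshold_pct: float,
    pair_mode: str = "independent",
    denominator: str = "aligned",
    drop_unmapped: bool = False,
) -> tuple[list[ReadRecord], FilterReport]:
    """Filter an in-memory record sequence; the library-level core.

    Returns the kept records (order preserved) and the report. For
    ``pair_mode="drop_pair"`` the sequence is iterated twice, so pass a
    list, not a one-shot generator.
    """
    if pair_mode not in ("independent", "drop_pair"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    report = FilterReport(threshold_pct=threshold_pct, pair_mode=pair_mode)

    doomed_qnames: set[str] = set()
    if pair_mode == "drop_pair":
        records = list(records)
        for rec in records:
            if rec.unmapped:
                continue
            if decide(rec, maskset, threshold_pct, denominator).verdict is Verdict.REMOVE:
                doomed_qnames.add(rec.qname)

    kept: list[ReadRecord] = []
    for rec in records:
        report.total_in += 1
        if rec.unmapped:
            if drop_unmapped:
                report.removed_unmapped += 1
            else:
                kept.append(rec)
            continue
        decision = decide(rec, maskset, threshold_pct, denominator)
        if decision.verdict is Verdict.REMOVE:
            _count_removal(report, decision, rec.chrom)
        elif pair_mode == "drop_pair" and rec.qname in doomed_qnames:
            _count_mate_removal(report, rec.chrom)
        else:
            kept.append(rec)
    report.kept = len(kept)
    return kept, report


def filter_file(
    in_path: str | Path,
    maskset: MaskSet,
    threshold_pct: float,
    out_path: str | Path,
    pair_mode: str = "independent",
    repair_flags: bool = False,
    denominator: str = "aligned",
    drop_unmapped: bool = False,
    report_path: str | Path | None = None,
) -> FilterReport:
    """Filter a SAM/BAM file on disk, writing the cleaned file and a report.

    Output format mirrors the input (SAM in, SAM out; BAM in, BAM out).
    ``drop_pair`` mode and ``repair_flags`` read the input twice, so the
    input must be a real file, not a pipe. Mask chromosomes absent from the
    header are inert and trigger a warning only.
    """
    if pair_mode not in ("independent", "drop_pair"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    need_two_pass = pair_mode == "drop_pair" or repair_flags
    if str(in_path) == "-" and need_two_pass:
        raise ValueError(
            "drop_pair mode and flag repair require a seekable input file, not a pipe"
        )
    in_path, out_path = Path(in_path), Path(out_path)

    with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as probe:
        is_bam = probe.is_bam
        header_refs = set(probe.references)
    inert = [c for c in maskset.chromosomes if c not in header_refs]
    if inert:
        logger.warning(
            "mask chromosomes absent from the alignment header are inert: %s",
            ", ".join(inert),
        )

    # pass 1 (only when mate-aware behaviour was requested): find failing
    # records; doomed_qnames drives drop_pair, removed_keys drives repair
    doomed_qnames: set[str] = set()
    removed_keys: set[tuple[str, bool]] = set()
    if need_two_pass:
        with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as reader:
            for aln in reader:
                rec = ReadRecord.from_pysam(aln)
                if rec.unmapped:
                    continue
                if decide(rec, maskset, threshold_pct, denominator).verdict is Verdict.REMOVE:
                    doomed_qnames.add(rec.qname)
                    if rec.paired and not (rec.secondary or rec.supplementary):
                        removed_keys.add(_record_key(rec))

    report = FilterReport(threshold_pct=threshold_pct, pair_mode=pair_mode)
    with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as reader:
        header = reader.header.to_dict()
        header.setdefault("PG", []).append(
            {
                "ID": _PG_ID,
                "PN": _PG_ID,
                "CL": (
                    f"filter --threshold {threshold_pct} --pair-mode {pair_mode} "
                    f"--denominator {denominator}"
                    + (" --repair-flags" if repair_flags else "")
                    + (" --drop-unmapped" if drop_unmapped else "")
                ),
            }
        )
        mode = "wb" if is_bam else "w"
        with pysam.AlignmentFile(str(out_path), mode, header=header) as writer:
            for aln in reader:
                rec = ReadRecord.from_pysam(aln)
                report.total_in += 1
                if rec.unmapped:
                    if drop_unmapped or (
                        pair_mode == "drop_pair" and rec.qname in doomed_qnames
                    ):
                        if drop_unmapped:
                            report.removed_unmapped += 1
                        else:
                            _count_mate_removal(report, None)
                        continue
                    writer.write(aln)
                    report.kept += 1
                    continue
                decision = decide(rec, maskset, threshold_pct, denominator)
                if decision.verdict is Verdict.REMOVE:
                    _count_removal(report, decision, rec.chrom)
                    continue
                if pair_mode == "drop_pair" and rec.qname in doomed_qnames:
                    _count_mate_removal(report, rec.chrom)
                    continue
                if repair_flags and rec.paired and _mate_key(rec) in removed_keys:
                    aln.mate_is_unmapped = True
                    aln.is_proper_pair = False
                writer.write(aln)
                report.kept += 1
    if report_path is not None:
        with open(report_path, "w") as fh:
            report.write_tsv(fh)
    return report
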