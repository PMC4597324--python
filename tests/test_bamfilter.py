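"""End-to-end SAM/BAM filtering: pair modes, flag repair, reports, fidelity."""

import logging

import pysam
import pytest

from repeatsoaker import (
    GenomicInterval,
    ReadRecord,
    filter_alignments,
    filter_file,
    merge_intervals,
)
from conftest import SAM_HEADER

# mask chr1:[150,250); reads of 100M at various starts give known fractions
MASK = merge_intervals([GenomicInterval("chr1", 150, 250)])


def frac_read(name, start1):
    """Unpaired 100M read at 1-based start1."""
    return (name, 0, "chr1", start1, "100M", "*", 0, 0)


def read_lines(path):
    return [l for l in path.read_text().splitlines() if not l.startswith("@")]


class TestIndependentMode:
    def test_known_fractions_filtered_at_75(self, sam_file, tmp_path):
        # overlaps of a 100M read with [150,250): start1=1 → 0; 60 → 10;
        # 101 → 50; 151 → 100 (fully inside? [150,250) len 100 → yes)
        recs = [
            frac_read("keep_zero", 1),
            frac_read("keep_10pct", 61),
            frac_read("keep_50pct", 101),
            frac_read("rm_full_a", 151),
            frac_read("rm_80pct", 131),
            frac_read("rm_75pct", 126),
        ]
        out = tmp_path / "out.sam"
        report = filter_file(sam_file(recs), MASK, 75, out)
        assert report.total_in == 6
        assert report.kept == 3
        assert report.removed_overlap == 3
        assert report.removed_adjacent == 0
        assert report.percent_removed == pytest.approx(50.0)
        assert report.removed_by_chrom == {"chr1": 3}
        kept_names = [l.split("\t")[0] for l in read_lines(out)]
        assert kept_names == ["keep_zero", "keep_10pct", "keep_50pct"]

    def test_kept_records_byte_identical_and_order_preserved(self, sam_file, tmp_path):
        recs = [frac_read(f"r{i}", 1 + 17 * i) for i in range(30)]
        src = sam_file(recs)
        out = tmp_path / "out.sam"
        filter_file(src, MASK, 50, out)
        in_lines = read_lines(src)
        out_lines = read_lines(out)
        # out_lines must be a subsequence of in_lines, byte for byte
        idx = 0
        for line in out_lines:
            while idx < len(in_lines) and in_lines[idx] != line:
                idx += 1
            assert idx < len(in_lines), "output record not found in input order"
            idx += 1

    def test_adjacent_read_removed_only_at_zero(self, sam_file, tmp_path):
        # read [100,150) exactly abuts mask start 150
        recs = [("abut", 0, "chr1", 101, "50M", "*", 0, 0)]
        src = sam_file(recs)
        for t, expect_kept in ((0, 0), (25, 1), (50, 1), (75, 1)):
            out = tmp_path / f"t{t}.sam"
            report = filter_file(src, MASK, t, out)
            assert report.kept == expect_kept
            if t == 0:
                assert report.removed_adjacent == 1 and report.removed_overlap == 0

    def test_empty_input_gives_zero_report(self, sam_file, tmp_path):
        src = sam_file(SAM_HEADER)
        out = tmp_path / "out.sam"
        report = filter_file(src, MASK, 75, out)
        assert report.total_in == report.kept == 0
        assert report.percent_removed == 0.0
        assert read_lines(out) == []

    def test_unmapped_kept_by_default_dropped_on_request(self, sam_file, tmp_path):
        recs = [("un", 4, "*", 0, "*", "*", 0, 0), frac_read("ok", 1)]
        src = sam_file(recs)
        r1 = filter_file(src, MASK, 75, tmp_path / "a.sam")
        assert r1.kept == 2
        r2 = filter_file(src, MASK, 75, tmp_path / "b.sam", drop_unmapped=True)
        assert r2.kept == 1 and r2.removed_unmapped == 1

    def test_idempotence(self, sam_file, tmp_path):
        recs = [frac_read(f"r{i}", 1 + 13 * i) for i in range(40)]
        out1 = tmp_path / "o1.sam"
        out2 = tmp_path / "o2.sam"
        filter_file(sam_file(recs), MASK, 50, out1)
        report = filter_file(out1, MASK, 50, out2)
        assert report.kept == report.total_in
        assert read_lines(out1) == read_lines(out2)

    def test_threshold_monotonic_kept_sets(self, sam_file, tmp_path):
        recs = [frac_read(f"r{i}", 1 + 7 * i) for i in range(60)]
        src = sam_file(recs)
        kept = {}
        for t in (0, 25, 50, 75, 100):
            out = tmp_path / f"m{t}.sam"
            filter_file(src, MASK, t, out)
            kept[t] = {l.split("\t")[0] for l in read_lines(out)}
        for lo, hi in zip((0, 25, 50, 75), (25, 50, 75, 100)):
            assert kept[lo] <= kept[hi]

    def test_inert_mask_chromosome_warns(self, sam_file, tmp_path, caplog):
        mask = merge_intervals(
            [GenomicInterval("chr1", 150, 250), GenomicInterval("chrUn", 0, 100)]
        )
        with caplog.at_level(logging.WARNING, logger="repeatsoaker"):
            filter_file(sam_file([frac_read("r", 1)]), mask, 75, tmp_path / "o.sam")
        assert any("chrUn" in r.message for r in caplog.records)


PAIR_FLAGS_R1 = 0x1 | 0x2 | 0x20 | 0x40
PAIR_FLAGS_R2 = 0x1 | 0x2 | 0x10 | 0x80


def pair(name, start1_a, start1_b):
    return [
        (name, PAIR_FLAGS_R1, "chr1", start1_a, "100M", "=", start1_b, 300),
        (name, PAIR_FLAGS_R2, "chr1", start1_b, "100M", "=", start1_a, -300),
    ]


class TestPairModes:
    def test_drop_pair_removes_passing_mates(self, sam_file, tmp_path):
        # p1: both mates fail at 75; p2: first fails, second clean;
        # p3: both clean
        recs = pair("p1", 151, 151) + pair("p2", 151, 1001) + pair("p3", 1001, 2001)
        src = sam_file(recs)
        indep = filter_file(src, MASK, 75, tmp_path / "i.sam")
        assert indep.kept == 3 and indep.removed_overlap == 3
        dp = filter_file(src, MASK, 75, tmp_path / "d.sam", pair_mode="drop_pair")
        assert dp.kept == 2
        assert dp.removed_overlap == 3 and dp.removed_mate == 1
        names = {l.split("\t")[0] for l in read_lines(tmp_path / "d.sam")}
        assert names == {"p3"}

    def test_repair_flags_on_widowed_mate(self, sam_file, tmp_path):
        recs = pair("p", 151, 1001)  # first mate removed at 75, second kept
        out = tmp_path / "r.sam"
        filter_file(sam_file(recs), MASK, 75, out, repair_flags=True)
        (line,) = read_lines(out)
        flag = int(line.split("\t")[1])
        assert flag & 0x8, "mate-unmapped bit should be set"
        assert not flag & 0x2, "proper-pair bit should be cleared"

    def test_without_repair_widow_flags_untouched(self, sam_file, tmp_path):
        recs = pair("p", 151, 1001)
        out = tmp_path / "r.sam"
        filter_file(sam_file(recs), MASK, 75, out)
        (line,) = read_lines(out)
        flag = int(line.split("\t")[1])
        assert flag & 0x2 and not flag & 0x8

    def test_drop_pair_on_pipe_rejected(self, simple_mask, tmp_path):
        with pytest.raises(ValueError, match="seekable"):
            filter_file("-", simple_mask, 50, tmp_path / "o.sam", pair_mode="drop_pair")

    def test_unknown_pair_mode_rejected(self, simple_mask, sam_file, tmp_path):
        with pytest.raises(ValueError):
            filter_file(sam_file([]), simple_mask, 50, tmp_path / "o.sam",
                        pair_mode="both")


class TestInMemoryFilter:
    def test_conservation_and_report(self):
        recs = [
            ReadRecord(qname=f"r{i}", chrom="chr1", pos=100 + 10 * i, cigar="100M")
            for i in range(30)
        ]
        kept, report = filter_alignments(recs, MASK, 25)
        assert report.kept + report.removed == report.total_in == 30
        kept_names = {r.qname for r in kept}
        assert [r.qname for r in kept] == [r.qname for r in recs if r.qname in kept_names]

    def test_drop_pair_in_memory(self):
        recs = [
            ReadRecord(qname="p", paired=True, first_in_pair=True,
                       chrom="chr1", pos=150, cigar="100M"),
            ReadRecord(qname="p", paired=True, second_in_pair=True,
                       chrom="chr1", pos=5000, cigar="100M"),
        ]
        kept, report = filter_alignments(recs, MASK, 75, pair_mode="drop_pair")
        assert kept == [] and report.removed_mate == 1


class TestBamRoundTrip:
    def test_bam_in_bam_out(self, sam_file, tmp_path):
        src_sam = sam_file([frac_read("keep", 1), frac_read("rm", 151)])
        src_bam = tmp_path / "in.bam"
        pysam.sort("-o", str(src_bam), str(src_sam))
        out = tmp_path / "out.bam"
        report = filter_file(src_bam, MASK, 75, out)
        assert report.kept == 1
        with pysam.AlignmentFile(str(out), "rb") as fh:
            assert fh.is_bam
            names = [a.query_name for a in fh]
        assert names == ["keep"]

    def test_program_group_line_added(self, sam_file, tmp_path):
        out = tmp_path / "out.sam"
        filter_file(sam_file([frac_read("r", 1)]), MASK, 75, out)
        pg = [l for l in out.read_text().splitlines() if l.startswith("@PG")]
        assert any("repeatsoaker" in l and "--threshold 75" in l for l in pg)

    def test_report_tsv_written(self, sam_file, tmp_path):
        rep_path = tmp_path / "report.tsv"
        filter_file(sam_file([frac_read("r", 151)]), MASK, 75, tmp_path / "o.sam",
                    report_path=rep_path)
        body = rep_path.read_text()
        assert "removed_overlap\t1" in body and "percent_removed\t100.0000" in body
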