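import pytest

from repeatsoaker import GenomicInterval, merge_intervals

SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


def make_sam(records):
    """Assemble SAM text from (qname, flag, rname, pos1, cigar, rnext, pnext1, tlen) tuples.

    pos1/pnext1 are 1-based as in the SAM text itself. SEQ/QUAL are filled
    to match the CIGAR's query length.
    """
    lines = [SAM_HEADER.rstrip("\n")]
    for qname, flag, rname, pos1, cigar, rnext, pnext1, tlen in records:
        qlen = 0
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "MIS=X":
                    qlen += int(num)
                num = ""
        qlen = qlen or 10  # unmapped record with CIGAR '*'
        lines.append(
            f"{qname}\t{flag}\t{rname}\t{pos1}\t{60 if not flag & 0x4 else 0}\t{cigar}"
            f"\t{rnext}\t{pnext1}\t{tlen}\t{'A' * qlen}\t{'I' * qlen}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def sam_file(tmp_path):
    """Write SAM text (or record tuples) to a temp file, returning its path."""

    counter = {"n": 0}

    def _write(text_or_records):
        text = (
            text_or_records
            if isinstance(text_or_records, str)
            else make_sam(text_or_records)
        )
        counter["n"] += 1
        path = tmp_path / f"reads{counter['n']}.sam"
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def simple_mask():
    """One merged mask interval chr1:[150,250)."""
    return merge_intervals([GenomicInterval("chr1", 150, 250)])
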