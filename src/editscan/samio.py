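"""SAM/BAM reading and writing, backed by pysam/htslib."""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pysam

from editscan.model import AlignedRead

log = logging.getLogger(__name__)


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Load mapped records, keeping only the fields the pipeline uses.

    Records whose CIGAR does not consume exactly ``len(seq)`` query bases
    are rejected with a warning; the run continues.
    """
    reads: list[AlignedRead] = []
    n_rejected = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        it = iter(fh)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except OSError as exc:
                # htslib aborts on a malformed record; keep what parsed
                n_rejected += 1
                log.warning("rejecting malformed record(s) in %s: %s", path, exc)
                break
            if rec.is_unmapped or rec.cigarstring is None or rec.query_sequence is None:
                continue
            read = AlignedRead(
                qname=rec.query_name or "",
                chrom=rec.reference_name or "",
                pos=rec.reference_start + 1,
                cigar=rec.cigarstring,
                seq=rec.query_sequence,
                quals=list(rec.query_qualities or [30] * len(rec.query_sequence)),
                strand="-" if rec.is_reverse else "+",
                is_duplicate=rec.is_duplicate,
            )
            if read.query_length_from_cigar() != len(read.seq):
                n_rejected += 1
                log.warning(
                    "rejecting %s: CIGAR %s consumes %d query bases, seq is %d",
                    read.qname, read.cigar, read.query_length_from_cigar(), len(read.seq),
                )
                continue
            reads.append(read)
    if n_rejected:
        log.warning("rejected %d records with CIGAR/seq length mismatch", n_rejected)
    return reads


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    reference_lengths: Mapping[str, int],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = read.qname
            rec.reference_name = read.chrom
            rec.reference_start = read.pos - 1
            rec.cigarstring = read.cigar
            rec.query_sequence = read.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 60) + 33) for q in read.quals)
            )
            rec.mapping_quality = 60
            flag = 0
            if read.strand == "-":
                flag |= 0x10
            if read.is_duplicate:
                flag |= 0x400
            rec.flag = flag
            fh.write(rec)
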