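"""BED interval I/O and transcript-table loading.

Internally all intervals are 1-based inclusive; the BED writer converts
to 0-based half-open at the boundary of the format, and the reader
converts back.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from editscan.model import Interval, TranscriptModel


def write_bed(intervals: Iterable[tuple[str, Interval, str]], path: str | Path) -> None:
    """Write (chrom, interval, name) triples as BED."""
    with open(path, "w") as fh:
        for chrom, iv, name in intervals:
            fh.write(f"{chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, Interval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            out.append((chrom, Interval(start0 + 1, end), name))
    return out


def write_transcript_table(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """One exon per row: gene, chrom, strand, start, end, cds_start_phase."""
    rows = [
        {
            "gene": m.gene,
            "chrom": m.chrom,
            "strand": m.strand,
            "start": iv.start,
            "end": iv.end,
            "cds_start_phase": m.cds_start_phase,
        }
        for m in models
        for iv in m.exons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcript_table(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for (gene, chrom, strand, phase), grp in df.groupby(
        ["gene", "chrom", "strand", "cds_start_phase"], sort=False
    ):
        models.append(
            TranscriptModel(
                gene=str(gene),
                chrom=str(chrom),
                strand=str(strand),
                exons=[Interval(int(r.start), int(r.end)) for r in grp.itertuples()],
                cds_start_phase=int(phase),
            )
        )
    return models
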