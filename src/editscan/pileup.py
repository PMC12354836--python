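"""Text pileup reading/writing and pileup construction from aligned reads.

The reader speaks the legacy samtools (0.1.x) six-column pileup dialect:
chrom, 1-based position, reference base, depth, read-base string, base
qualities. The read-base mini-language is decoded fully: ``.``/``,`` are
reference matches on the forward/reverse strand, upper/lower-case letters
are substitutions, ``^X`` marks a read start (X encodes mapping quality
and is discarded), ``$`` a read end, ``+n<seq>``/``-n<seq>`` attach an
indel to the preceding observation, ``*`` is a deleted base and ``>``/``<``
are reference skips from spliced alignments.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

from editscan.model import AlignedRead, PileupColumn, ReadObservation

log = logging.getLogger(__name__)


class PileupParseError(ValueError):
    pass


def _decode_base_string(bases: str, quals: str, ref: str, lineno: int) -> list[ReadObservation]:
    obs: list[ReadObservation] = []
    i = 0
    qi = 0
    n = len(bases)
    ref = ref.upper()
    while i < n:
        ch = bases[i]
        if ch == "^":
            if i + 2 >= n + 1:
                raise PileupParseError(f"line {lineno}: dangling '^'")
            i += 2  # skip mapping-quality symbol; next obs starts a read
            if i >= n:
                raise PileupParseError(f"line {lineno}: '^' with no base")
            obs.append(_one_obs(bases[i], quals, qi, ref, lineno, first=True))
            qi += 1
            i += 1
        elif ch == "$":
            if not obs:
                raise PileupParseError(f"line {lineno}: '$' before any base")
            obs[-1].last_in_read = True
            i += 1
        elif ch in "+-":
            j = i + 1
            num = ""
            while j < n and bases[j].isdigit():
                num += bases[j]
                j += 1
            if not num:
                raise PileupParseError(f"line {lineno}: indel without length")
            length = int(num)
            if j + length > n:
                raise PileupParseError(f"line {lineno}: truncated indel sequence")
            if not obs:
                raise PileupParseError(f"line {lineno}: indel before any base")
            obs[-1].in_indel = True
            i = j + length
        else:
            obs.append(_one_obs(ch, quals, qi, ref, lineno))
            qi += 1
            i += 1
    if qi != len(quals):
        raise PileupParseError(
            f"line {lineno}: {qi} observations but {len(quals)} quality characters"
        )
    return obs


def _one_obs(ch: str, quals: str, qi: int, ref: str, lineno: int, first: bool = False) -> ReadObservation:
    if qi >= len(quals):
        raise PileupParseError(f"line {lineno}: quality string too short")
    q = ord(quals[qi]) - 33
    if ch == ".":
        base, strand = ref, "+"
    elif ch == ",":
        base, strand = ref, "-"
    elif ch in "ACGTN":
        base, strand = ch, "+"
    elif ch in "acgtn":
        base, strand = ch.upper(), "-"
    elif ch in "*#":
        base, strand = "*", "+"
    elif ch == ">":
        base, strand = ">", "+"
    elif ch == "<":
        base, strand = ">", "-"
    else:
        raise PileupParseError(f"line {lineno}: unexpected symbol {ch!r} in base string")
    o = ReadObservation(base=base, base_quality=q, read_strand=strand)
    if first:
        o.first_in_read = True
        o.pos_in_read = 1
    return o


def read_pileup(path: str | Path, material: str = "RNA", sample_id: str = "") -> list[PileupColumn]:
    """Parse a samtools-style text pileup into per-site columns.

    The decoded observation count is checked against the depth column for
    every line; a mismatch raises :class:`PileupParseError` with the line
    number.
    """
    columns: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PileupParseError(f"line {lineno}: expected >= 6 columns, got {len(fields)}")
            chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise PileupParseError(f"line {lineno}: non-integer pos/depth") from exc
            obs = _decode_base_string(bases, quals, ref, lineno)
            if len(obs) != depth:
                raise PileupParseError(
                    f"line {lineno}: depth column {depth} != decoded observations {len(obs)}"
                )
            columns.append(
                PileupColumn(
                    chrom=chrom,
                    pos=pos,
                    ref_base=ref.upper(),
                    observations=obs,
                    material=material,
                    sample_id=sample_id,
                )
            )
    log.debug("read %d pileup columns from %s", len(columns), path)
    return columns


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    """Serialize columns back to the six-column text dialect."""
    with open(path, "w") as fh:
        for col in columns:
            bases, quals = [], []
            for o in col.observations:
                if o.base == col.ref_base:
                    sym = "." if o.read_strand == "+" else ","
                elif o.base == "*":
                    sym = "*"
                elif o.base == ">":
                    sym = ">" if o.read_strand == "+" else "<"
                else:
                    sym = o.base if o.read_strand == "+" else o.base.lower()
                if o.first_in_read:
                    sym = "^~" + sym
                if o.last_in_read:
                    sym = sym + "$"
                bases.append(sym)
                quals.append(chr(min(o.base_quality, 60) + 33))
            fh.write(
                f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{col.coverage}\t"
                f"{''.join(bases)}\t{''.join(quals)}\n"
            )


def pileup_from_reads(
    reads: Sequence[AlignedRead],
    chrom: str,
    positions: Sequence[int],
    ref_bases: Sequence[str],
    material: str = "RNA",
    sample_id: str = "",
    exclude_duplicates: bool = True,
) -> list[PileupColumn]:
    """Build pileup columns at the requested positions from aligned reads.

    Reference skips (CIGAR N) are omitted by default, matching how spliced
    reads contribute no observation inside the intron they skip.
    """
    wanted = {p: i for i, p in enumerate(positions)}
    per_site: list[list[ReadObservation]] = [[] for _ in positions]
    for read in reads:
        if exclude_duplicates and read.is_duplicate:
            continue
        span = read.reference_span()
        if read.chrom != chrom or span.end < min(wanted) or span.start > max(wanted):
            continue
        rlen = read.query_length_from_cigar()
        for ref_pos, read_pos, base, qual, in_indel in read.walk():
            idx = wanted.get(ref_pos)
            if idx is None:
                continue
            per_site[idx].append(
                ReadObservation(
                    base=base,
                    base_quality=qual,
                    read_strand=read.strand,
                    pos_in_read=read_pos if base != "*" else None,
                    read_length=rlen if base != "*" else None,
                    in_indel=in_indel,
                )
            )
    return [
        PileupColumn(
            chrom=chrom,
            pos=pos,
            ref_base=ref_bases[i].upper(),
            observations=per_site[i],
            material=material,
            sample_id=sample_id,
        )
        for i, pos in enumerate(positions)
    ]
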