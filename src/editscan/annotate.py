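"""Minimal transcript-model annotation of editing calls.

Locates the codon containing a substitution from the exon structure and
strand of a transcript model, translates before/after codons with the
standard genetic code, and records the substitution as seen on the
transcript strand (so a genomic G>A in a minus-strand gene is reported
as C>U editing).
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

from Bio.Seq import Seq

from editscan.model import (
    COMPLEMENT,
    CodingAnnotation,
    EditingSiteCall,
    TranscriptModel,
    revcomp,
)


class Genome:
    """Sequence accessor over plain chromosome strings (1-based fetch)."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {k: v.upper() for k, v in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self._seqs[chrom][start - 1 : end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chroms(self) -> dict[str, int]:
        return {k: len(v) for k, v in self._seqs.items()}


GenomeLike = Union[Genome, Mapping[str, str]]


def _fetch(genome: GenomeLike, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Genome):
        return genome.fetch(chrom, start, end)
    return genome[chrom][start - 1 : end].upper()


def transcript_sequence(model: TranscriptModel, genome: GenomeLike) -> str:
    """Spliced transcript sequence in transcript orientation."""
    plus = "".join(_fetch(genome, model.chrom, iv.start, iv.end) for iv in model.exons)
    return plus if model.strand == "+" else revcomp(plus)


def _edit_class(tref: str, talt: str) -> str:
    if (tref, talt) == ("C", "T"):
        return "C>U"
    if (tref, talt) == ("A", "G"):
        return "A>I"
    to_rna = {"T": "U"}
    return f"{to_rna.get(tref, tref)}>{to_rna.get(talt, talt)}"


def annotate_site(
    chrom: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    model: TranscriptModel,
    genome: GenomeLike,
) -> CodingAnnotation:
    """Compute the coding consequence of a plus-strand substitution."""
    if chrom != model.chrom:
        raise ValueError(f"site on {chrom} but model on {model.chrom}")
    t = model.genomic_to_transcript(pos)
    if model.strand == "+":
        tref, talt = ref_base, alt_base
    else:
        tref, talt = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    edit_class = _edit_class(tref, talt)
    noncoding = CodingAnnotation(
        gene=model.gene,
        transcript_strand=model.strand,
        codon_before="",
        codon_after="",
        aa_before="",
        aa_after="",
        aa_position=0,
        effect="noncoding",
        edit_class_on_transcript=edit_class,
    )
    if t is None or t < model.cds_start_phase:
        return noncoding
    tx = transcript_sequence(model, genome)
    if tx[t] != tref:
        raise ValueError(
            f"transcript/reference inconsistency at {chrom}:{pos}: "
            f"transcript base {tx[t]!r}, expected {tref!r}"
        )
    codon_index = (t - model.cds_start_phase) // 3
    cs = model.cds_start_phase + 3 * codon_index
    codon_before = tx[cs : cs + 3]
    if len(codon_before) < 3:
        return noncoding
    within = t - cs
    codon_after = codon_before[:within] + talt + codon_before[within + 1 :]
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    if aa_after == "*" and aa_before != "*":
        effect = "stopgain"
    elif aa_after == aa_before:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return CodingAnnotation(
        gene=model.gene,
        transcript_strand=model.strand,
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=aa_before,
        aa_after=aa_after,
        aa_position=codon_index + 1,
        effect=effect,
        edit_class_on_transcript=edit_class,
    )


def annotate(call: EditingSiteCall, model: TranscriptModel, genome: GenomeLike) -> EditingSiteCall:
    """Attach a coding annotation to a call (in place, also returned)."""
    call.annotation = annotate_site(
        call.site.chrom, call.site.pos, call.site.ref_base, call.site.alt_base, model, genome
    )
    return call
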