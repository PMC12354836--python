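"""Domain types shared by every stage of the editing pipeline.

Coordinates are 1-based inclusive throughout (UCSC browser convention);
conversion to 0-based half-open happens only inside format writers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single-base substitution locus on the genomic plus strand."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"base must be one of ACGT, got {b!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass
class ReadObservation:
    """One read's evidence at one pileup column.

    ``pos_in_read``/``read_length`` may be unknown (None) when decoded from
    a text pileup, where only read-start (^) and read-end ($) marks carry
    positional information; ``first_in_read``/``last_in_read`` capture those.
    """

    base: str  # A/C/G/T, '*' for deletion, '>' for reference skip
    base_quality: int
    read_strand: str  # '+' or '-'
    pos_in_read: Optional[int] = None
    read_length: Optional[int] = None
    in_indel: bool = False
    first_in_read: bool = False
    last_in_read: bool = False

    def __post_init__(self) -> None:
        if self.base_quality < 0:
            raise ValueError("base_quality must be >= 0")
        if self.pos_in_read is not None:
            if self.pos_in_read < 1:
                raise ValueError("pos_in_read must be >= 1")
            if self.pos_in_read == 1:
                self.first_in_read = True
            if self.read_length is not None:
                if self.pos_in_read > self.read_length:
                    raise ValueError("pos_in_read exceeds read_length")
                if self.pos_in_read == self.read_length:
                    self.last_in_read = True

    @property
    def at_read_edge(self) -> bool:
        return self.first_in_read or self.last_in_read

    @property
    def is_base(self) -> bool:
        """True for an actual base call (not a deletion or reference skip)."""
        return self.base in "ACGT" or self.base == "N"


@dataclass
class PileupColumn:
    """Per-read observations at one genomic site for one sample/material."""

    chrom: str
    pos: int
    ref_base: str
    observations: list[ReadObservation]
    material: str = "RNA"  # 'DNA' or 'RNA'
    sample_id: str = ""

    @property
    def coverage(self) -> int:
        return len(self.observations)

    def base_count(self, base: str) -> int:
        return sum(1 for o in self.observations if o.base == base)

    def alt_observations(self, alt: str) -> list[ReadObservation]:
        return [o for o in self.observations if o.base == alt]

    def mean_base_quality(self) -> float:
        quals = [o.base_quality for o in self.observations if o.is_base]
        return sum(quals) / len(quals) if quals else 0.0

    def vaf(self, alt: str) -> float:
        ref = self.base_count(self.ref_base)
        altn = self.base_count(alt)
        return altn / (ref + altn) if (ref + altn) else 0.0


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class TranscriptModel:
    """Exon structure and reading frame of one gene on one chromosome.

    ``cds_start_phase`` is the number of transcript bases preceding the
    first complete codon (0 means the transcript starts in frame).
    """

    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds_start_phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(ex, ex[1:]):
            if b.start <= a.end:
                raise ValueError("exons overlap")
        self.exons = ex
        if not 0 <= self.cds_start_phase <= 2:
            raise ValueError("cds_start_phase must be 0..2")

    @property
    def exonic_length(self) -> int:
        return sum(len(iv) for iv in self.exons)

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position to a 0-based transcript offset, or None
        if the position is intronic/outside the model."""
        offset = 0
        for iv in self.exons:
            if pos in iv:
                plus_off = offset + (pos - iv.start)
                if self.strand == "+":
                    return plus_off
                return self.exonic_length - 1 - plus_off
            offset += len(iv)
        return None


@dataclass
class AlignedRead:
    """Minimal aligned-read record: exactly the fields the pipeline uses."""

    qname: str
    chrom: str
    pos: int  # 1-based leftmost mapped position
    cigar: str
    seq: str
    quals: list[int]
    strand: str = "+"
    is_duplicate: bool = False

    def cigar_ops(self) -> list[tuple[int, str]]:
        ops, n = [], ""
        for ch in self.cigar:
            if ch.isdigit():
                n += ch
            else:
                ops.append((int(n), ch))
                n = ""
        if n:
            raise ValueError(f"truncated CIGAR: {self.cigar!r}")
        return ops

    def query_length_from_cigar(self) -> int:
        return sum(n for n, op in self.cigar_ops() if op in "MIS=X")

    def reference_span(self) -> Interval:
        """Reference interval covered by the alignment (gaps included)."""
        ref = sum(n for n, op in self.cigar_ops() if op in "MDN=X")
        return Interval(self.pos, self.pos + ref - 1)

    def walk(self):
        """Yield (ref_pos, read_pos_1based, base, qual, in_indel) for every
        aligned or deleted reference position.

        Following pileup semantics, the aligned base immediately preceding
        an inserted or deleted segment carries the indel context; deleted
        positions themselves yield base '*'.
        """
        ops = self.cigar_ops()
        anchors: set[int] = set()  # 0-based query indices flanking an indel
        qp = 0
        for n, op in ops:
            if op in "ID":
                if qp > 0:
                    anchors.add(qp - 1)
                if op == "I":
                    anchors.update(range(qp, qp + n))  # inserted bases too
            if op in "MIS=X":
                qp += n
        rpos, qpos = self.pos, 0
        for n, op in ops:
            if op in "M=X":
                for i in range(n):
                    yield (
                        rpos + i,
                        qpos + i + 1,
                        self.seq[qpos + i].upper(),
                        self.quals[qpos + i],
                        (qpos + i) in anchors,
                    )
                rpos += n
                qpos += n
            elif op == "D":
                q = self.quals[qpos - 1] if qpos else 30
                for i in range(n):
                    yield (rpos + i, qpos, "*", q, True)
                rpos += n
            elif op == "N":
                rpos += n
            elif op in "IS":
                qpos += n
            elif op == "H":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")


@dataclass
class JunctionSpec:
    """One exon–intron–exon junction plus the edit site inside the
    downstream exon; geometry as printed in genome-browser coordinates."""

    chrom: str
    upstream_exon: Interval
    intron: Interval
    downstream_exon: Interval
    edit_site: GenomicSite
    boundary_width: int = 2
    assembly: str = "synthetic"

    def __post_init__(self) -> None:
        if self.intron.start != self.upstream_exon.end + 1:
            raise ValueError("intron must abut upstream exon")
        if self.downstream_exon.start != self.intron.end + 1:
            raise ValueError("downstream exon must abut intron")
        if self.edit_site.pos not in self.downstream_exon:
            raise ValueError("edit site must lie in the downstream exon")

    @property
    def boundary(self) -> Interval:
        """First bases of the downstream exon used to select junction reads."""
        s = self.downstream_exon.start
        return Interval(s, min(s + self.boundary_width - 1, self.downstream_exon.end))


@dataclass
class SpliceEditingResult:
    """Splice-state-resolved editing and intron retention for one sample."""

    sample_id: str
    n_spliced: int
    n_unspliced: int
    vaf_spliced: Optional[float]
    vaf_unspliced: Optional[float]
    retention_read: Optional[float]
    retention_cov: Optional[float] = None
    coverage_by_interval: dict[str, float] = field(default_factory=dict)


@dataclass
class CodingAnnotation:
    gene: str
    transcript_strand: str
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    aa_position: int
    effect: str  # synonymous | nonsynonymous | stopgain | noncoding
    edit_class_on_transcript: str  # e.g. 'C>U'

    @property
    def hgvs_p(self) -> str:
        return f"{self.aa_before}{self.aa_position}{self.aa_after}"


@dataclass
class EditingSiteCall:
    """A candidate RNA/DNA difference at one site in one sample."""

    site: GenomicSite
    sample_id: str
    dna_cov: int
    dna_alt: int
    rna_cov: int
    rna_alt: int
    fisher_p: float = 1.0
    filters: set[str] = field(default_factory=set)
    annotation: Optional[CodingAnnotation] = None

    @property
    def rna_vaf(self) -> float:
        return self.rna_alt / self.rna_cov if self.rna_cov else 0.0

    @property
    def dna_vaf(self) -> float:
        return self.dna_alt / self.dna_cov if self.dna_cov else 0.0

    @property
    def is_pass(self) -> bool:
        return not self.filters


@dataclass
class RecurrentSite:
    site: GenomicSite
    n_samples_detected: int
    sample_vafs: dict[str, float]
    annotation: Optional[CodingAnnotation] = None
    validated: Optional[bool] = None
    validation_flag: str = ""


@dataclass
class CohortRecord:
    """Per-sample phenotype row for association and survival analyses."""

    sample_id: str
    editing_pct: float
    time_tt: Optional[float] = None
    event_tt: Optional[int] = None
    time_os: Optional[float] = None
    event_os: Optional[int] = None
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.editing_pct <= 100.0:
            raise ValueError("editing_pct must be within [0, 100]")
        for t, e in ((self.time_tt, self.event_tt), (self.time_os, self.event_os)):
            if t is not None and t < 0:
                raise ValueError("survival times must be >= 0")
            if e is not None and e not in (0, 1):
                raise ValueError("event indicators must be 0/1")


@dataclass
class CutpointResult:
    """Maximally selected rank statistic outcome for one endpoint."""

    cutoff: float
    max_std_logrank: float
    n_low: int
    n_high: int
    hr: Optional[float]
    hr_ci_low: Optional[float]
    hr_ci_high: Optional[float]
    logrank_p: float


@dataclass
class AmplitudeWindow:
    """Per-basecall peak amplitudes around a Sanger-trace edit site."""

    positions: list[int]
    amp: dict[str, list[float]]  # keys A/C/G/T
    target_index: int
    orientation: str = "forward"  # relative to the transcript

    def __post_init__(self) -> None:
        npos = len(self.positions)
        for b in "ACGT":
            if b not in self.amp or len(self.amp[b]) != npos:
                raise ValueError(f"amplitude channel {b} missing or wrong length")
            if any(a < 0 for a in self.amp[b]):
                raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.target_index < npos:
            raise ValueError("target_index outside window")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward/reverse")
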