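"""Synthetic matched DNA/RNA data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a two-exon/one-intron locus whose geometry copies a real editing locus
  (68 bp upstream exon, 7,116 bp retained intron, 122 bp downstream exon,
  edit site 11 bases into the downstream exon at the middle C of a TCG
  serine codon, so the C>U change is the S>L recoding class);
* RNA reads drawn per *template*: a transcript molecule is intron-retained
  with probability rho and carries the edit with a class-specific rate
  (e_u on retained templates, e_s on spliced ones), so editing marks
  molecules, not reads;
* uniform substitution sequencing error at rate eps per base;
* a panel of independent sites (edited in sample subsets, plus clean
  sites, plus an HLA-gene decoy) to exercise calling, recurrence and
  validation;
* one regulator gene whose expression is linearly coupled to editing
  (standardized slope b against unit noise), among unrelated genes;
* exponential survival whose hazard drops for samples above an editing
  threshold placed at a fixed quantile, with independent uniform
  censoring.

Randomness is split with ``numpy.random.SeedSequence.spawn`` so each
sample owns an independent stream: adding samples never perturbs the
data of earlier ones.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from editscan.annotate import Genome
from editscan.model import (
    AlignedRead,
    AmplitudeWindow,
    CohortRecord,
    GenomicSite,
    Interval,
    JunctionSpec,
    PileupColumn,
    ReadObservation,
    TranscriptModel,
    revcomp,
)

BASES = np.array(list("ACGT"))

# geometry defaults: 68 bp exon, 7,116 bp intron, 122 bp exon, edit site
# 11 bases into the downstream exon (third codon base offset handled below)
DEFAULT_EXON_UP = 68
DEFAULT_INTRON = 7116
DEFAULT_EXON_DOWN = 122
DEFAULT_EDIT_OFFSET = 10  # 0-based offset of the edited C inside the downstream exon


@dataclass
class Locus:
    genome: Genome
    model: TranscriptModel
    junction: JunctionSpec

    @property
    def chrom(self) -> str:
        return self.model.chrom


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def make_locus(
    seed: int = 0,
    exon_up_len: int = DEFAULT_EXON_UP,
    intron_len: int = DEFAULT_INTRON,
    exon_down_len: int = DEFAULT_EXON_DOWN,
    flank: int = 300,
    strand: str = "+",
    chrom: str = "chrS",
    read_len: int = 100,
) -> Locus:
    """Build the reference sequence, transcript model and junction spec."""
    if min(exon_up_len, exon_down_len) < 2 or intron_len < read_len:
        raise ValueError("locus geometry too small for the read length")
    if exon_down_len < DEFAULT_EDIT_OFFSET + 2:
        raise ValueError("downstream exon too short to host the edit site")
    rng = np.random.default_rng(seed)
    total = flank + exon_up_len + intron_len + exon_down_len + flank
    seq = _random_seq(rng, total)

    exon_up = Interval(flank + 1, flank + exon_up_len)
    intron = Interval(exon_up.end + 1, exon_up.end + intron_len)
    exon_down = Interval(intron.end + 1, intron.end + exon_down_len)
    edit_pos = exon_down.start + DEFAULT_EDIT_OFFSET

    model = TranscriptModel(
        gene="GENE_S",
        chrom=chrom,
        strand=strand,
        exons=[exon_up, exon_down],
        cds_start_phase=0,
    )
    if strand == "+":
        # plant T C G so the edited C sits at codon position 2 (TCG -> TTG)
        seq[edit_pos - 2 : edit_pos + 1] = list("TCG")
        t = model.genomic_to_transcript(edit_pos)
        model.cds_start_phase = (t - 1) % 3
        site = GenomicSite(chrom, edit_pos, "C", "T")
    else:
        # genomic C G A reverse-complements to T C G on the transcript
        seq[edit_pos - 2 : edit_pos + 1] = list("CGA")
        t = model.genomic_to_transcript(edit_pos)
        model.cds_start_phase = (t - 1) % 3
        site = GenomicSite(chrom, edit_pos, "G", "A")

    genome = Genome({chrom: "".join(seq)})
    junction = JunctionSpec(
        chrom=chrom,
        upstream_exon=exon_up,
        intron=intron,
        downstream_exon=exon_down,
        edit_site=site,
    )
    return Locus(genome=genome, model=model, junction=junction)


# ---------------------------------------------------------------- reads

def _apply_errors(rng: np.random.Generator, bases: np.ndarray, eps: float) -> np.ndarray:
    err = rng.random(len(bases)) < eps
    if err.any():
        idx = np.flatnonzero(err)
        for i in idx:
            choices = [b for b in "ACGT" if b != bases[i]]
            bases[i] = choices[rng.integers(0, 3)]
    return bases


def _quals(rng: np.random.Generator, n: int) -> list[int]:
    return [int(q) for q in np.clip(np.round(rng.normal(37, 3, size=n)), 2, 41)]


def simulate_junction_reads(
    rng: np.random.Generator,
    locus: Locus,
    depth: int,
    e_s: float,
    e_u: float,
    rho: float,
    eps: float = 0.001,
    read_len: int = 100,
    sample_id: str = "S",
) -> tuple[list[AlignedRead], int]:
    """Draw ``depth`` junction-covering RNA reads; every read covers both
    the intron/exon boundary and the edit site. Returns (reads, number of
    reads drawn from edited templates)."""
    j = locus.junction
    g = locus.genome
    s = j.downstream_exon.start
    edit_pos = j.edit_site.pos
    edit_off = edit_pos - s  # offset inside downstream exon
    reads: list[AlignedRead] = []
    n_edited = 0
    retained = rng.random(depth) < rho
    for i in range(depth):
        edited = rng.random() < (e_u if retained[i] else e_s)
        n_edited += edited
        if retained[i]:
            # contiguous template across the intron/exon border
            lo = edit_pos - read_len + 1
            hi = s - 1
            pos = int(rng.integers(lo, hi + 1))
            bases = np.array(list(g.fetch(j.chrom, pos, pos + read_len - 1)))
            if edited:
                bases[edit_pos - pos] = j.edit_site.alt_base
            cigar = f"{read_len}M"
        else:
            # spliced template: suffix of upstream exon + prefix of downstream
            b_min = edit_off + 1 + 1  # cover edit site, 1-based prefix length
            a_max = min(read_len - b_min, len(j.upstream_exon))
            a = int(rng.integers(1, a_max + 1))
            b = read_len - a
            pos = j.upstream_exon.end - a + 1
            bases = np.array(
                list(
                    g.fetch(j.chrom, pos, j.upstream_exon.end)
                    + g.fetch(j.chrom, s, s + b - 1)
                )
            )
            if edited:
                bases[a + edit_off] = j.edit_site.alt_base
            cigar = f"{a}M{len(j.intron)}N{b}M"
        bases = _apply_errors(rng, bases, eps)
        reads.append(
            AlignedRead(
                qname=f"{sample_id}:r{i}",
                chrom=j.chrom,
                pos=pos,
                cigar=cigar,
                seq="".join(bases),
                quals=_quals(rng, read_len),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return reads, n_edited


def simulate_coverage_reads(
    rng: np.random.Generator,
    locus: Locus,
    n_reads: int,
    e_s: float,
    e_u: float,
    rho: float,
    eps: float = 0.001,
    read_len: int = 100,
    sample_id: str = "S",
) -> list[AlignedRead]:
    """Depth-uniform RNA reads over the whole locus.

    A fraction rho of transcript molecules retain the intron. The modeled
    exons are interior segments of a longer mRNA, so templates extend one
    read length beyond them on both sides; fragment starts are uniform
    over each template's valid positions and reads are allocated to a
    class proportionally to rho times its fragment count. Under this
    scheme both the junction-read and the depth-ratio retention
    estimators converge to rho.
    """
    j = locus.junction
    g = locus.genome
    pad = read_len - 1
    len_up = len(j.upstream_exon)
    len_intron = len(j.intron)
    len_down = len(j.downstream_exon)
    lr_starts = (pad + len_up + len_intron + len_down + pad) - read_len + 1
    ls_starts = (pad + len_up + len_down + pad) - read_len + 1
    w_u = rho * lr_starts
    w_s = (1 - rho) * ls_starts
    p_retained = w_u / (w_u + w_s) if (w_u + w_s) > 0 else 0.0
    j_off = pad + len_up  # 0-based template offset of the downstream exon start
    edit_off = j.edit_site.pos - j.downstream_exon.start
    reads: list[AlignedRead] = []
    for i in range(n_reads):
        retained = rng.random() < p_retained
        edited = rng.random() < (e_u if retained else e_s)
        if retained:
            start = int(rng.integers(0, lr_starts))  # 0-based template offset
            pos = j.upstream_exon.start - pad + start
            bases = np.array(list(g.fetch(j.chrom, pos, pos + read_len - 1)))
            if edited and pos <= j.edit_site.pos <= pos + read_len - 1:
                bases[j.edit_site.pos - pos] = j.edit_site.alt_base
            cigar = f"{read_len}M"
        else:
            start = int(rng.integers(0, ls_starts))
            if start + read_len - 1 < j_off:
                pos = j.upstream_exon.start - pad + start
                cigar = f"{read_len}M"
                bases = np.array(list(g.fetch(j.chrom, pos, pos + read_len - 1)))
            elif start >= j_off:
                pos = j.downstream_exon.start + (start - j_off)
                cigar = f"{read_len}M"
                bases = np.array(list(g.fetch(j.chrom, pos, pos + read_len - 1)))
            else:
                a = j_off - start
                b = read_len - a
                pos = j.upstream_exon.start - pad + start
                cigar = f"{a}M{len_intron}N{b}M"
                bases = np.array(
                    list(
                        g.fetch(j.chrom, pos, j.upstream_exon.end)
                        + g.fetch(j.chrom, j.downstream_exon.start, j.downstream_exon.start + b - 1)
                    )
                )
            if edited and start <= j_off + edit_off <= start + read_len - 1:
                bases[j_off + edit_off - start] = j.edit_site.alt_base
        bases = _apply_errors(rng, bases, eps)
        reads.append(
            AlignedRead(
                qname=f"{sample_id}:c{i}",
                chrom=j.chrom,
                pos=pos,
                cigar=cigar,
                seq="".join(bases),
                quals=_quals(rng, read_len),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return reads


def synthetic_pileup_column(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    depth: int,
    vaf: float,
    eps: float = 0.001,
    read_len: int = 100,
    material: str = "RNA",
    sample_id: str = "",
) -> PileupColumn:
    """One pileup column with alt planted at the given fraction, uniform
    substitution errors, alternating strands and uniform read positions."""
    obs = []
    for i in range(depth):
        base = alt if rng.random() < vaf else ref
        if rng.random() < eps:
            choices = [b for b in "ACGT" if b != base]
            base = choices[rng.integers(0, 3)]
        obs.append(
            ReadObservation(
                base=base,
                base_quality=int(np.clip(round(rng.normal(37, 3)), 2, 41)),
                read_strand="+" if i % 2 == 0 else "-",
                pos_in_read=int(rng.integers(1, read_len + 1)),
                read_length=read_len,
            )
        )
    return PileupColumn(
        chrom=chrom, pos=pos, ref_base=ref, observations=obs,
        material=material, sample_id=sample_id,
    )


def sanger_window(
    rng: np.random.Generator,
    locus: Locus,
    editing_fraction: float,
    peak: float = 1000.0,
    noise: float = 5.0,
    half_width: int = 3,
) -> AmplitudeWindow:
    """Amplitude table around the edit site whose edited/(edited+primary)
    ratio at the target equals the overall transcript editing fraction."""
    j = locus.junction
    pos0 = j.edit_site.pos - half_width
    seq = locus.genome.fetch(j.chrom, pos0, j.edit_site.pos + half_width)
    amp = {b: [] for b in "ACGT"}
    for i, base in enumerate(seq):
        for b in "ACGT":
            signal = 0.0
            if i == half_width:
                if b == j.edit_site.ref_base:
                    signal = peak * (1.0 - editing_fraction)
                elif b == j.edit_site.alt_base:
                    signal = peak * editing_fraction
            elif b == base:
                signal = peak
            amp[b].append(float(max(0.0, signal + rng.normal(0, noise) * (signal > 0))))
    return AmplitudeWindow(
        positions=list(range(pos0, pos0 + len(seq))),
        amp=amp,
        target_index=half_width,
        orientation="forward",
    )


# ---------------------------------------------------------------- sample

@dataclass
class SampleSim:
    sample_id: str
    e_s: float
    e_u: float
    rho: float
    rna_reads: list[AlignedRead]
    dna_column: PileupColumn
    sanger: AmplitudeWindow
    n_edited_templates: int

    @property
    def expected_overall_editing(self) -> float:
        return self.rho * self.e_u + (1 - self.rho) * self.e_s


def simulate_sample(
    rng: np.random.Generator,
    locus: Locus,
    e_s: float,
    e_u: float,
    rho: float,
    depth_rna: int = 500,
    depth_dna: int = 50,
    eps: float = 0.001,
    read_len: int = 100,
    sample_id: str = "S",
) -> SampleSim:
    """Matched DNA/RNA data for one sample at the junction locus."""
    reads, n_edited = simulate_junction_reads(
        rng, locus, depth_rna, e_s, e_u, rho, eps=eps, read_len=read_len, sample_id=sample_id
    )
    site = locus.junction.edit_site
    dna_col = synthetic_pileup_column(
        rng, site.chrom, site.pos, site.ref_base, site.alt_base,
        depth=depth_dna, vaf=0.0, eps=eps, read_len=read_len,
        material="DNA", sample_id=sample_id,
    )
    overall = rho * e_u + (1 - rho) * e_s
    amps = sanger_window(rng, locus, overall)
    return SampleSim(
        sample_id=sample_id,
        e_s=e_s,
        e_u=e_u,
        rho=rho,
        rna_reads=reads,
        dna_column=dna_col,
        sanger=amps,
        n_edited_templates=n_edited,
    )


# ----------------------------------------------------------------- panel

@dataclass
class SitePanel:
    """Multi-site matched pileups across a cohort with planted truth."""

    genome: Genome
    models: list[TranscriptModel]
    sites: list[GenomicSite]
    dna: dict[str, dict[tuple[str, int], PileupColumn]]
    rna: dict[str, dict[tuple[str, int], PileupColumn]]
    edited_in: dict[tuple, list[str]]  # site.key -> sample ids edited
    planted_vaf: dict[tuple, float]
    recurrent_truth: set  # site.keys edited in >= 2 samples (non-HLA)
    hla_site_keys: set


def _panel_genome(rng: np.random.Generator, n_sites: int, chrom: str = "chrP"):
    """A chromosome hosting one mini-gene per site, each a single exon
    with the site's C at codon position 2 of a TCG codon; one decoy gene
    carries an HLA symbol."""
    spacing = 60
    length = spacing * (n_sites + 2)
    seq = _random_seq(rng, length)
    models, sites = [], []
    for k in range(n_sites):
        pos = spacing * (k + 1)  # 1-based site position
        seq[pos - 2 : pos + 1] = list("TCG")
        exon = Interval(pos - 16, pos + 13)  # 30 bp exon, site at offset 15
        t_off = pos - exon.start  # transcript offset of the C
        phase = (t_off - 1) % 3
        gene = "HLA-TEST" if k == n_sites - 1 else f"GENE{k:03d}"
        models.append(
            TranscriptModel(gene=gene, chrom=chrom, strand="+", exons=[exon], cds_start_phase=phase)
        )
        sites.append(GenomicSite(chrom, pos, "C", "T"))
    return Genome({chrom: "".join(seq)}), models, sites


def simulate_site_panel(
    seed_seq: np.random.SeedSequence,
    sample_ids: Sequence[str],
    n_recurrent: int = 6,
    n_singleton: int = 2,
    n_unedited: int = 20,
    vaf_range: tuple[float, float] = (0.10, 0.50),
    cov_range: tuple[int, int] = (30, 100),
    dna_depth: int = 50,
    eps: float = 0.001,
) -> SitePanel:
    """Plant editing at some sites in >= 2 samples, at some in exactly one,
    and leave the rest clean; the last planted-recurrent site sits in an
    HLA decoy gene so the exclusion stage has work to do."""
    rng = np.random.default_rng(seed_seq)
    n_sites = n_recurrent + n_singleton + n_unedited + 1  # +1 HLA decoy
    genome, models, sites = _panel_genome(rng, n_sites)
    edited_in: dict[tuple, list[str]] = {}
    planted_vaf: dict[tuple, float] = {}
    hla_keys = {sites[-1].key}
    edited_sites = list(sites[:n_recurrent]) + [sites[-1]]  # HLA decoy is recurrent too
    singleton_sites = sites[n_recurrent : n_recurrent + n_singleton]
    for site in edited_sites:
        k = int(rng.integers(2, max(3, len(sample_ids) // 3) + 1))
        chosen = list(rng.choice(sample_ids, size=min(k, len(sample_ids)), replace=False))
        edited_in[site.key] = sorted(chosen)
        planted_vaf[site.key] = float(rng.uniform(*vaf_range))
    for site in singleton_sites:
        edited_in[site.key] = [str(rng.choice(sample_ids))]
        planted_vaf[site.key] = float(rng.uniform(*vaf_range))
    dna: dict[str, dict] = {}
    rna: dict[str, dict] = {}
    for sid in sample_ids:
        dna[sid], rna[sid] = {}, {}
        for site in sites:
            cov = int(rng.integers(cov_range[0], cov_range[1] + 1))
            vaf = planted_vaf.get(site.key, 0.0) if sid in edited_in.get(site.key, []) else 0.0
            dna[sid][(site.chrom, site.pos)] = synthetic_pileup_column(
                rng, site.chrom, site.pos, site.ref_base, site.alt_base,
                depth=dna_depth, vaf=0.0, eps=eps, material="DNA", sample_id=sid,
            )
            rna[sid][(site.chrom, site.pos)] = synthetic_pileup_column(
                rng, site.chrom, site.pos, site.ref_base, site.alt_base,
                depth=cov, vaf=vaf, eps=eps, material="RNA", sample_id=sid,
            )
    recurrent_truth = {
        key for key, samples in edited_in.items()
        if len(samples) >= 2 and key not in hla_keys
    }
    return SitePanel(
        genome=genome,
        models=models,
        sites=sites,
        dna=dna,
        rna=rna,
        edited_in=edited_in,
        planted_vaf=planted_vaf,
        recurrent_truth=recurrent_truth,
        hla_site_keys=hla_keys,
    )


def simulate_validation_pileups(
    seed_seq: np.random.SeedSequence,
    panel: SitePanel,
    n_samples: int = 20,
    validated_fraction: float = 0.6,
    cov_range: tuple[int, int] = (30, 100),
    eps: float = 0.001,
) -> tuple[dict[str, dict[tuple[str, int], PileupColumn]], set]:
    """RNA-only pileups for an independent cohort; a fixed subset of the
    planted recurrent sites is re-edited there (the validated truth)."""
    rng = np.random.default_rng(seed_seq)
    rec_keys = sorted(panel.recurrent_truth)
    n_val = max(1, int(round(validated_fraction * len(rec_keys))))
    chosen = rng.permutation(len(rec_keys))[:n_val]
    validated_truth = {rec_keys[i] for i in chosen}
    cols: dict[str, dict] = {}
    for i in range(n_samples):
        sid = f"V{i:03d}"
        cols[sid] = {}
        for site in panel.sites:
            cov = int(rng.integers(cov_range[0], cov_range[1] + 1))
            edited_here = site.key in validated_truth and rng.random() < 0.3
            vaf = panel.planted_vaf.get(site.key, 0.2) if edited_here else 0.0
            cols[sid][(site.chrom, site.pos)] = synthetic_pileup_column(
                rng, site.chrom, site.pos, site.ref_base, site.alt_base,
                depth=cov, vaf=vaf, eps=eps, material="RNA", sample_id=sid,
            )
    return cols, validated_truth


# ---------------------------------------------------------------- cohort

@dataclass
class SyntheticTruth:
    """Planted parameters serialized next to every simulated cohort."""

    seed: int
    n_samples: int
    e_s: list[float]
    e_u: list[float]
    rho: list[float]
    editing_pct: list[float]
    retention_alpha: float
    retention_beta: float
    retention_sigma: float
    regulator_gene: str
    regulator_slope: float
    regulator_sigma: float
    hazard_low_editing: float
    hazard_high_editing: float
    survival_cutoff_pct: float
    cut_quantile: float
    censor_max: float
    eps: float
    depth_rna: int
    depth_dna: int
    recurrent_sites: list[list] = field(default_factory=list)
    validated_sites: list[list] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


@dataclass
class CohortSim:
    locus: Locus
    samples: list[SampleSim]
    panel: SitePanel
    validation: dict[str, dict[tuple[str, int], PileupColumn]]
    records: list[CohortRecord]
    expression: pd.DataFrame  # samples x genes
    truth: SyntheticTruth


def _survival_draw(
    rng: np.random.Generator,
    editing_pct: np.ndarray,
    tau: float,
    lam_low_editing: float,
    lam_high_editing: float,
    censor_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    lam = np.where(editing_pct > tau, lam_high_editing, lam_low_editing)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(0, censor_max, size=len(lam))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def simulate_cohort(
    n_samples: int = 40,
    seed: int = 0,
    p_unedited: float = 0.3,
    beta_a: float = 2.0,
    beta_b: float = 3.0,
    e_s_edited: float = 0.0,
    retention_alpha: float = 0.1,
    retention_beta: float = 0.6,
    retention_sigma: float = 0.03,
    depth_rna: int = 500,
    depth_dna: int = 50,
    eps: float = 0.001,
    n_genes: int = 500,
    regulator_slope: float = 2.0,
    regulator_sigma: float = 1.0,
    hazard_low_editing: float = 0.3,
    hazard_high_editing: float = 0.1,
    cut_quantile: float = 0.4,
    censor_max: float = 18.0,
    n_validation: int = 20,
    locus_strand: str = "+",
) -> CohortSim:
    """Generate a full synthetic cohort with serialized ground truth.

    Per-sample editing on retained templates is a mixture: unedited with
    probability ``p_unedited``, otherwise Beta(a, b). Retention follows
    rho = alpha + beta * e_u + N(0, sigma). The regulator gene's
    expression is a + slope * z(editing) + N(0, sigma_g); survival is
    exponential with the hazard dropping for samples above the editing
    quantile ``cut_quantile``.
    """
    root = np.random.SeedSequence(seed)
    # fixed stream layout: 0 cohort-level, 1 panel, 2 validation, 3 expression,
    # 4 survival, then one stream per sample (so adding samples never
    # perturbs the data of earlier ones)
    streams = root.spawn(5 + n_samples)

    locus = make_locus(seed=seed, strand=locus_strand)
    sample_ids = [f"P{i:03d}" for i in range(n_samples)]
    samples = []
    e_s_list, e_u_list, rho_list = [], [], []
    for i in range(n_samples):
        rng_i = np.random.default_rng(streams[5 + i])
        unedited = rng_i.random() < p_unedited
        e_u_i = 0.0 if unedited else float(rng_i.beta(beta_a, beta_b))
        e_s_i = 0.0 if unedited else e_s_edited
        rho_i = float(
            np.clip(
                retention_alpha + retention_beta * e_u_i + rng_i.normal(0, retention_sigma),
                0.0,
                1.0,
            )
        )
        samples.append(
            simulate_sample(
                rng_i,
                locus,
                e_s=e_s_i,
                e_u=e_u_i,
                rho=rho_i,
                depth_rna=depth_rna,
                depth_dna=depth_dna,
                eps=eps,
                sample_id=sample_ids[i],
            )
        )
        e_s_list.append(e_s_i)
        e_u_list.append(e_u_i)
        rho_list.append(rho_i)
    e_s = np.array(e_s_list)
    e_u = np.array(e_u_list)
    rho = np.array(rho_list)
    editing_pct = np.array([100.0 * s.expected_overall_editing for s in samples])

    panel = simulate_site_panel(streams[1], sample_ids, eps=eps)
    validation, validated_truth = simulate_validation_pileups(
        streams[2], panel, n_samples=n_validation, eps=eps
    )

    rng_expr = np.random.default_rng(streams[3])
    gene_names = [f"G{i:04d}" for i in range(n_genes)]
    regulator = gene_names[0]
    expr = rng_expr.normal(0, 1, size=(n_samples, n_genes))
    z = (editing_pct - editing_pct.mean()) / (editing_pct.std() or 1.0)
    expr[:, 0] = 5.0 + regulator_slope * z + rng_expr.normal(0, regulator_sigma, n_samples)
    expression = pd.DataFrame(expr, index=sample_ids, columns=gene_names)

    rng_surv = np.random.default_rng(streams[4])
    tau = float(np.quantile(editing_pct, cut_quantile, method="inverted_cdf"))
    time_tt, event_tt = _survival_draw(
        rng_surv, editing_pct, tau, hazard_low_editing, hazard_high_editing, censor_max
    )
    time_os, event_os = _survival_draw(
        rng_surv, editing_pct, tau, hazard_low_editing, hazard_high_editing, censor_max
    )
    records = [
        CohortRecord(
            sample_id=sample_ids[i],
            editing_pct=float(editing_pct[i]),
            time_tt=float(time_tt[i]),
            event_tt=int(event_tt[i]),
            time_os=float(time_os[i]),
            event_os=int(event_os[i]),
        )
        for i in range(n_samples)
    ]
    truth = SyntheticTruth(
        seed=seed,
        n_samples=n_samples,
        e_s=[float(x) for x in e_s],
        e_u=[float(x) for x in e_u],
        rho=[float(x) for x in rho],
        editing_pct=[float(x) for x in editing_pct],
        retention_alpha=retention_alpha,
        retention_beta=retention_beta,
        retention_sigma=retention_sigma,
        regulator_gene=regulator,
        regulator_slope=regulator_slope,
        regulator_sigma=regulator_sigma,
        hazard_low_editing=hazard_low_editing,
        hazard_high_editing=hazard_high_editing,
        survival_cutoff_pct=tau,
        cut_quantile=cut_quantile,
        censor_max=censor_max,
        eps=eps,
        depth_rna=depth_rna,
        depth_dna=depth_dna,
        recurrent_sites=sorted([list(k) for k in panel.recurrent_truth]),
        validated_sites=sorted([list(k) for k in validated_truth]),
    )
    return CohortSim(
        locus=locus,
        samples=samples,
        panel=panel,
        validation=validation,
        records=records,
        expression=expression,
        truth=truth,
    )


def draw_editing_pct(rng: np.random.Generator, n: int, p_unedited: float = 0.3,
                     beta_a: float = 2.0, beta_b: float = 3.0,
                     retention_alpha: float = 0.1, retention_beta: float = 0.6,
                     retention_sigma: float = 0.03) -> np.ndarray:
    """Per-sample overall editing percentage under the cohort model
    (unedited point mass + Beta on retained templates, retention-coupled)."""
    unedited = rng.random(n) < p_unedited
    e_u = np.where(unedited, 0.0, rng.beta(beta_a, beta_b, size=n))
    rho = np.clip(
        retention_alpha + retention_beta * e_u + rng.normal(0, retention_sigma, n), 0.0, 1.0
    )
    return 100.0 * rho * e_u


def simulate_screen_cohorts(
    seed_seq: np.random.SeedSequence | int,
    n_cohorts: int = 3,
    n_samples: int = 40,
    n_genes: int = 500,
    regulator_slope: float = 2.0,
    regulator_sigma: float = 1.0,
) -> tuple[list[tuple[np.ndarray, pd.DataFrame]], str]:
    """Editing + expression matrices for several cohorts sharing one
    regulator gene (standardized slope b against unit noise); returns
    (cohorts, regulator gene name) ready for the Pearson screen."""
    if isinstance(seed_seq, int):
        seed_seq = np.random.SeedSequence(seed_seq)
    gene_names = [f"G{i:04d}" for i in range(n_genes)]
    regulator = gene_names[0]
    cohorts = []
    for ss in seed_seq.spawn(n_cohorts):
        rng = np.random.default_rng(ss)
        ed = draw_editing_pct(rng, n_samples)
        expr = rng.normal(0, 1, size=(n_samples, n_genes))
        z = (ed - ed.mean()) / (ed.std() or 1.0)
        expr[:, 0] = 5.0 + regulator_slope * z + rng.normal(0, regulator_sigma, n_samples)
        cohorts.append((ed, pd.DataFrame(expr, columns=gene_names)))
    return cohorts, regulator


# ----------------------------------------------------------------- output

def write_cohort(sim: CohortSim, out_dir: str | Path) -> None:
    """Serialize a cohort to plain-text files (FASTA, SAM, pileups, TSVs,
    truth JSON)."""
    from editscan.intervals import write_transcript_table
    from editscan.pileup import write_pileup
    from editscan.samio import write_sam
    from editscan.sanger import write_amplitude_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.locus.genome.to_fasta(out / "locus.fasta")
    write_transcript_table([sim.locus.model] + sim.panel.models, out / "transcripts.tsv")
    ref_lens = {**sim.locus.genome.chroms(), **sim.panel.genome.chroms()}
    for s in sim.samples:
        write_sam(s.rna_reads, out / f"{s.sample_id}.rna.sam", ref_lens)
        write_pileup([s.dna_column], out / f"{s.sample_id}.dna.pileup")
        write_amplitude_tsv(s.sanger, out / f"{s.sample_id}.amps.tsv")
    for sid, cols in sim.panel.dna.items():
        write_pileup(cols.values(), out / f"{sid}.panel.dna.pileup")
    for sid, cols in sim.panel.rna.items():
        write_pileup(cols.values(), out / f"{sid}.panel.rna.pileup")
    for sid, cols in sim.validation.items():
        write_pileup(cols.values(), out / f"{sid}.validation.rna.pileup")
    cohort = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "editing_pct": r.editing_pct,
                "time_tt": r.time_tt,
                "event_tt": r.event_tt,
                "time_os": r.time_os,
                "event_os": r.event_os,
            }
            for r in sim.records
        ]
    )
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    sim.expression.to_csv(out / "expression.tsv", sep="\t")
    sim.truth.to_json(out / "truth.json")
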