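"""Matched DNA/RNA editing-site discovery.

The chain mirrors a somatic-style caller specialised for RNA editing:

1. site gate — mean base quality and coverage in *both* materials;
2. read-level filters — alt support at the first/last base of a read,
   single-strand (strand-biased) support, and support confined to
   inserted/deleted alignment segments is discounted;
3. RNA-unique calling — RNA coverage and variant-fraction thresholds, a
   ceiling on the DNA alt fraction (editing must be absent from the
   genome), and a two-sided Fisher exact test on the DNA-vs-RNA allele
   counts;
4. cohort filters — HLA-gene exclusion, recurrence across samples, and
   re-detection in an independent validation cohort.

Each filter is an independent predicate on the fixed observations, so
the PASS set does not depend on the order the filters run in. Thresholds
are strict in the "reject below" direction: a site at exactly the mean
quality or coverage threshold passes.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import fisher_exact

from editscan.config import PipelineConfig
from editscan.model import (
    EditingSiteCall,
    GenomicSite,
    PileupColumn,
    ReadObservation,
    RecurrentSite,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- site gate

def gate_site(dna: PileupColumn, rna: PileupColumn, cfg: PipelineConfig) -> tuple[bool, str]:
    """Site-level quality/coverage gate; returns (passed, reason)."""
    if (dna.chrom, dna.pos) != (rna.chrom, rna.pos):
        raise ValueError("DNA and RNA columns refer to different sites")
    if dna.coverage == 0 or rna.coverage == 0:
        return False, "no coverage"
    if dna.coverage < cfg.min_site_cov or rna.coverage < cfg.min_site_cov:
        return False, "site_coverage"
    if (
        dna.mean_base_quality() < cfg.min_mean_baseq
        or rna.mean_base_quality() < cfg.min_mean_baseq
    ):
        return False, "site_quality"
    return True, ""


# ------------------------------------------------------- read-level filters

def _alt_obs(col: PileupColumn, alt: str) -> list[ReadObservation]:
    return [o for o in col.observations if o.base == alt]


def filter_read_position(
    col: PileupColumn, alt: str, drop_on_any: bool = False
) -> tuple[list[ReadObservation], bool]:
    """Discount alt support at the first or last base of its read.

    Returns (surviving support, variant_dropped). With ``drop_on_any`` the
    stricter reading is applied: one end-of-read supporting observation
    kills the variant outright.
    """
    support = _alt_obs(col, alt)
    if not support:
        return [], False
    at_edge = [o for o in support if o.at_read_edge]
    if drop_on_any and at_edge:
        return [], True
    remaining = [o for o in support if not o.at_read_edge]
    return remaining, not remaining


def filter_strand_bias(col: PileupColumn, alt: str) -> bool:
    """True (fail) iff all alt support sits on a single strand."""
    strands = {o.read_strand for o in _alt_obs(col, alt)}
    return len(strands) < 2


def filter_indel_region(col: PileupColumn, alt: str) -> tuple[list[ReadObservation], bool]:
    """Exclude alt support lying in inserted/deleted alignment segments.

    Returns (clean support, failed) where failed means no clean support
    remains.
    """
    support = _alt_obs(col, alt)
    clean = [o for o in support if not o.in_indel]
    return clean, not clean


# --------------------------------------------------------------- calling

def fisher_p_dna_rna(dna_ref: int, dna_alt: int, rna_ref: int, rna_alt: int) -> float:
    """Two-sided Fisher exact p for the DNA-vs-RNA 2x2 allele table."""
    _, p = fisher_exact([[dna_ref, dna_alt], [rna_ref, rna_alt]], alternative="two-sided")
    return float(p)


def dominant_alt(rna: PileupColumn) -> Optional[str]:
    """Most frequent non-reference base call in the RNA column."""
    counts = Counter(
        o.base for o in rna.observations if o.is_base and o.base != rna.ref_base and o.base != "N"
    )
    if not counts:
        return None
    # ties broken alphabetically for determinism
    top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return top[0]


def evaluate_site(
    dna: PileupColumn,
    rna: PileupColumn,
    alt: Optional[str],
    cfg: PipelineConfig,
) -> Optional[EditingSiteCall]:
    """Run the full per-site filter chain; returns a call with the set of
    failed filters (empty set = PASS), or None when RNA shows no alt base.
    """
    if alt is None:
        alt = dominant_alt(rna)
        if alt is None:
            return None
    filters: set[str] = set()

    ok, reason = gate_site(dna, rna, cfg)
    if not ok:
        filters.add("no_coverage" if reason == "no coverage" else reason)

    support = _alt_obs(rna, alt)
    if not support:
        return None

    _, end_fail = filter_read_position(rna, alt, cfg.drop_variant_on_any_end_read)
    if end_fail:
        filters.add("read_end_support")
    if filter_strand_bias(rna, alt):
        filters.add("strand_bias")
    _, indel_fail = filter_indel_region(rna, alt)
    if indel_fail:
        filters.add("indel_context")

    # effective support excludes both end-of-read and indel-context evidence
    clean = [o for o in support if not o.at_read_edge and not o.in_indel]

    dna_ref = dna.base_count(dna.ref_base)
    dna_alt_n = dna.base_count(alt)
    rna_ref = rna.base_count(rna.ref_base)
    rna_alt_n = len(clean)
    rna_cov = sum(1 for o in rna.observations if o.is_base)
    dna_cov = sum(1 for o in dna.observations if o.is_base)

    call = EditingSiteCall(
        site=GenomicSite(rna.chrom, rna.pos, rna.ref_base, alt),
        sample_id=rna.sample_id,
        dna_cov=dna_cov,
        dna_alt=dna_alt_n,
        rna_cov=rna_cov,
        rna_alt=rna_alt_n,
    )
    if rna_cov < cfg.min_rna_cov_call:
        filters.add("low_rna_cov")
    if call.rna_vaf < cfg.min_var_freq:
        filters.add("low_rna_vaf")
    if rna_alt_n < cfg.min_alt_reads_call:
        filters.add("low_alt_support")
    if call.dna_vaf > cfg.max_dna_vaf:
        filters.add("dna_shared")
    call.fisher_p = fisher_p_dna_rna(dna_ref, dna_alt_n, rna_ref, rna_alt_n)
    if call.fisher_p > cfg.fisher_alpha:
        filters.add("not_significant")
    call.filters = filters
    return call


def call_rna_unique(
    dna: PileupColumn, rna: PileupColumn, cfg: PipelineConfig, alt: Optional[str] = None
) -> Optional[EditingSiteCall]:
    """RNA-unique variant call at one gated site; None unless PASS."""
    call = evaluate_site(dna, rna, alt, cfg)
    if call is None or not call.is_pass:
        return None
    return call


def call_sample(
    dna_columns: Mapping[tuple[str, int], PileupColumn],
    rna_columns: Mapping[tuple[str, int], PileupColumn],
    cfg: PipelineConfig,
) -> list[EditingSiteCall]:
    """Evaluate every site present in both materials for one sample."""
    calls = []
    shared = sorted(set(dna_columns) & set(rna_columns))
    for key in shared:
        call = evaluate_site(dna_columns[key], rna_columns[key], None, cfg)
        if call is not None:
            calls.append(call)
    n_pass = sum(c.is_pass for c in calls)
    log.info(
        "call_sample: %d shared sites -> %d candidate calls, %d PASS",
        len(shared), len(calls), n_pass,
    )
    return calls


# ------------------------------------------------------------ cohort stage

def exclude_hla(calls: Iterable[EditingSiteCall], cfg: PipelineConfig) -> list[EditingSiteCall]:
    """Drop calls annotated to HLA genes (prefix match on the symbol)."""
    kept = []
    for call in calls:
        gene = call.annotation.gene if call.annotation else ""
        if any(gene.startswith(p) for p in cfg.hla_gene_prefixes):
            call.filters.add("hla_gene")
            continue
        kept.append(call)
    return kept


def recurrence_filter(
    calls_by_sample: Mapping[str, Sequence[EditingSiteCall]],
    cfg: PipelineConfig,
    require_nonsynonymous: bool = False,
) -> list[RecurrentSite]:
    """Keep sites PASS-called in at least ``recurrence_min_samples`` samples."""
    per_site: dict[tuple, list[EditingSiteCall]] = defaultdict(list)
    for sample, calls in calls_by_sample.items():
        for call in calls:
            if not call.is_pass:
                continue
            if require_nonsynonymous and (
                call.annotation is None or call.annotation.effect != "nonsynonymous"
            ):
                continue
            per_site[call.site.key].append(call)
    out = []
    for key in sorted(per_site):
        calls = per_site[key]
        samples = {c.sample_id for c in calls}
        if len(samples) >= cfg.recurrence_min_samples:
            out.append(
                RecurrentSite(
                    site=calls[0].site,
                    n_samples_detected=len(samples),
                    sample_vafs={c.sample_id: c.rna_vaf for c in calls},
                    annotation=calls[0].annotation,
                )
            )
    log.info(
        "recurrence_filter: %d distinct PASS sites -> %d recurrent (>=%d samples)",
        len(per_site), len(out), cfg.recurrence_min_samples,
    )
    return out


def validate_in_cohort(
    sites: Sequence[RecurrentSite],
    validation_pileups: Mapping[str, Mapping[tuple[str, int], PileupColumn]],
    cfg: PipelineConfig,
) -> list[RecurrentSite]:
    """Flag each recurrent site as validated when at least one validation
    sample re-detects the alt allele at the calling thresholds."""
    for rec in sites:
        key = (rec.site.chrom, rec.site.pos)
        covered = False
        validated = False
        for cols in validation_pileups.values():
            col = cols.get(key)
            if col is None or col.coverage == 0:
                continue
            covered = True
            if col.coverage >= cfg.min_site_cov and col.vaf(rec.site.alt_base) >= cfg.min_var_freq:
                validated = True
                break
        rec.validated = validated
        rec.validation_flag = "" if covered else "uncovered"
    n_val = sum(bool(s.validated) for s in sites)
    log.info("validate_in_cohort: %d recurrent sites -> %d validated", len(sites), n_val)
    return list(sites)
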