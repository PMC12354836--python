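"""Splice-state-resolved editing and intron retention at one junction.

Reads overlapping the first bases of the downstream exon are split into
a spliced class (CIGAR reference-skip ending exactly at the 3' end of
the intron) and an unspliced class (contiguous alignment across the
intron/exon border). Editing is then re-genotyped separately per class,
and intron retention is estimated both from the read-class counts and
from interval depth-of-coverage.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from editscan.config import PipelineConfig
from editscan.model import AlignedRead, Interval, JunctionSpec, SpliceEditingResult
from editscan.pileup import pileup_from_reads

log = logging.getLogger(__name__)


def _aligned_blocks(read: AlignedRead) -> tuple[list[Interval], list[Interval]]:
    """(aligned reference blocks, N-gap blocks); D merges into blocks."""
    blocks: list[list[int]] = []
    gaps: list[Interval] = []
    rpos = read.pos
    for n, op in read.cigar_ops():
        if op in "MD=X":
            if blocks and blocks[-1][1] == rpos - 1:
                blocks[-1][1] = rpos + n - 1
            else:
                blocks.append([rpos, rpos + n - 1])
            rpos += n
        elif op == "N":
            gaps.append(Interval(rpos, rpos + n - 1))
            rpos += n
    return [Interval(a, b) for a, b in blocks], gaps


def classify_reads(
    reads: Sequence[AlignedRead],
    j: JunctionSpec,
    any_n: bool = False,
) -> tuple[list[AlignedRead], list[AlignedRead], list[AlignedRead]]:
    """Split boundary-overlapping reads into (spliced, unspliced, unclassified).

    With ``any_n`` the split keys on the mere presence of a reference skip
    in the CIGAR (the coarse historical rule); by default a skip must end
    exactly at the intron's 3' end to count as spliced at *this* junction.
    """
    spliced: list[AlignedRead] = []
    unspliced: list[AlignedRead] = []
    unclassified: list[AlignedRead] = []
    n_outside = 0
    boundary = j.boundary
    for read in reads:
        span = read.reference_span()
        if read.chrom != j.chrom or span.end < boundary.start or span.start > boundary.end:
            n_outside += 1
            continue
        if any_n:
            (spliced if "N" in read.cigar else unspliced).append(read)
            continue
        if read.pos >= j.downstream_exon.start:
            unclassified.append(read)
            continue
        blocks, gaps = _aligned_blocks(read)
        if any(g.end == j.intron.end for g in gaps):
            spliced.append(read)
        elif any(j.intron.end in b and j.downstream_exon.start in b for b in blocks):
            unspliced.append(read)
        else:
            unclassified.append(read)
    if n_outside:
        log.debug("classify_reads: %d reads did not overlap the boundary", n_outside)
    return spliced, unspliced, unclassified


def _class_vaf(
    reads: Sequence[AlignedRead], j: JunctionSpec, cfg: PipelineConfig
) -> Optional[float]:
    if not reads:
        return None
    (col,) = pileup_from_reads(
        reads, j.chrom, [j.edit_site.pos], [j.edit_site.ref_base],
        exclude_duplicates=cfg.exclude_duplicates,
    )
    ref = col.base_count(j.edit_site.ref_base)
    alt = col.base_count(j.edit_site.alt_base)
    if ref + alt == 0:
        return None
    vaf = alt / (ref + alt)
    if alt < cfg.min_reads2_splice or vaf < cfg.min_var_freq_splice:
        return 0.0
    return vaf


def vaf_by_class(
    spliced: Sequence[AlignedRead],
    unspliced: Sequence[AlignedRead],
    j: JunctionSpec,
    cfg: PipelineConfig,
) -> tuple[Optional[float], Optional[float]]:
    """Editing fraction at the target site per splice class (None when the
    class has no coverage at the site)."""
    return _class_vaf(spliced, j, cfg), _class_vaf(unspliced, j, cfg)


def retention_fraction(n_spliced: int, n_unspliced: int) -> Optional[float]:
    """Read-based intron retention: unspliced / (spliced + unspliced)."""
    total = n_spliced + n_unspliced
    return n_unspliced / total if total else None


def interval_mean_depth(reads: Sequence[AlignedRead], chrom: str, iv: Interval) -> float:
    total = 0
    for read in reads:
        if read.chrom != chrom:
            continue
        blocks, _ = _aligned_blocks(read)
        for b in blocks:
            lo, hi = max(b.start, iv.start), min(b.end, iv.end)
            if hi >= lo:
                total += hi - lo + 1
    return total / len(iv)


def coverage_retention(
    reads: Sequence[AlignedRead], j: JunctionSpec
) -> tuple[Optional[float], dict[str, float]]:
    """Depth-based retention: mean intron depth over mean flanking-exon
    depth, clipped to [0, 1]; also returns the per-interval mean depths."""
    depths = {
        "upstream_exon": interval_mean_depth(reads, j.chrom, j.upstream_exon),
        "intron": interval_mean_depth(reads, j.chrom, j.intron),
        "downstream_exon": interval_mean_depth(reads, j.chrom, j.downstream_exon),
    }
    exon_mean = (depths["upstream_exon"] + depths["downstream_exon"]) / 2
    if exon_mean == 0:
        return None, depths
    return float(np.clip(depths["intron"] / exon_mean, 0.0, 1.0)), depths


def quantify_sample(
    reads: Sequence[AlignedRead],
    j: JunctionSpec,
    cfg: PipelineConfig,
    sample_id: str = "",
    any_n: bool = False,
) -> SpliceEditingResult:
    """Full splice/editing quantification for one sample's reads."""
    if cfg.exclude_duplicates:
        n0 = len(reads)
        reads = [r for r in reads if not r.is_duplicate]
        if n0 and n0 != len(reads):
            log.info("quantify_sample[%s]: duplicate fraction %.3f", sample_id, 1 - len(reads) / n0)
    spliced, unspliced, _ = classify_reads(reads, j, any_n=any_n)
    vaf_s, vaf_u = vaf_by_class(spliced, unspliced, j, cfg)
    ret_cov, depths = coverage_retention(reads, j)
    return SpliceEditingResult(
        sample_id=sample_id,
        n_spliced=len(spliced),
        n_unspliced=len(unspliced),
        vaf_spliced=vaf_s,
        vaf_unspliced=vaf_u,
        retention_read=retention_fraction(len(spliced), len(unspliced)),
        retention_cov=ret_cov,
        coverage_by_interval=depths,
    )


def editing_retention_correlation(
    editing: Sequence[float], retention: Sequence[float]
) -> tuple[Optional[float], Optional[float]]:
    """Pearson r (and two-sided t-based p) between per-sample editing depth
    and intron retention; None when either vector is constant or n < 3."""
    x = np.asarray(editing, dtype=float)
    y = np.asarray(retention, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
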