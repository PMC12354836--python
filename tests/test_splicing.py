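"""Read classification at the intron/exon boundary, per-class editing,
retention estimators and the editing-retention correlation."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from editscan.config import PipelineConfig
from editscan.model import AlignedRead
from editscan.simulate import (
    make_locus,
    simulate_coverage_reads,
    simulate_junction_reads,
)
from editscan.splicing import (
    classify_reads,
    coverage_retention,
    editing_retention_correlation,
    quantify_sample,
    retention_fraction,
    vaf_by_class,
)


def _read(chrom, pos, cigar, length=None):
    if length is None:
        length = sum(
            int(n) for n, op in __import__("re").findall(r"(\d+)([MIS=X])", cigar)
        )
    return AlignedRead("q", chrom, pos, cigar, "A" * length, [30] * length)


class TestClassification:
    def test_contiguous_read_across_border_is_unspliced(self, locus):
        j = locus.junction
        r = _read(j.chrom, j.downstream_exon.start - 10, "20M")
        spliced, unspliced, other = classify_reads([r], j)
        assert (len(spliced), len(unspliced), len(other)) == (0, 1, 0)

    def test_junction_gap_read_is_spliced(self, locus):
        j = locus.junction
        a, b = 10, 10
        r = _read(j.chrom, j.upstream_exon.end - a + 1, f"{a}M{len(j.intron)}N{b}M")
        spliced, unspliced, other = classify_reads([r], j)
        assert (len(spliced), len(unspliced), len(other)) == (1, 0, 0)

    def test_read_inside_downstream_exon_is_unclassified(self, locus):
        j = locus.junction
        r = _read(j.chrom, j.downstream_exon.start, "20M")
        spliced, unspliced, other = classify_reads([r], j)
        assert (len(spliced), len(unspliced), len(other)) == (0, 0, 1)

    def test_gap_at_foreign_junction_only_counts_with_any_n_rule(self, locus):
        """A reference skip that does not end at this intron's 3' end is
        not evidence of splicing at this junction under the anchored rule,
        but the coarse any-N rule accepts it."""
        j = locus.junction
        # 5M in the intron, a 10-base gap ending before the intron's 3' end,
        # then a match spanning the last 5 intron bases and 10 exon bases
        r = AlignedRead(
            "q", j.chrom, j.intron.end - 19, "5M10N15M", "A" * 20, [30] * 20
        )
        spliced, unspliced, other = classify_reads([r], j)
        assert len(spliced) == 0 and len(unspliced) == 1
        spliced, unspliced, other = classify_reads([r], j, any_n=True)
        assert len(spliced) == 1

    def test_conservation_of_boundary_reads(self, locus, rng):
        reads = simulate_coverage_reads(rng, locus, 4000, 0.0, 0.4, 0.3)
        j = locus.junction
        b = j.boundary
        overlapping = [
            r for r in reads
            if r.reference_span().start <= b.end and r.reference_span().end >= b.start
        ]
        spliced, unspliced, other = classify_reads(reads, j)
        assert len(spliced) + len(unspliced) + len(other) == len(overlapping)

    def test_class_purity_on_simulated_reads(self, locus, rng):
        """Reads generated from the retained template must never be called
        spliced, and vice versa (simulation has no soft clips)."""
        reads, _ = simulate_junction_reads(rng, locus, 2000, 0.0, 0.4, 0.5)
        spliced, unspliced, _ = classify_reads(reads, locus.junction)
        assert all("N" in r.cigar for r in spliced)
        assert all("N" not in r.cigar for r in unspliced)


class TestVafByClass:
    def test_fraction_arithmetic(self, locus, cfg):
        j = locus.junction
        rng = np.random.default_rng(0)
        reads, _ = simulate_junction_reads(rng, locus, 120, 0.0, 0.25, 0.5, eps=0.0)
        spliced, unspliced, _ = classify_reads(reads, j)
        vaf_s, vaf_u = vaf_by_class(spliced, unspliced, j, cfg)
        # exact: count alt among unspliced reads at the site
        from editscan.pileup import pileup_from_reads

        (col,) = pileup_from_reads(unspliced, j.chrom, [j.edit_site.pos], [j.edit_site.ref_base])
        assert vaf_u == pytest.approx(col.base_count("T") / col.coverage)
        assert vaf_s == 0.0

    def test_empty_class_reports_missing(self, locus, cfg):
        vaf_s, vaf_u = vaf_by_class([], [], locus.junction, cfg)
        assert vaf_s is None and vaf_u is None

    def test_planted_rates_recovered_within_two_se(self, locus, cfg):
        rng = np.random.default_rng(77)
        e_u = 0.4
        reads, _ = simulate_junction_reads(rng, locus, 2000, 0.0, e_u, 0.35)
        res = quantify_sample(reads, locus.junction, cfg)
        se = np.sqrt(e_u * (1 - e_u) / res.n_unspliced)
        assert res.vaf_spliced < 0.02
        assert abs(res.vaf_unspliced - e_u) <= 2 * se + 0.01


class TestRetention:
    def test_read_fraction_arithmetic(self):
        assert retention_fraction(90, 10) == pytest.approx(0.10)
        assert retention_fraction(50, 0) == 0.0
        assert retention_fraction(0, 0) is None

    def test_estimators_agree_with_planted_fraction(self, locus):
        rng = np.random.default_rng(21)
        reads = simulate_coverage_reads(rng, locus, 30000, 0.0, 0.4, 0.3)
        res = quantify_sample(reads, locus.junction, PipelineConfig())
        assert abs(res.retention_read - 0.3) < 0.05
        assert abs(res.retention_cov - 0.3) < 0.05
        assert abs(res.retention_read - res.retention_cov) < 0.05

    def test_all_spliced_gives_zero_retention(self, locus):
        rng = np.random.default_rng(3)
        reads = simulate_coverage_reads(rng, locus, 3000, 0.0, 0.0, 0.0)
        res = quantify_sample(reads, locus.junction, PipelineConfig())
        assert res.retention_read == 0.0
        _, depths = coverage_retention(reads, locus.junction)
        assert depths["intron"] < 0.2


class TestCorrelation:
    def test_noiseless_linear_coupling_gives_r_one(self):
        x = [0.1, 0.2, 0.3, 0.4]
        y = [0.15, 0.25, 0.35, 0.45]
        r, p = editing_retention_correlation(x, y)
        assert r == pytest.approx(1.0)

    def test_constant_vector_reports_missing(self):
        r, p = editing_retention_correlation([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])
        assert r is None and p is None

    def test_planted_r_recovered_on_average(self):
        """Bivariate draws with population r = 0.8 at n = 50: the mean
        estimate over seeds stays within 0.05 of truth."""
        target = 0.8
        cov = [[1, target], [target, 1]]
        estimates = []
        for ss in np.random.SeedSequence(404).spawn(100):
            g = np.random.default_rng(ss)
            xy = g.multivariate_normal([0, 0], cov, size=50)
            r, _ = editing_retention_correlation(xy[:, 0], xy[:, 1])
            estimates.append(r)
        assert abs(np.mean(estimates) - target) < 0.05

    def test_independent_vectors_give_uniform_p(self):
        ps = []
        for ss in np.random.SeedSequence(11).spawn(300):
            g = np.random.default_rng(ss)
            r, p = editing_retention_correlation(g.normal(size=50), g.normal(size=50))
            ps.append(p)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 <= frac <= 0.09
        assert stats.kstest(ps, "uniform").pvalue > 0.01
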