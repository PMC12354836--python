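"""Editing-caller behavior: site gates, read-level filters, RNA-unique
calling against an exact-enumeration Fisher oracle, HLA exclusion,
recurrence and validation, and planted-cohort recovery."""
from __future__ import annotations

import math

import numpy as np
import pytest

from editscan.calling import (
    call_rna_unique,
    evaluate_site,
    exclude_hla,
    filter_indel_region,
    filter_read_position,
    filter_strand_bias,
    fisher_p_dna_rna,
    gate_site,
    recurrence_filter,
    validate_in_cohort,
)
from editscan.config import PipelineConfig
from editscan.model import CodingAnnotation, EditingSiteCall, GenomicSite, RecurrentSite
from editscan.simulate import simulate_site_panel, synthetic_pileup_column

from conftest import make_column


def brute_force_fisher(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration:
    sum of the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's."""
    r1, r2, k = a + b, c + d, b + d
    n = r1 + r2

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, k - x) / math.comb(n, k)
        )

    p_obs = prob(b)
    total = 0.0
    for x in range(max(0, k - r2), min(k, r1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestGateSite:
    def test_low_dna_coverage_fails(self, cfg):
        dna = make_column(n_ref=5, material="DNA")
        rna = make_column(n_ref=30)
        ok, reason = gate_site(dna, rna, cfg)
        assert not ok and reason == "site_coverage"

    def test_boundary_equality_passes(self, cfg):
        dna = make_column(n_ref=6, baseq=20, material="DNA")
        rna = make_column(n_ref=6, baseq=20)
        assert gate_site(dna, rna, cfg)[0]

    def test_mean_quality_just_below_threshold_fails(self, cfg):
        dna = make_column(n_ref=30, material="DNA")
        rna = make_column(n_ref=10, baseq=19)
        ok, reason = gate_site(dna, rna, cfg)
        assert not ok and reason == "site_quality"

    def test_empty_column_fails_with_no_coverage(self, cfg):
        dna = make_column(n_ref=0, material="DNA")
        rna = make_column(n_ref=10)
        assert gate_site(dna, rna, cfg) == (False, "no coverage")


class TestReadLevelFilters:
    def test_all_support_at_read_ends_drops_variant(self):
        col = make_column(n_ref=20, n_alt=3, alt_edge=True)
        remaining, dropped = filter_read_position(col, "T")
        assert dropped and remaining == []

    def test_internal_support_survives_edge_removal(self):
        col = make_column(n_ref=20)
        from editscan.model import ReadObservation

        col.observations += [
            ReadObservation("T", 37, "+", pos_in_read=1, read_length=100),
            ReadObservation("T", 37, "-", pos_in_read=100, read_length=100),
            ReadObservation("T", 37, "+", pos_in_read=50, read_length=100),
        ]
        remaining, dropped = filter_read_position(col, "T")
        assert not dropped and len(remaining) == 1

    def test_no_alt_support_is_not_a_variant(self):
        col = make_column(n_ref=20, n_alt=0)
        remaining, dropped = filter_read_position(col, "T")
        assert remaining == [] and not dropped

    def test_strict_mode_drops_on_any_edge_support(self):
        col = make_column(n_ref=20, n_alt=4, alt_edge=True)
        _, dropped = filter_read_position(col, "T", drop_on_any=True)
        assert dropped

    @pytest.mark.parametrize(
        "strands,expect_fail",
        [(("+",), True), (("+", "-"), False), ((), True)],
    )
    def test_strand_bias_requires_both_strands(self, strands, expect_fail):
        col = make_column(n_ref=10, n_alt=4 if strands else 0, alt_strands=strands or ("+",))
        assert filter_strand_bias(col, "T") is expect_fail

    def test_indel_only_support_fails(self):
        col = make_column(n_ref=10, n_alt=3, alt_indel=True)
        clean, failed = filter_indel_region(col, "T")
        assert failed and clean == []

    def test_mixed_indel_support_counts_clean_observations(self):
        col = make_column(n_ref=10, n_alt=2, alt_indel=True)
        from editscan.model import ReadObservation

        col.observations += [
            ReadObservation("T", 37, "+", pos_in_read=30, read_length=100),
            ReadObservation("T", 37, "-", pos_in_read=40, read_length=100),
        ]
        clean, failed = filter_indel_region(col, "T")
        assert not failed and len(clean) == 2


class TestRnaUniqueCalling:
    def test_clear_editing_site_called(self, cfg):
        dna = make_column(n_ref=20, material="DNA")
        rna = make_column(n_ref=10, n_alt=10)
        call = call_rna_unique(dna, rna, cfg)
        assert call is not None and call.is_pass
        assert call.fisher_p == pytest.approx(brute_force_fisher(20, 0, 10, 10), rel=1e-6)

    def test_vaf_below_threshold_not_called(self, cfg):
        dna = make_column(n_ref=50, material="DNA")
        rna = make_column(n_ref=96, n_alt=4)  # VAF 0.04
        assert call_rna_unique(dna, rna, cfg) is None

    def test_dna_shared_variant_not_called(self, cfg):
        dna = make_column(n_ref=10, n_alt=10, material="DNA")
        rna = make_column(n_ref=10, n_alt=10)
        call = evaluate_site(dna, rna, "T", cfg)
        assert "dna_shared" in call.filters and call_rna_unique(dna, rna, cfg) is None

    def test_filter_set_is_order_independent(self, cfg, rng):
        """Each filter is an independent predicate, so the failed-filter
        set must equal the union of individually evaluated predicates."""
        for _ in range(50):
            n_alt = int(rng.integers(0, 8))
            col = make_column(
                n_ref=int(rng.integers(0, 30)),
                n_alt=n_alt,
                alt_strands=("+",) if rng.random() < 0.4 else ("+", "-"),
                alt_edge=bool(rng.random() < 0.3),
                alt_indel=bool(rng.random() < 0.3),
                baseq=int(rng.integers(15, 41)),
            )
            dna = make_column(n_ref=int(rng.integers(0, 30)), material="DNA")
            call = evaluate_site(dna, col, "T", cfg)
            if call is None:
                assert col.base_count("T") == 0
                continue
            expected = set()
            ok, reason = gate_site(dna, col, cfg)
            if not ok:
                expected.add("no_coverage" if reason == "no coverage" else reason)
            if filter_read_position(col, "T")[1]:
                expected.add("read_end_support")
            if filter_strand_bias(col, "T"):
                expected.add("strand_bias")
            if filter_indel_region(col, "T")[1]:
                expected.add("indel_context")
            assert expected == call.filters & (
                {"no_coverage", "site_coverage", "site_quality",
                 "read_end_support", "strand_bias", "indel_context"}
            )


class TestCohortFilters:
    def _annotated_call(self, gene, sample="S1", pos=100, effect="nonsynonymous"):
        call = EditingSiteCall(
            site=GenomicSite("chr1", pos, "C", "T"), sample_id=sample,
            dna_cov=50, dna_alt=0, rna_cov=40, rna_alt=10, fisher_p=1e-4,
        )
        call.annotation = CodingAnnotation(
            gene=gene, transcript_strand="+", codon_before="TCG", codon_after="TTG",
            aa_before="S", aa_after="L", aa_position=1, effect=effect,
            edit_class_on_transcript="C>U",
        )
        return call

    def test_hla_prefixed_genes_removed(self, cfg):
        calls = [self._annotated_call("HLA-DRB1"), self._annotated_call("MFN1")]
        kept = exclude_hla(calls, cfg)
        assert [c.annotation.gene for c in kept] == ["MFN1"]
        assert exclude_hla([], cfg) == []

    def test_recurrence_requires_two_samples(self, cfg):
        by_sample = {
            "S1": [self._annotated_call("A", "S1", 100), self._annotated_call("B", "S1", 200)],
            "S2": [self._annotated_call("A", "S2", 100)],
        }
        sites = recurrence_filter(by_sample, cfg)
        assert [s.site.pos for s in sites] == [100]
        assert sites[0].n_samples_detected == 2

    def test_validation_threshold_rule(self, cfg):
        site = RecurrentSite(
            site=GenomicSite("chr1", 100, "C", "T"), n_samples_detected=2, sample_vafs={}
        )
        rng = np.random.default_rng(0)
        good = synthetic_pileup_column(rng, "chr1", 100, "C", "T", depth=30, vaf=0.08, eps=0.0)
        (validated,) = validate_in_cohort([site], {"V1": {("chr1", 100): good}}, cfg)
        assert validated.validated

        site2 = RecurrentSite(
            site=GenomicSite("chr1", 100, "C", "T"), n_samples_detected=2, sample_vafs={}
        )
        clean = synthetic_pileup_column(rng, "chr1", 100, "C", "T", depth=30, vaf=0.0, eps=0.0)
        (nv,) = validate_in_cohort([site2], {"V1": {("chr1", 100): clean}}, cfg)
        assert nv.validated is False

        site3 = RecurrentSite(
            site=GenomicSite("chr1", 100, "C", "T"), n_samples_detected=2, sample_vafs={}
        )
        (unc,) = validate_in_cohort([site3], {"V1": {}}, cfg)
        assert unc.validated is False and unc.validation_flag == "uncovered"


class TestPlantedRecovery:
    def test_sensitivity_and_specificity_across_seeds(self, cfg):
        """Planted sites (VAF >= 0.10, coverage >= 30) must be recovered
        with sensitivity >= 0.95 and there must be no PASS calls at clean
        sites, across 20 seeds."""
        sample_ids = [f"S{i}" for i in range(8)]
        planted, found, false_pos = 0, 0, 0
        for ss in np.random.SeedSequence(777).spawn(20):
            panel = simulate_site_panel(ss, sample_ids)
            for sid in sample_ids:
                for site in panel.sites:
                    key = (site.chrom, site.pos)
                    call = evaluate_site(panel.dna[sid][key], panel.rna[sid][key], None, cfg)
                    is_pass = call is not None and call.is_pass
                    if sid in panel.edited_in.get(site.key, []):
                        planted += 1
                        found += is_pass
                    else:
                        false_pos += is_pass
        assert false_pos == 0
        assert found / planted >= 0.95

    def test_recurrent_set_matches_planted_truth(self, cfg):
        sample_ids = [f"S{i}" for i in range(10)]
        panel = simulate_site_panel(np.random.SeedSequence(5), sample_ids)
        from editscan.annotate import annotate
        from editscan.pipeline import _model_for

        by_sample = {}
        for sid in sample_ids:
            calls = []
            for site in panel.sites:
                key = (site.chrom, site.pos)
                call = evaluate_site(panel.dna[sid][key], panel.rna[sid][key], None, cfg)
                if call is None:
                    continue
                model = _model_for(call.site.pos, call.site.chrom, panel.models)
                annotate(call, model, panel.genome)
                calls.append(call)
            by_sample[sid] = exclude_hla(calls, cfg)
        recurrent = recurrence_filter(by_sample, cfg, require_nonsynonymous=True)
        assert {r.site.key for r in recurrent} == panel.recurrent_truth
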