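"""End-to-end orchestration over a synthetic cohort.

Stages: simulate -> call (+ annotate, HLA exclusion, recurrence,
validation) -> splice quantification -> Sanger comparison -> expression
screen -> survival. Each stage is an importable function returning plain
data structures; ``run_end_to_end`` wires them together, writes TSV/JSON
outputs and a run manifest, and reports recovery against the planted
truth.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from editscan.calling import (
    evaluate_site,
    exclude_hla,
    recurrence_filter,
    validate_in_cohort,
)
from editscan.annotate import annotate
from editscan.config import PipelineConfig, RunManifest
from editscan.model import RecurrentSite, TranscriptModel
from editscan.pileup import pileup_from_reads
from editscan.sanger import editing_fraction
from editscan.simulate import CohortSim, simulate_cohort, write_cohort
from editscan.splicing import editing_retention_correlation, quantify_sample
from editscan.survival import (
    cox_hr_binary,
    endpoint_arrays,
    maxstat_cutpoint,
    pearson_screen,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("call", "splice", "sanger", "screen", "survive")


def _model_for(pos: int, chrom: str, models: list[TranscriptModel]) -> Optional[TranscriptModel]:
    for m in models:
        if m.chrom == chrom and any(pos in iv for iv in m.exons):
            return m
    return None


def stage_call(sim: CohortSim, cfg: PipelineConfig) -> dict:
    """Per-sample calling over the site panel plus the junction locus,
    annotation, HLA exclusion, recurrence and validation."""
    panel = sim.panel
    calls_by_sample: dict[str, list] = {}
    for s in sim.samples:
        sid = s.sample_id
        calls = []
        for key in sorted(panel.dna[sid]):
            call = evaluate_site(panel.dna[sid][key], panel.rna[sid][key], None, cfg)
            if call is None:
                continue
            model = _model_for(call.site.pos, call.site.chrom, panel.models)
            if model is not None:
                annotate(call, model, panel.genome)
            calls.append(call)
        # the junction locus site, genotyped from the RNA reads
        site = sim.locus.junction.edit_site
        (rna_col,) = pileup_from_reads(
            s.rna_reads, site.chrom, [site.pos], [site.ref_base],
            material="RNA", sample_id=sid, exclude_duplicates=cfg.exclude_duplicates,
        )
        call = evaluate_site(s.dna_column, rna_col, site.alt_base, cfg)
        if call is not None:
            annotate(call, sim.locus.model, sim.locus.genome)
            calls.append(call)
        calls_by_sample[sid] = exclude_hla(calls, cfg)
    recurrent = recurrence_filter(calls_by_sample, cfg, require_nonsynonymous=True)
    panel_recurrent = [r for r in recurrent if r.site.chrom == panel.sites[0].chrom]
    validate_in_cohort(panel_recurrent, sim.validation, cfg)
    found = {r.site.key for r in panel_recurrent}
    validated_found = {r.site.key for r in panel_recurrent if r.validated}
    truth_rec = {tuple(k) for k in sim.truth.recurrent_sites}
    truth_val = {tuple(k) for k in sim.truth.validated_sites}
    return {
        "calls_by_sample": calls_by_sample,
        "recurrent": recurrent,
        "n_recurrent": len(panel_recurrent),
        "recurrent_exact": found == truth_rec,
        "validated_exact": validated_found == truth_val,
        "recurrent_found": sorted(found),
        "validated_found": sorted(validated_found),
    }


def stage_splice(sim: CohortSim, cfg: PipelineConfig) -> pd.DataFrame:
    """Splice-state editing, retention and overall editing depth per sample."""
    rows = []
    site = sim.locus.junction.edit_site
    for s in sim.samples:
        res = quantify_sample(s.rna_reads, sim.locus.junction, cfg, sample_id=s.sample_id)
        (col,) = pileup_from_reads(
            s.rna_reads, site.chrom, [site.pos], [site.ref_base],
            exclude_duplicates=cfg.exclude_duplicates,
        )
        rows.append(
            {
                "sample_id": s.sample_id,
                "n_spliced": res.n_spliced,
                "n_unspliced": res.n_unspliced,
                "vaf_spliced": res.vaf_spliced,
                "vaf_unspliced": res.vaf_unspliced,
                "retention_read": res.retention_read,
                "retention_cov": res.retention_cov,
                "editing_depth": col.vaf(site.alt_base),
            }
        )
    return pd.DataFrame(rows)


def stage_sanger(sim: CohortSim, splice_table: pd.DataFrame) -> pd.DataFrame:
    """Sanger peak-ratio estimate next to the sequencing-based VAF."""
    site = sim.locus.junction.edit_site
    rows = []
    for s in sim.samples:
        frac = editing_fraction(s.sanger, primary=site.ref_base, edited=site.alt_base)
        rows.append({"sample_id": s.sample_id, "sanger_fraction": frac})
    out = pd.DataFrame(rows).merge(
        splice_table[["sample_id", "editing_depth"]], on="sample_id"
    )
    out["abs_diff"] = (out["sanger_fraction"] - out["editing_depth"]).abs()
    return out


def stage_screen(sim: CohortSim) -> dict:
    """Expression-vs-editing Pearson screen on the cohort's matrix."""
    editing = [r.editing_pct for r in sim.records]
    ranked = pearson_screen([(editing, sim.expression)])
    regulator_rank = int(ranked.loc[sim.truth.regulator_gene, "rank"])
    return {"table": ranked, "regulator_rank": regulator_rank}


def stage_survival(sim: CohortSim, cfg: PipelineConfig) -> dict:
    """Maxstat cutpoint, Cox HR and log-rank for both endpoints."""
    out = {}
    for endpoint in ("tt", "os"):
        ed, t, e = endpoint_arrays(sim.records, endpoint)
        cut = maxstat_cutpoint(ed, t, e, cfg)
        # HR of the elevated-hazard (editing-low) group vs editing-high
        hr_low, ci_low, p_low = cox_hr_binary((ed <= cut.cutoff).astype(int), t, e)
        out[endpoint] = {
            "cutpoint": cut,
            "hr_low_vs_high": hr_low,
            "hr_low_ci": ci_low,
            "cutoff_error_pct": float(cut.cutoff - sim.truth.survival_cutoff_pct),
        }
    return out


def run_end_to_end(
    out_dir: str | Path,
    n_samples: int = 40,
    seed: int = 0,
    cfg: Optional[PipelineConfig] = None,
    stages: tuple[str, ...] = ALL_STAGES,
    write_inputs: bool = False,
    sim: Optional[CohortSim] = None,
) -> dict:
    """Simulate a cohort and run the requested stages, writing plain-text
    outputs plus a manifest; returns the stage summaries."""
    cfg = cfg or PipelineConfig(rng_seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sim is None:
        sim = simulate_cohort(n_samples=n_samples, seed=seed)
    if write_inputs:
        write_cohort(sim, out / "inputs")
    summary: dict = {"seed": seed, "n_samples": len(sim.samples)}

    if "call" in stages:
        res = stage_call(sim, cfg)
        summary["call"] = {
            "n_recurrent": res["n_recurrent"],
            "recurrent_exact": res["recurrent_exact"],
            "validated_exact": res["validated_exact"],
        }
        from editscan.vcfio import write_vcf

        all_calls = [c for calls in res["calls_by_sample"].values() for c in calls]
        write_vcf(all_calls, out / "calls.vcf")
        pd.DataFrame(
            [
                {
                    "chrom": r.site.chrom,
                    "pos": r.site.pos,
                    "ref": r.site.ref_base,
                    "alt": r.site.alt_base,
                    "n_samples": r.n_samples_detected,
                    "validated": r.validated,
                }
                for r in res["recurrent"]
            ]
        ).to_csv(out / "recurrent_sites.tsv", sep="\t", index=False)

    splice_table = None
    if "splice" in stages:
        splice_table = stage_splice(sim, cfg)
        splice_table.to_csv(out / "splice_editing.tsv", sep="\t", index=False)
        r, p = editing_retention_correlation(
            splice_table["editing_depth"], splice_table["retention_read"]
        )
        summary["splice"] = {
            "editing_retention_r": r,
            "editing_retention_p": p,
            "max_vaf_spliced": float(splice_table["vaf_spliced"].max()),
        }

    if "sanger" in stages:
        if splice_table is None:
            splice_table = stage_splice(sim, cfg)
        sg = stage_sanger(sim, splice_table)
        sg.to_csv(out / "sanger.tsv", sep="\t", index=False)
        summary["sanger"] = {"max_abs_diff": float(sg["abs_diff"].max())}

    if "screen" in stages:
        res = stage_screen(sim)
        res["table"].to_csv(out / "screen_ranked.tsv", sep="\t")
        summary["screen"] = {"regulator_rank": res["regulator_rank"]}

    if "survive" in stages:
        res = stage_survival(sim, cfg)
        summary["survive"] = {
            ep: {
                "cutoff": res[ep]["cutpoint"].cutoff,
                "max_std_logrank": res[ep]["cutpoint"].max_std_logrank,
                "logrank_p": res[ep]["cutpoint"].logrank_p,
                "hr_low_vs_high": res[ep]["hr_low_vs_high"],
                "cutoff_error_pct": res[ep]["cutoff_error_pct"],
            }
            for ep in res
        }
        (out / "survival.json").write_text(json.dumps(summary["survive"], indent=2) + "\n")

    manifest = RunManifest(config=cfg, seed=seed)
    manifest.write(out / "manifest.json")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
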