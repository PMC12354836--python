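#!/usr/bin/env python
"""Call RNA-unique editing sites across the cohort, collapse to
recurrent sites, and screen them in the validation cohort.

Finding on the default cohort: every planted recurrent site is
recovered, the HLA decoy is excluded, no false-positive site survives,
and the validated subset matches the planted truth exactly.
"""
import json
from pathlib import Path

from editscan.config import PipelineConfig
from editscan.pipeline import stage_call
from editscan.simulate import simulate_cohort
from editscan.vcfio import write_vcf

SEED = 7
OUT = Path("results/calling")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(rng_seed=SEED)
    sim = simulate_cohort(n_samples=40, seed=SEED)
    res = stage_call(sim, cfg)
    all_calls = [c for calls in res["calls_by_sample"].values() for c in calls]
    write_vcf(all_calls, OUT / "calls.vcf")
    truth_rec = {tuple(k) for k in sim.truth.recurrent_sites}
    found = set(res["recurrent_found"])
    print(f"candidate calls: {len(all_calls)} ({sum(c.is_pass for c in all_calls)} PASS)")
    print(f"recurrent sites: {len(found)} found / {len(truth_rec)} planted; "
          f"exact match: {res['recurrent_exact']}")
    print(f"validated subset exact: {res['validated_exact']}")
    (OUT / "recovery.json").write_text(
        json.dumps(
            {
                "n_calls": len(all_calls),
                "recurrent_exact": res["recurrent_exact"],
                "validated_exact": res["validated_exact"],
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
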