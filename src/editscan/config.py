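"""Run configuration and reproducibility manifest.

Defaults reproduce the published pipeline settings: site gates at mean
base quality 20 and coverage 6 in both materials, RNA-unique calling at
coverage 8 / variant fraction 0.05, splice-resolved re-genotyping at
min 1 alt read / fraction 0.001, and recurrence across >= 2 samples.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    min_mean_baseq: float = 20.0  # strict: fail if mean baseq below this
    min_site_cov: int = 6  # strict: fail if coverage less than this
    min_rna_cov_call: int = 8
    min_var_freq: float = 0.05
    min_var_freq_splice: float = 0.001
    min_reads2_splice: int = 1
    min_alt_reads_call: int = 2
    recurrence_min_samples: int = 2
    max_dna_vaf: float = 0.02
    fisher_alpha: float = 0.05
    hla_gene_prefixes: list[str] = field(default_factory=lambda: ["HLA-"])
    maxstat_quantile_bounds: tuple[float, float] = (0.10, 0.90)
    editing_high_cutoff_pct: float = 14.29  # published high/low example cutoff
    drop_variant_on_any_end_read: bool = False
    exclude_duplicates: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            self.min_mean_baseq >= 0,
            self.min_site_cov >= 0,
            self.min_rna_cov_call >= 0,
            0.0 <= self.min_var_freq <= 1.0,
            0.0 <= self.min_var_freq_splice <= 1.0,
            self.min_reads2_splice >= 0,
            self.recurrence_min_samples >= 1,
            0.0 <= self.max_dna_vaf <= 1.0,
            0.0 < self.fisher_alpha <= 1.0,
            0.0 <= self.maxstat_quantile_bounds[0]
            < self.maxstat_quantile_bounds[1]
            <= 1.0,
        ]
        if not all(checks):
            raise ValueError("PipelineConfig threshold out of range")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "maxstat_quantile_bounds" in raw:
            raw["maxstat_quantile_bounds"] = tuple(raw["maxstat_quantile_bounds"])
        return cls(**raw)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config, seed, input hashes."""

    config: PipelineConfig
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    tool_version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.tool_version:
            from editscan import __version__

            self.tool_version = __version__
        if not self.created:
            self.created = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def write(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
            "inputs": self.inputs,
            "tool_version": self.tool_version,
            "created": self.created,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
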