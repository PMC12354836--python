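"""Shared fixtures: a default configuration, the synthetic locus, and
helpers for hand-building pileup columns."""
from __future__ import annotations

import numpy as np
import pytest

from editscan.config import PipelineConfig
from editscan.model import PileupColumn, ReadObservation
from editscan.simulate import Locus, make_locus


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def locus() -> Locus:
    return make_locus(seed=11)


@pytest.fixture(scope="session")
def minus_locus() -> Locus:
    return make_locus(seed=11, strand="-")


def make_column(
    chrom="chr1",
    pos=100,
    ref="C",
    n_ref=20,
    alt="T",
    n_alt=0,
    baseq=37,
    material="RNA",
    sample_id="S1",
    alt_strands=("+", "-"),
    alt_edge=False,
    alt_indel=False,
    read_len=100,
) -> PileupColumn:
    """Hand-built pileup column: n_ref reference observations split over
    both strands, plus n_alt alt observations with controllable strand,
    read-edge and indel context."""
    obs = []
    for i in range(n_ref):
        obs.append(
            ReadObservation(
                base=ref,
                base_quality=baseq,
                read_strand="+" if i % 2 == 0 else "-",
                pos_in_read=10 + (i % 50),
                read_length=read_len,
            )
        )
    for i in range(n_alt):
        strand = alt_strands[i % len(alt_strands)]
        pos_in_read = 1 if (alt_edge and i % 2 == 0) else (read_len if alt_edge else 20 + i)
        obs.append(
            ReadObservation(
                base=alt,
                base_quality=baseq,
                read_strand=strand,
                pos_in_read=pos_in_read,
                read_length=read_len,
                in_indel=alt_indel,
            )
        )
    return PileupColumn(
        chrom=chrom, pos=pos, ref_base=ref, observations=obs,
        material=material, sample_id=sample_id,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
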