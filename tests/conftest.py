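import numpy as np
import pytest

from methyltag.core import AlignedFragment, BisulfiteStrand, Genome, MateRead
from methyltag.simulate import SimulationConfig, simulate_dataset


def make_mate(seq: str, ref_start: int, is_read1: bool = True, qual: int = 40):
    return MateRead(
        seq=seq,
        quals=np.full(len(seq), qual, dtype=np.int64),
        ref_start=ref_start,
        is_read1=is_read1,
    )


def make_fragment(
    contig="c1",
    start=0,
    end=None,
    strand=BisulfiteStrand.OT,
    mates=(),
    name="f1",
    mapq=40,
):
    if end is None:
        end = max(m.ref_end for m in mates) if mates else start + 1
    return AlignedFragment(
        query_name=name,
        contig=contig,
        start=start,
        end=end,
        bisulfite_strand=strand,
        mapq=mapq,
        mates=tuple(mates),
    )


@pytest.fixture
def tiny_genome():
    return Genome.from_sequences({"c1": "TACGT"})


@pytest.fixture(scope="session")
def sim_small():
    """Default-noise simulation at reduced scale, shared across tests."""
    cfg = SimulationConfig(seed=11, genome_length=50_000, n_peaks=10)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_noise_free():
    """Noise-free chemistry: conversion perfect, no failures, no errors."""
    cfg = SimulationConfig(
        seed=7,
        genome_length=50_000,
        n_peaks=10,
        conversion_rate=1.0,
        failure_rate=0.0,
        sequencing_error=0.0,
    )
    return cfg, simulate_dataset(cfg)
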