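"""Shared fixtures and record-construction helpers."""

from __future__ import annotations

import itertools

import pytest

from pirnaflow.io_core import AlignmentRecord, Library, SmallRNARead
from pirnaflow.simulate import (
    ClusterSpec,
    ConditionSpec,
    GenomeSpec,
    ReadModel,
    SimConfig,
    TESpec,
    simulate,
)

_counter = itertools.count()


def uniq_seq(length: int) -> str:
    """Deterministic distinct sequence of the given length (base-4 counter)."""
    n = next(_counter)
    digits = []
    for _ in range(length):
        digits.append("ACGT"[n % 4])
        n //= 4
    return "".join(digits)


def rec(
    ref: str,
    fp: int,
    length: int,
    strand: str,
    seq: str | None = None,
    copy: int = 1,
) -> AlignmentRecord:
    """Build a record from its 5'-end position, length and strand."""
    if strand == "+":
        start, end = fp, fp + length
    else:
        start, end = fp - length + 1, fp + 1
    return AlignmentRecord(
        read=SmallRNARead(seq or uniq_seq(length), copy),
        ref_id=ref,
        start=start,
        end=end,
        strand=strand,
    )


def lib_of(records, ref_lengths=None, total_mapped=None, name="test") -> Library:
    return Library(
        name=name,
        records=list(records),
        total_mapped=total_mapped,
        ref_lengths=ref_lengths,
    )


def pirna_only_config(
    seed: int,
    *,
    genome=None,
    clusters=None,
    total_reads: int = 15_000,
    n_species: int = 1_500,
    pingpong: float = 0.0,
    conditions=None,
) -> SimConfig:
    """A piRNA-only simulation (no miRNA/20-nt/TE classes)."""
    return SimConfig(
        seed=seed,
        genome=genome or GenomeSpec(n_contigs=2, contig_length=30_000),
        clusters=clusters
        or ClusterSpec(
            n_clusters=4,
            cluster_length=4_000,
            bidirectional_fraction=1.0,
            inside_fraction=0.9,
        ),
        te=TESpec(n_te=0),
        reads=ReadModel(
            total_reads=total_reads,
            mode_weights={30: 1.0},
            n_pirna_species=n_species,
            n_mirna=0,
            n_bg20_species=0,
            te_read_fraction=0.0,
            n_te_species=0,
            pingpong_fraction=pingpong,
        ),
        conditions=conditions or [ConditionSpec("ctrl", 1.0, 1.0, 1)],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One full default simulation shared across the suite."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_genome_lib(default_sim):
    return default_sim.genome_library("luciferase", 1)
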