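"""Size/complexity profiles, positional nucleotide bias, and miRNA annotation.

Abundance is the copy-weighted (uncollapsed) read count; complexity is the
number of distinct collapsed sequences.  Both are reported in reads per
million total genome-mapped reads (RPM), so over the full length range the
abundance curve sums to 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Library, normalize_sequence, to_rna

__all__ = [
    "size_profile",
    "nucleotide_bias",
    "annotate_mirnas",
    "MirnaAnnotation",
]

_BASES = ("A", "C", "G", "U")


def size_profile(lib: Library, lo: int, hi: int) -> pd.DataFrame:
    """Per-length abundance and complexity of mapped reads, in RPM.

    Returns a DataFrame indexed by read length over ``[lo, hi]`` with columns
    ``abundance_rpm`` (copy-weighted) and ``complexity_rpm`` (distinct
    collapsed sequences), both divided by ``lib.total_mapped`` and scaled to
    a million.
    """
    if not lib.total_mapped:
        raise ValueError("library has no mapped reads (total_mapped == 0)")
    lengths = range(lo, hi + 1)
    abundance = dict.fromkeys(lengths, 0)
    complexity = dict.fromkeys(lengths, 0)
    for read in lib.distinct_reads():
        L = len(read)
        if lo <= L <= hi:
            abundance[L] += read.copy_count
            complexity[L] += 1
    scale = 1e6 / lib.total_mapped
    return pd.DataFrame(
        {
            "abundance_rpm": [abundance[L] * scale for L in lengths],
            "complexity_rpm": [complexity[L] * scale for L in lengths],
        },
        index=pd.Index(lengths, name="length"),
    )


def nucleotide_bias(
    lib: Library,
    lo: int,
    hi: int,
    weighting: str = "collapsed",
    positions: int | None = None,
) -> pd.DataFrame:
    """Positional nucleotide frequencies of reads in the ``[lo, hi]`` window.

    Rows are 5'-anchored positions 1..P (P defaults to ``lo``, the shortest
    length considered, so every row is defined for every read); columns are
    A/C/G/U and each row sums to 1.  ``weighting='collapsed'`` counts each
    distinct sequence once (the convention for sequence logos on collapsed
    sets); ``'abundance'`` weights by copy count.
    """
    if weighting not in ("collapsed", "abundance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    reads = [r for r in lib.distinct_reads() if lo <= len(r) <= hi]
    if not reads:
        raise ValueError(f"no reads in length window [{lo}, {hi}]")
    P = positions if positions is not None else lo
    if P > min(len(r) for r in reads):
        raise ValueError("positions exceeds the shortest read length considered")
    counts = np.zeros((P, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for read in reads:
        w = read.copy_count if weighting == "abundance" else 1
        for pos in range(P):
            counts[pos, base_idx[read.sequence[pos]]] += w
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        freqs, index=pd.Index(range(1, P + 1), name="position"), columns=list(_BASES)
    )


@dataclass(frozen=True)
class MirnaAnnotation:
    """A library read matched at full-length 100% identity to a mature miRNA."""

    sequence: str
    mirna_id: str
    rpm: float
    tied_ids: tuple[str, ...] = ()


def annotate_mirnas(
    lib: Library,
    mature_ref: dict[str, str],
    min_rpm: float = 1.0,
) -> list[MirnaAnnotation]:
    """Annotate library reads matching mature miRNA reference sequences.

    A read is annotated when its sequence equals a reference mature sequence
    exactly (full length, no mismatches, no 3' trimming) and its abundance is
    at least ``min_rpm`` reads per million total mapped reads.  When several
    reference entries share a sequence the lexicographically smallest id is
    reported and the remaining ties listed.
    """
    if not mature_ref:
        raise ValueError("empty mature miRNA reference")
    if not lib.total_mapped:
        raise ValueError("library has no mapped reads")
    by_seq: dict[str, list[str]] = {}
    for mid, seq in mature_ref.items():
        by_seq.setdefault(normalize_sequence(seq), []).append(mid)
    out: list[MirnaAnnotation] = []
    for read in lib.distinct_reads():
        ids = by_seq.get(read.sequence)
        if ids is None:
            continue
        rpm = read.copy_count * 1e6 / lib.total_mapped
        if rpm < min_rpm:
            continue
        ids = sorted(ids)
        out.append(
            MirnaAnnotation(
                sequence=to_rna(read.sequence),
                mirna_id=ids[0],
                rpm=rpm,
                tied_ids=tuple(ids[1:]),
            )
        )
    out.sort(key=lambda a: (-a.rpm, a.mirna_id))
    return out
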