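"""Sliding-window piRNA cluster discovery and cluster summaries.

Clusters are called from uniquely-mapping collapsed 28-32-nt reads by
counting distinct sequences whose 5' ends fall in 1-kb windows tiled every
968 nt, keeping windows with at least 10 reads, and merging qualifying
windows that overlap or abut.  The 32-nt overlap between consecutive windows
(1000 - 968) matches the longest piRNA considered, so no read can straddle
every window boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import AlignmentRecord, Library, filter_by_length

__all__ = [
    "PiRNACluster",
    "ClusterSummary",
    "call_clusters",
    "classify_directionality",
    "summarize_clusters",
    "assign_transcripts_to_clusters",
]


@dataclass
class PiRNACluster:
    """A merged-window genomic interval with unique-read support."""

    ref_id: str
    start: int
    end: int
    n_unique_reads: int
    plus_count: int
    minus_count: int
    directionality: str = "unidirectional"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClusterSummary:
    n_clusters: int
    median_length: float
    max_length: int
    genome_fraction: float
    unique_pirna_fraction: float


def _pirna_unique_records(
    lib: Library, lo: int, hi: int
) -> list[AlignmentRecord]:
    sized = filter_by_length(lib, lo, hi)
    return [r for r in sized.records if r.n_hits == 1]


def _window_starts(contig_len: int, window_size: int, step: int) -> list[int]:
    # every window start < contig length; windows are clipped at the contig end
    return list(range(0, max(contig_len, 1), step))


def call_clusters(
    lib: Library,
    window_size: int = 1000,
    step: int = 968,
    min_reads: int = 10,
    lo: int = 28,
    hi: int = 32,
    trim: bool = True,
) -> list[PiRNACluster]:
    """Call piRNA clusters on a genome-aligned library.

    Windows of ``window_size`` tiled every ``step`` nt are scored by the
    number of distinct uniquely-mapping collapsed sequences of length
    ``lo``..``hi`` whose 5' end lies in the window.  Windows with at least
    ``min_reads`` such sequences are merged when they overlap or abut, and
    (by default) the merged bounds are trimmed to the outermost supporting
    reads.  Requires ``lib.ref_lengths`` for window tiling.
    """
    if not window_size > step > 0:
        raise ValueError("require window_size > step > 0")
    if lib.ref_lengths is None:
        raise ValueError("library has no reference lengths; load with a FASTA")
    records = _pirna_unique_records(lib, lo, hi)
    by_ref: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_ref.setdefault(r.ref_id, []).append(r)

    clusters: list[PiRNACluster] = []
    for ref_id in sorted(by_ref):
        recs = by_ref[ref_id]
        contig_len = lib.ref_lengths[ref_id]
        fps = np.array(sorted(r.five_prime for r in recs))
        # qualifying windows
        qual: list[tuple[int, int]] = []
        for w in _window_starts(contig_len, window_size, step):
            w_end = min(w + window_size, contig_len)
            n = int(
                np.searchsorted(fps, w_end, side="left")
                - np.searchsorted(fps, w, side="left")
            )
            if n >= min_reads:
                qual.append((w, w_end))
        # merge overlapping/abutting qualifying windows
        merged: list[list[int]] = []
        for s, e in qual:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            support = [r for r in recs if s <= r.five_prime < e]
            if not support:
                continue
            if trim:
                cs = min(r.start for r in support)
                ce = max(r.end for r in support)
            else:
                cs, ce = s, e
            plus = sum(1 for r in support if r.strand == "+")
            minus = len(support) - plus
            clusters.append(
                PiRNACluster(
                    ref_id=ref_id,
                    start=cs,
                    end=ce,
                    n_unique_reads=len(support),
                    plus_count=plus,
                    minus_count=minus,
                )
            )
    for c in clusters:
        c.directionality = classify_directionality(c)
    return clusters


def classify_directionality(
    cluster: PiRNACluster, bidir_min_frac: float = 0.25
) -> str:
    """Bidirectional iff the minor strand holds >= ``bidir_min_frac`` of reads."""
    total = cluster.plus_count + cluster.minus_count
    if total == 0:
        raise ValueError("cluster has no supporting reads")
    minor = min(cluster.plus_count, cluster.minus_count)
    return "bidirectional" if minor / total >= bidir_min_frac else "unidirectional"


def summarize_clusters(
    clusters: list[PiRNACluster],
    lib: Library,
    lo: int = 28,
    hi: int = 32,
) -> ClusterSummary:
    """Aggregate statistics over a cluster catalogue.

    ``unique_pirna_fraction`` is the share of distinct uniquely-mapping
    ``lo``..``hi``-nt sequences whose 5' end lies inside any cluster;
    ``genome_fraction`` is total cluster length over total contig length.
    """
    if lib.ref_lengths is None:
        raise ValueError("library has no reference lengths")
    genome_size = sum(lib.ref_lengths.values())
    if not clusters:
        return ClusterSummary(0, 0.0, 0, 0.0, 0.0)
    lengths = np.array([c.length for c in clusters])
    by_ref: dict[str, list[PiRNACluster]] = {}
    for c in clusters:
        by_ref.setdefault(c.ref_id, []).append(c)
    records = _pirna_unique_records(lib, lo, hi)
    n_in = 0
    for r in records:
        fp = r.five_prime
        if any(c.start <= fp < c.end for c in by_ref.get(r.ref_id, ())):
            n_in += 1
    frac = n_in / len(records) if records else 0.0
    return ClusterSummary(
        n_clusters=len(clusters),
        median_length=float(np.median(lengths)),
        max_length=int(lengths.max()),
        genome_fraction=float(lengths.sum() / genome_size),
        unique_pirna_fraction=frac,
    )


def assign_transcripts_to_clusters(
    transcript_placements: dict[str, tuple[str, int, int] | None],
    clusters: list[PiRNACluster],
    min_overlap_frac: float = 0.5,
) -> dict[str, str]:
    """Flag transcripts as inside or outside the cluster catalogue.

    ``transcript_placements`` maps transcript id to its genomic interval
    ``(ref_id, start, end)`` or ``None`` when unplaced.  A transcript is
    ``"in"`` when a cluster covers at least ``min_overlap_frac`` of its
    length; unplaced transcripts are flagged ``"unplaced"`` and excluded
    from any denominator downstream.
    """
    by_ref: dict[str, list[PiRNACluster]] = {}
    for c in clusters:
        by_ref.setdefault(c.ref_id, []).append(c)
    out: dict[str, str] = {}
    for tid, placement in transcript_placements.items():
        if placement is None:
            out[tid] = "unplaced"
            continue
        ref_id, start, end = placement
        t_len = end - start
        if t_len <= 0:
            raise ValueError(f"transcript {tid} has non-positive length")
        best = 0
        for c in by_ref.get(ref_id, ()):
            ov = min(end, c.end) - max(start, c.start)
            best = max(best, ov)
        out[tid] = "in" if best >= min_overlap_frac * t_len else "out"
    return out
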