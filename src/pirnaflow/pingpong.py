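"""Ping-pong signature: 5'-overlap histograms and the position-10 Z-score.

Secondary piRNA biogenesis produces sense/antisense pairs whose 5' ends
overlap by exactly 10 nt.  Its statistical footprint is an excess of
opposite-strand read pairs at overlap 10 over neighbouring overlap lengths,
summarised as a Z-score of the overlap-10 score against a background of
other overlap lengths.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np

from .io_core import Library, filter_by_length

__all__ = ["OverlapHistogram", "overlap_histogram", "zscore10"]

DEFAULT_BACKGROUND = tuple(range(1, 10)) + tuple(range(11, 21))


@dataclass
class OverlapHistogram:
    """Overlap-length -> pair-score map with the position-10 Z-score.

    ``scores[o]`` is the summed pair weight at 5'-overlap ``o`` (1-based);
    ``z10`` is None when undefined, with the reason in ``z10_reason``.
    """

    scores: dict[int, float]
    n_pairs: int
    z10: float | None = None
    z10_reason: str | None = None
    o_max: int = 30
    background: tuple[int, ...] = field(default=DEFAULT_BACKGROUND)

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[o] for o in range(1, self.o_max + 1)])


def overlap_histogram(
    lib: Library,
    lo: int = 28,
    hi: int = 32,
    weight: str = "product",
    o_max: int = 30,
    background: tuple[int, ...] = DEFAULT_BACKGROUND,
) -> OverlapHistogram:
    """Score 5' overlaps between opposite-strand reads on the same contig.

    A (+, -) record pair contributes to overlap ``o`` when
    ``minus_five_prime - plus_five_prime + 1 == o`` with ``1 <= o <= o_max``,
    i.e. the two 5' ends face each other and overlap by ``o`` nt.  Pair
    weight is ``product`` (copy_count_a * copy_count_b), ``min``, or ``unit``
    (1 per pair), in every case divided by ``n_hits_a * n_hits_b`` so that
    multi-mapping reads contribute fractionally per placement pair.

    The Z-score of the overlap-10 score against the ``background`` overlap
    lengths is filled in; it is left undefined on an empty selection or a
    zero-variance background.
    """
    if weight not in ("product", "min", "unit"):
        raise ValueError(f"unknown weight scheme {weight!r}")
    sized = filter_by_length(lib, lo, hi)
    # index minus-strand records by (contig, 5' position)
    minus_at: dict[tuple[str, int], list] = collections.defaultdict(list)
    for r in sized.records:
        if r.strand == "-":
            minus_at[(r.ref_id, r.five_prime)].append(r)
    scores = dict.fromkeys(range(1, o_max + 1), 0.0)
    n_pairs = 0
    for r in sized.records:
        if r.strand != "+":
            continue
        for o in range(1, o_max + 1):
            for m in minus_at.get((r.ref_id, r.five_prime + o - 1), ()):
                if weight == "product":
                    w = r.read.copy_count * m.read.copy_count
                elif weight == "min":
                    w = min(r.read.copy_count, m.read.copy_count)
                else:
                    w = 1.0
                scores[o] += w / (r.n_hits * m.n_hits)
                n_pairs += 1
    hist = OverlapHistogram(
        scores=scores, n_pairs=n_pairs, o_max=o_max, background=tuple(background)
    )
    if n_pairs == 0:
        hist.z10_reason = "no opposite-strand pairs in selection"
    else:
        hist.z10, hist.z10_reason = _z10(hist)
    return hist


def _z10(hist: OverlapHistogram) -> tuple[float | None, str | None]:
    bg = np.array([hist.scores[o] for o in hist.background], dtype=float)
    sd = bg.std(ddof=1)
    if sd == 0:
        # a flat background with s(10) equal to it means no enrichment at
        # all; any other s(10) over a flat background has no defined scale
        if hist.scores[10] == bg.mean():
            return 0.0, None
        return None, "zero-variance background (all background scores equal)"
    return float((hist.scores[10] - bg.mean()) / sd), None


def zscore10(hist: OverlapHistogram) -> float | None:
    """Z-score of the overlap-10 score against the histogram's background set.

    Computed as ``(s(10) - mean(background)) / sd(background)`` with the
    sample (ddof=1) standard deviation; None when the background has zero
    variance (reason recorded on the histogram).
    """
    z, reason = _z10(hist)
    hist.z10, hist.z10_reason = z, reason
    return z
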