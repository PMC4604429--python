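"""Multi-mapper-aware transposon quantification and condition comparison.

Reads aligned to a transposon-consensus set are counted with 1/n_hits
weighting (each placement of a read carries copy_count / n_hits), then
normalised for consensus length and for the total number of reads aligned
to the whole genome, giving an RPKM-like expression value per consensus.
The same weighting drives per-consensus strand bias and the transcript
qualification rule (>= 100 RPKM or >= 100 reads per million).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Library, filter_by_length

__all__ = [
    "TEQuant",
    "TranscriptQuant",
    "ConditionComparison",
    "quantify_te",
    "strand_bias_table",
    "qualify_pirna_transcripts",
    "compare_conditions",
]


@dataclass
class TEQuant:
    """Weighted, normalised expression of one transposon consensus."""

    te_id: str
    weighted_count: float
    norm_expr: float  # weighted_count / (length_kb * total_genome_mapped / 1e6)
    sense_frac: float
    length_nt: int

    @property
    def antisense_frac(self) -> float:
        return 1.0 - self.sense_frac


@dataclass
class TranscriptQuant:
    transcript_id: str
    length_nt: int
    raw_count: float  # copy-weighted, multiplicity-divided
    rpm: float
    rpkm: float
    qualifies: bool


@dataclass
class ConditionComparison:
    feature_id: str
    mean_control: float
    mean_treatment: float
    log2fc: float
    n_control: int
    n_treatment: int


def _weighted_counts(lib: Library) -> dict[str, tuple[float, float]]:
    """Per-reference (total, sense) copy-weighted multiplicity-divided counts."""
    out: dict[str, list[float]] = {}
    for r in lib.records:
        w = r.read.copy_count / r.n_hits
        tot_sense = out.setdefault(r.ref_id, [0.0, 0.0])
        tot_sense[0] += w
        if r.strand == "+":
            tot_sense[1] += w
    return {k: (v[0], v[1]) for k, v in out.items()}


def quantify_te(
    lib: Library,
    total_genome_mapped: int,
    consensus_lengths: dict[str, int] | None = None,
) -> list[TEQuant]:
    """Quantify each transposon consensus from a consensus-aligned library.

    ``n_hits`` must reflect placements on the consensus set (a library
    loaded against the consensus FASTA satisfies this).  Consensuses with
    no placements are reported with zeros.  Conservation holds exactly:
    the weighted counts sum to the copy-weighted number of aligned reads.
    """
    if consensus_lengths is None:
        if lib.ref_lengths is None:
            raise ValueError("consensus lengths unavailable")
        consensus_lengths = lib.ref_lengths
    for te_id, L in consensus_lengths.items():
        if L <= 0:
            raise ValueError(f"consensus {te_id!r} has non-positive length")
    counts = _weighted_counts(lib)
    denom = total_genome_mapped / 1e6
    out = []
    for te_id in sorted(consensus_lengths):
        total, sense = counts.get(te_id, (0.0, 0.0))
        length = consensus_lengths[te_id]
        norm = total / (length / 1000 * denom) if total else 0.0
        out.append(
            TEQuant(
                te_id=te_id,
                weighted_count=total,
                norm_expr=norm,
                sense_frac=sense / total if total else float("nan"),
                length_nt=length,
            )
        )
    return out


def strand_bias_table(
    libs: list[Library],
    total_genome_mapped: dict[str, int],
    te_ids: list[str] | None = None,
    min_count: float = 10.0,
) -> pd.DataFrame:
    """Sense-fraction matrix (consensus x library) for strand-bias heatmaps.

    Cells whose weighted total count is below ``min_count`` are masked (NaN).
    ``total_genome_mapped`` maps library name to its genome-alignment RPM
    denominator.
    """
    columns = {}
    for lib in libs:
        quants = quantify_te(lib, total_genome_mapped[lib.name])
        columns[lib.name] = {
            q.te_id: (q.sense_frac if q.weighted_count >= min_count else np.nan)
            for q in quants
        }
    df = pd.DataFrame(columns)
    if te_ids is not None:
        df = df.reindex(te_ids)
    df.index.name = "te_id"
    return df


def qualify_pirna_transcripts(
    lib: Library,
    total_genome_mapped: int,
    transcript_lengths: dict[str, int] | None = None,
    lo: int = 28,
    hi: int = 32,
    threshold: float = 100.0,
) -> list[TranscriptQuant]:
    """Qualify piRNA-producing transcripts from a transcript-aligned library.

    Counts are copy-weighted, multiplicity-divided 28-32-nt reads.  A
    transcript qualifies when its RPKM **or** its reads-per-million reaches
    ``threshold``.  Output is sorted by RPKM descending.
    """
    if transcript_lengths is None:
        if lib.ref_lengths is None:
            raise ValueError("transcript lengths unavailable")
        transcript_lengths = lib.ref_lengths
    sized = filter_by_length(lib, lo, hi)
    counts = _weighted_counts(sized)
    denom = total_genome_mapped / 1e6
    out = []
    for tid in sorted(transcript_lengths):
        length = transcript_lengths[tid]
        if length <= 0:
            raise ValueError(f"transcript {tid!r} has non-positive length")
        raw, _ = counts.get(tid, (0.0, 0.0))
        rpm = raw / denom
        rpkm = raw / (length / 1000 * denom)
        out.append(
            TranscriptQuant(
                transcript_id=tid,
                length_nt=length,
                raw_count=raw,
                rpm=rpm,
                rpkm=rpkm,
                qualifies=(rpkm >= threshold or rpm >= threshold),
            )
        )
    out.sort(key=lambda q: (-q.rpkm, q.transcript_id))
    return out


def compare_conditions(
    counts_by_replicate: dict[str, dict[str, float]],
    design: dict[str, str],
    control: str = "control",
    treatment: str = "treatment",
    epsilon: float = 0.5,
) -> list[ConditionComparison]:
    """Per-feature fold change between two condition arms.

    ``counts_by_replicate`` maps replicate name -> feature -> count;
    ``design`` maps replicate name to its condition label.  For each feature
    present in either arm,
    ``log2fc = log2((mean_treatment + eps) / (mean_control + eps))``, with a
    feature absent from a replicate counted as 0 there.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    ctrl_reps = [r for r, c in design.items() if c == control]
    trt_reps = [r for r, c in design.items() if c == treatment]
    if not ctrl_reps or not trt_reps:
        raise ValueError(
            f"need >= 1 replicate per arm (control={len(ctrl_reps)}, "
            f"treatment={len(trt_reps)})"
        )
    missing = [r for r in ctrl_reps + trt_reps if r not in counts_by_replicate]
    if missing:
        raise ValueError(f"replicates without counts: {missing}")
    features = sorted(
        {f for r in ctrl_reps + trt_reps for f in counts_by_replicate[r]}
    )
    out = []
    for feat in features:
        mc = float(np.mean([counts_by_replicate[r].get(feat, 0.0) for r in ctrl_reps]))
        mt = float(np.mean([counts_by_replicate[r].get(feat, 0.0) for r in trt_reps]))
        out.append(
            ConditionComparison(
                feature_id=feat,
                mean_control=mc,
                mean_treatment=mt,
                log2fc=math.log2((mt + epsilon) / (mc + epsilon)),
                n_control=len(ctrl_reps),
                n_treatment=len(trt_reps),
            )
        )
    return out


def decreased_features(
    comparisons: list[ConditionComparison], max_log2fc: float = -1.0
) -> list[str]:
    """Features whose production decreased (log2 fold change <= threshold)."""
    return [c.feature_id for c in comparisons if c.log2fc <= max_log2fc]
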