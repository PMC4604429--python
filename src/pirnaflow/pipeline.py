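"""End-to-end orchestration: profile -> clusters -> transcripts -> ping-pong
-> transposon quantification -> condition comparison.

Stages communicate through files in the output directory so that any stage's
artifact can be inspected or reused; one machine-readable JSON report
collects every stage's summary together with all parameters and the SHA-256
checksum of every input.  Default parameters are the study values: 1-kb
windows with a 968-nt step, at least 10 reads per window, the 28-32-nt
piRNA window, a 100 RPKM-or-RPM transcript threshold, and a 1-rpm miRNA
floor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from pydantic import BaseModel

from . import __version__
from .clusters import call_clusters, summarize_clusters
from .io_core import Library, read_alignments, write_bed
from .pingpong import overlap_histogram
from .profiles import annotate_mirnas, nucleotide_bias, size_profile
from .te_quant import compare_conditions, quantify_te, qualify_pirna_transcripts

__all__ = ["RunConfig", "LibraryInput", "StageError", "run_all", "Report"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class LibraryInput:
    name: str
    condition: str
    genome_bed: str
    te_bed: str | None = None
    transcript_bed: str | None = None


@dataclass
class Params:
    window_size: int = 1000
    step: int = 968
    min_reads: int = 10
    pirna_lo: int = 28
    pirna_hi: int = 32
    transcript_threshold: float = 100.0
    mirna_min_rpm: float = 1.0
    bidir_min_frac: float = 0.25
    epsilon: float = 0.5
    size_profile_lo: int = 15
    size_profile_hi: int = 45


@dataclass
class RunConfig:
    genome_fasta: str
    libraries: list[LibraryInput]
    outdir: str
    te_fasta: str | None = None
    transcript_fasta: str | None = None
    mirna_fasta: str | None = None
    control_condition: str = "control"
    params: Params = field(default_factory=Params)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["libraries"] = [LibraryInput(**lib) for lib in d.get("libraries", [])]
        if "params" in d:
            d["params"] = Params(**d["params"])
        return cls(**d)

    def validate(self) -> None:
        missing = []
        for p in [self.genome_fasta, self.te_fasta, self.transcript_fasta,
                  self.mirna_fasta]:
            if p is not None and not Path(p).exists():
                missing.append(p)
        for lib in self.libraries:
            for p in [lib.genome_bed, lib.te_bed, lib.transcript_bed]:
                if p is not None and not Path(p).exists():
                    missing.append(p)
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        if not self.libraries:
            raise ValueError("no libraries configured")


class Report(BaseModel):
    """Machine-readable pipeline report (one per run)."""

    pirnaflow_version: str
    seed: int
    parameters: dict[str, float | int | str]
    inputs: dict[str, str]  # path -> sha256
    stages: dict[str, dict]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _round(x: float, nd: int = 6) -> float:
    return float(round(x, nd))


def _read_mirna_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line
    return seqs


def run_all(config: RunConfig) -> Report:
    """Execute every stage on every configured library and write the report.

    Any stage failure aborts the run with a :class:`StageError` naming the
    stage; artifacts written before the failure stay on disk and the report
    is not written (a partial run leaves no ``report.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    P = config.params

    inputs: dict[str, str] = {}
    for p in [config.genome_fasta, config.te_fasta, config.transcript_fasta,
              config.mirna_fasta]:
        if p is not None:
            inputs[str(p)] = _sha256(p)
    for lib in config.libraries:
        for p in [lib.genome_bed, lib.te_bed, lib.transcript_bed]:
            if p is not None:
                inputs[str(p)] = _sha256(p)

    stages: dict[str, dict] = {}

    genome_libs: dict[str, Library] = {}
    try:
        for li in config.libraries:
            genome_libs[li.name] = read_alignments(
                li.genome_bed, config.genome_fasta, format="bed",
                name=li.name, condition=li.condition)
    except Exception as exc:
        raise StageError("load", exc)

    # --- profile ----------------------------------------------------------
    try:
        stage: dict = {}
        mirna_ref = (_read_mirna_fasta(config.mirna_fasta)
                     if config.mirna_fasta else None)
        for name, lib in sorted(genome_libs.items()):
            prof = size_profile(lib, P.size_profile_lo, P.size_profile_hi)
            prof.to_csv(outdir / f"{name}.size_profile.tsv", sep="\t",
                        float_format="%.4f")
            bias = nucleotide_bias(lib, P.pirna_lo, P.pirna_hi)
            bias.to_csv(outdir / f"{name}.bias_matrix.tsv", sep="\t",
                        float_format="%.6f")
            entry = {
                "total_mapped": lib.total_mapped,
                "abundance_rpm_sum": _round(prof["abundance_rpm"].sum()),
                "u1_frequency": _round(bias.loc[1, "U"]),
            }
            if mirna_ref:
                hits = annotate_mirnas(lib, mirna_ref, P.mirna_min_rpm)
                with open(outdir / f"{name}.mirna_hits.tsv", "w") as fh:
                    fh.write("sequence\tmirna_id\trpm\n")
                    for h in hits:
                        fh.write(f"{h.sequence}\t{h.mirna_id}\t{h.rpm:.4f}\n")
                entry["n_mirna_annotated"] = len(hits)
            stage[name] = entry
        stages["profile"] = stage
    except StageError:
        raise
    except Exception as exc:
        raise StageError("profile", exc)

    # --- clusters ---------------------------------------------------------
    try:
        stage = {}
        for name, lib in sorted(genome_libs.items()):
            cls = call_clusters(lib, P.window_size, P.step, P.min_reads,
                                P.pirna_lo, P.pirna_hi)
            with open(outdir / f"{name}.clusters.bed", "w") as fh:
                for i, c in enumerate(cls, 1):
                    strand = ("." if c.directionality == "bidirectional"
                              else ("+" if c.plus_count >= c.minus_count
                                    else "-"))
                    fh.write(f"{c.ref_id}\t{c.start}\t{c.end}\tcluster_{i}\t"
                             f"{c.n_unique_reads}\t{strand}\n")
            summ = summarize_clusters(cls, lib, P.pirna_lo, P.pirna_hi)
            stage[name] = {
                "n_clusters": summ.n_clusters,
                "median_length": _round(summ.median_length),
                "max_length": summ.max_length,
                "genome_fraction": _round(summ.genome_fraction),
                "unique_pirna_fraction": _round(summ.unique_pirna_fraction),
                "n_bidirectional": sum(
                    1 for c in cls if c.directionality == "bidirectional"),
            }
        stages["clusters"] = stage
    except StageError:
        raise
    except Exception as exc:
        raise StageError("clusters", exc)

    # --- piRNA-producing transcripts ---------------------------------------
    try:
        stage = {}
        for li in config.libraries:
            if li.transcript_bed is None or config.transcript_fasta is None:
                continue
            tlib = read_alignments(li.transcript_bed, config.transcript_fasta,
                                   format="bed", name=li.name)
            quants = qualify_pirna_transcripts(
                tlib, genome_libs[li.name].total_mapped,
                lo=P.pirna_lo, hi=P.pirna_hi,
                threshold=P.transcript_threshold)
            with open(outdir / f"{li.name}.transcript_quant.tsv", "w") as fh:
                fh.write("transcript_id\tlength_nt\traw_count\trpm\trpkm"
                         "\tqualifies\n")
                for q in quants:
                    fh.write(f"{q.transcript_id}\t{q.length_nt}\t"
                             f"{q.raw_count:.3f}\t{q.rpm:.3f}\t{q.rpkm:.3f}\t"
                             f"{int(q.qualifies)}\n")
            stage[li.name] = {
                "n_qualifying": sum(1 for q in quants if q.qualifies),
                "n_transcripts": len(quants),
            }
        if stage:
            stages["transcripts"] = stage
    except StageError:
        raise
    except Exception as exc:
        raise StageError("transcripts", exc)

    # --- ping-pong ----------------------------------------------------------
    try:
        stage = {}
        for name, lib in sorted(genome_libs.items()):
            hist = overlap_histogram(lib, P.pirna_lo, P.pirna_hi)
            with open(outdir / f"{name}.pingpong.tsv", "w") as fh:
                fh.write("overlap\tscore\n")
                for o in range(1, hist.o_max + 1):
                    fh.write(f"{o}\t{hist.scores[o]:.4f}\n")
            stage[name] = {
                "z10": _round(hist.z10) if hist.z10 is not None else None,
                "z10_reason": hist.z10_reason,
                "n_pairs": hist.n_pairs,
            }
        stages["pingpong"] = stage
    except StageError:
        raise
    except Exception as exc:
        raise StageError("pingpong", exc)

    # --- transposon quantification ------------------------------------------
    te_counts_by_rep: dict[str, dict[str, float]] = {}
    design: dict[str, str] = {}
    try:
        stage = {}
        for li in config.libraries:
            if li.te_bed is None or config.te_fasta is None:
                continue
            telib = read_alignments(li.te_bed, config.te_fasta, format="bed",
                                    name=li.name)
            quants = quantify_te(telib, genome_libs[li.name].total_mapped)
            with open(outdir / f"{li.name}.te_quant.tsv", "w") as fh:
                fh.write("te_id\tweighted_count\tnorm_expr\tsense_frac\n")
                for q in quants:
                    fh.write(f"{q.te_id}\t{q.weighted_count:.3f}\t"
                             f"{q.norm_expr:.3f}\t{q.sense_frac:.4f}\n")
            te_counts_by_rep[li.name] = {
                q.te_id: q.weighted_count for q in quants}
            design[li.name] = li.condition
            stage[li.name] = {
                "total_weighted": _round(
                    sum(q.weighted_count for q in quants), 3),
                "n_te": len(quants),
            }
        if stage:
            stages["tequant"] = stage
    except StageError:
        raise
    except Exception as exc:
        raise StageError("tequant", exc)

    # --- condition comparison -----------------------------------------------
    try:
        stage = {}
        treatments = sorted({c for c in design.values()
                             if c != config.control_condition})
        for trt in treatments:
            sub = {r: c for r, c in design.items()
                   if c in (config.control_condition, trt)}
            comps = compare_conditions(
                {r: te_counts_by_rep[r] for r in sub}, sub,
                control=config.control_condition, treatment=trt,
                epsilon=P.epsilon)
            with open(outdir / f"comparison.{trt}.tsv", "w") as fh:
                fh.write("feature_id\tmean_control\tmean_treatment\tlog2fc\n")
                for c in comps:
                    fh.write(f"{c.feature_id}\t{c.mean_control:.3f}\t"
                             f"{c.mean_treatment:.3f}\t{c.log2fc:.4f}\n")
            stage[trt] = {
                "n_features": len(comps),
                "median_log2fc": _round(
                    sorted(c.log2fc for c in comps)[len(comps) // 2]
                    if len(comps) % 2 else
                    (sorted(c.log2fc for c in comps)[len(comps) // 2 - 1]
                     + sorted(c.log2fc for c in comps)[len(comps) // 2]) / 2),
            }
        if stage:
            stages["compare"] = stage
    except StageError:
        raise
    except Exception as exc:
        raise StageError("compare", exc)

    report = Report(
        pirnaflow_version=__version__,
        seed=config.seed,
        parameters={k: v for k, v in asdict(P).items()},
        inputs=inputs,
        stages=stages,
    )
    (outdir / "report.json").write_text(
        json.dumps(report.model_dump(), sort_keys=True, indent=1) + "\n")
    return report
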