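"""Synthetic small-RNA data with planted ground truth.

The simulator emulates the statistical structure of a flatworm small-RNA
study: three read-length populations (a ~20-nt class, 22-nt miRNAs, and
28-32-nt piRNAs with a strong 5' U bias), piRNAs concentrated in planted
genomic clusters (unidirectional or bidirectional), sense/antisense
ping-pong pairs whose 5' ends overlap by exactly 10 nt, transposon-derived
multi-mapping reads, and RNAi-knockdown conditions modelled as a
multiplicative depletion of the piRNA classes plus transposon derepression
at the mRNA level.

The generative model is species-based: a fixed catalogue of distinct read
*species* (sequence + placement + origin) is drawn once per configuration,
and each condition replicate draws per-species copy counts from a Poisson
around the species' abundance, scaled by the condition's depletion factor
for piRNA species.  This makes every emitted read traceable to exactly one
planted origin and makes distinct-sequence (complexity) statistics follow
the planted fractions directly.

No aligner runs anywhere: the simulator emits ground-truth alignments
(BED dialect) against the genome, the transposon-consensus set, and the
transcript set, all of which load through :func:`pirnaflow.io_core.read_alignments`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io_core import AlignmentRecord, Library, SmallRNARead, revcomp, write_bed

__all__ = ["SimConfig", "GenomeSpec", "ClusterSpec", "TESpec", "ReadModel",
           "ConditionSpec", "SimTruth", "SimResult", "simulate"]

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    n_contigs: int = 3
    contig_length: int = 50_000


@dataclass
class ClusterSpec:
    n_clusters: int = 5
    cluster_length: int = 5_000
    bidirectional_fraction: float = 0.4
    # share of (non-TE) piRNA species planted inside clusters
    inside_fraction: float = 0.9


@dataclass
class TESpec:
    n_te: int = 8
    te_length_min: int = 1_000
    te_length_max: int = 2_500
    n_genomic_copies: int = 2
    # consecutive consensus pairs share a central block of this many nt,
    # creating controlled multi-mapping on the consensus set itself
    shared_block: int = 80
    # planted per-family expression; drawn lognormal when None
    expression: list[float] | None = None
    sense_fraction: float = 0.2


@dataclass
class ReadModel:
    total_reads: int = 50_000
    # weight of each length population; piRNA lengths spread over 28-32
    mode_weights: dict = field(
        default_factory=lambda: {20: 0.15, 22: 0.25, 30: 0.60}
    )
    pirna_length_probs: dict = field(
        default_factory=lambda: {28: 0.10, 29: 0.20, 30: 0.40, 31: 0.20, 32: 0.10}
    )
    u1_prob: float = 0.8  # probability of a U at piRNA position 1
    n_pirna_species: int = 3_000
    n_mirna: int = 25
    n_bg20_species: int = 300
    te_read_fraction: float = 0.25  # share of piRNA mass from TE consensus
    n_te_species: int = 600
    pingpong_fraction: float = 0.2  # share of cluster piRNA species that are
    # 10-nt-overlap responder reads


@dataclass
class ConditionSpec:
    name: str
    pirna_depletion: float = 1.0  # divide piRNA abundance by this factor
    te_derepression: float = 1.0  # multiply TE mRNA abundance by this factor
    n_replicates: int = 3


def _default_conditions() -> list[ConditionSpec]:
    return [
        ConditionSpec("luciferase", 1.0, 1.0, 3),
        ConditionSpec("macpiwi1_kd", 10.0, 4.0, 3),
        ConditionSpec("macvasa_kd", 10.0, 4.0, 3),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    clusters: ClusterSpec = field(default_factory=ClusterSpec)
    te: TESpec = field(default_factory=TESpec)
    reads: ReadModel = field(default_factory=ReadModel)
    conditions: list[ConditionSpec] = field(default_factory=_default_conditions)

    def validate(self) -> None:
        r = self.reads
        for p in (r.u1_prob, r.te_read_fraction, r.pingpong_fraction,
                  self.clusters.inside_fraction,
                  self.clusters.bidirectional_fraction,
                  self.te.sense_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if r.pingpong_fraction > 0.5:
            raise ValueError("pingpong_fraction > 0.5 not supported "
                             "(each responder needs a distinct driver)")
        if self.clusters.n_clusters > 0 and (
            self.clusters.cluster_length + 1000 > self.genome.contig_length
        ):
            raise ValueError("cluster interval exceeds contig bounds")
        for c in self.conditions:
            if c.pirna_depletion <= 0 or c.n_replicates < 1:
                raise ValueError(f"invalid condition {c.name}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        kw: dict = {}
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        for key, sub in (("genome", GenomeSpec), ("clusters", ClusterSpec),
                         ("te", TESpec), ("reads", ReadModel)):
            if key in d:
                kw[key] = sub(**d[key])
        if "conditions" in d:
            kw["conditions"] = [ConditionSpec(**c) for c in d["conditions"]]
        return cls(**kw)


@dataclass
class _Species:
    """One distinct read species: a sequence, its placements, its origin."""

    sid: int
    sequence: str
    origin: str  # "cluster:<i>" | "background" | "te:<id>" | "mirna:<id>" | "bg20"
    # placements on the genome / consensus set / transcript set
    genome: list[tuple[str, int, int, str]] = field(default_factory=list)
    te: list[tuple[str, int, int, str]] = field(default_factory=list)
    transcript: list[tuple[str, int, int, str]] = field(default_factory=list)
    abundance: float = 1.0  # expected copies per replicate, before depletion
    is_pirna: bool = False
    partner_of: int | None = None  # driver species id for ping-pong responders


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    clusters: list[dict]
    te_expression: dict[str, float]
    depletion: dict[str, float]
    derepression: dict[str, float]
    pingpong_fraction: float
    inside_fraction_planted: float
    inside_fraction_realized: float  # share of unique piRNA species in clusters
    mirna_ids: list[str]
    species_origins: dict[int, str]

    def as_json_dict(self) -> dict:
        d = asdict(self)
        d["species_origins"] = {str(k): v for k, v in d["species_origins"].items()}
        return d


class SimResult:
    """Everything the simulator produced, in memory, plus file writers."""

    def __init__(self, config: SimConfig, genome: dict[str, str],
                 te_seqs: dict[str, str], transcripts: dict[str, str],
                 transcript_placements: dict[str, tuple[str, int, int] | None],
                 mirna_ref: dict[str, str], species: list[_Species],
                 counts: dict[tuple[str, int], dict[int, int]],
                 mrna_counts: dict[str, dict[str, float]],
                 truth: SimTruth):
        self.config = config
        self.genome = genome
        self.te_seqs = te_seqs
        self.transcripts = transcripts
        self.transcript_placements = transcript_placements
        self.mirna_ref = mirna_ref
        self.species = species
        self._counts = counts
        self.mrna_counts = mrna_counts
        self.truth = truth
        self._by_sid = {sp.sid: sp for sp in species}

    # ---- library construction -------------------------------------------
    def replicates(self) -> list[tuple[str, int]]:
        return sorted(self._counts)

    def _build_library(self, condition: str, rep: int, which: str,
                       ref_lengths: dict[str, int],
                       total_mapped: int | None) -> Library:
        counts = self._counts[(condition, rep)]
        records = []
        for sid, k in counts.items():
            sp = self._by_sid[sid]
            placements = getattr(sp, which)
            read = None
            for ref_id, start, end, strand in placements:
                if read is None:
                    read = SmallRNARead(sp.sequence, k)
                records.append(AlignmentRecord(
                    read=read, ref_id=ref_id, start=start, end=end,
                    strand=strand))
        return Library(
            name=f"{condition}_rep{rep}", records=records, condition=condition,
            total_mapped=total_mapped, ref_lengths=dict(ref_lengths))

    def genome_library(self, condition: str, rep: int) -> Library:
        return self._build_library(
            condition, rep, "genome",
            {c: len(s) for c, s in self.genome.items()}, None)

    def te_library(self, condition: str, rep: int,
                   total_genome_mapped: int | None = None) -> Library:
        return self._build_library(
            condition, rep, "te", {t: len(s) for t, s in self.te_seqs.items()},
            total_genome_mapped)

    def transcript_library(self, condition: str, rep: int,
                           total_genome_mapped: int | None = None) -> Library:
        return self._build_library(
            condition, rep, "transcript",
            {t: len(s) for t, s in self.transcripts.items()},
            total_genome_mapped)

    def origin_of(self, sequence: str) -> str | None:
        for sp in self.species:
            if sp.sequence == sequence:
                return sp.origin
        return None

    # ---- output files ----------------------------------------------------
    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome_fasta"] = _write_fasta(outdir / "genome.fa", self.genome)
        paths["te_fasta"] = _write_fasta(outdir / "te_consensus.fa", self.te_seqs)
        paths["transcript_fasta"] = _write_fasta(
            outdir / "transcripts.fa", self.transcripts)
        paths["mirna_fasta"] = _write_fasta(
            outdir / "mirna_mature.fa", self.mirna_ref)
        for cond, rep in self.replicates():
            stem = f"{cond}_rep{rep}"
            for which, builder in (
                ("genome", self.genome_library),
                ("te", self.te_library),
                ("transcript", self.transcript_library),
            ):
                lib = builder(cond, rep)
                p = outdir / f"{stem}.{which}.bed"
                write_bed(lib, p)
                paths[f"{stem}.{which}"] = p
        truth_path = outdir / "truth.json"
        payload = {
            "truth": self.truth.as_json_dict(),
            "mrna_counts": self.mrna_counts,
            "transcript_placements": {
                t: list(v) if v is not None else None
                for t, v in self.transcript_placements.items()
            },
        }
        truth_path.write_text(json.dumps(payload, sort_keys=True, indent=1))
        paths["truth"] = truth_path
        return paths


def _write_fasta(path: Path, seqs: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")
    return path


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _force_first_base(seq: str, rng: np.random.Generator, u1_prob: float) -> str:
    """First base is U (stored T) with probability exactly ``u1_prob``."""
    first = "T" if rng.random() < u1_prob else "ACG"[rng.integers(0, 3)]
    return first + seq[1:]


class _Layout:
    """Non-overlapping placement of clusters, TE copies and miRNA loci."""

    def __init__(self, rng: np.random.Generator, genome: GenomeSpec):
        self.rng = rng
        self.contigs = [f"contig_{i + 1}" for i in range(genome.n_contigs)]
        self.length = genome.contig_length
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in self.contigs}

    def reserve(self, length: int, margin: int = 500,
                max_tries: int = 2000) -> tuple[str, int]:
        for _ in range(max_tries):
            contig = self.contigs[self.rng.integers(0, len(self.contigs))]
            if self.length - length - 2 * margin <= 0:
                raise ValueError("interval exceeds contig bounds")
            start = int(self.rng.integers(margin, self.length - length - margin))
            if all(start + length + margin <= s or start >= e + margin
                   for s, e in self.occupied[contig]):
                self.occupied[contig].append((start, start + length))
                return contig, start
        raise ValueError("could not place interval; genome too crowded")


def simulate(config: SimConfig) -> SimResult:
    """Generate genome, references, read libraries and planted truth.

    Deterministic: the same configuration (including its seed) yields
    byte-identical FASTA/BED/JSON outputs.
    """
    config.validate()
    root = np.random.SeedSequence([int(config.seed) % (2 ** 31), 20260929])
    (genome_ss, struct_ss, counts_ss, mrna_ss) = root.spawn(4)
    rng = np.random.default_rng(genome_ss)

    gspec, cspec, tspec, rspec = (config.genome, config.clusters,
                                  config.te, config.reads)
    layout = _Layout(rng, gspec)
    genome = {c: _random_seq(rng, gspec.contig_length) for c in layout.contigs}

    # --- transposon consensus set, with shared central blocks -------------
    te_ids = [f"TE_{i + 1:02d}" for i in range(tspec.n_te)]
    te_seqs: dict[str, str] = {}
    te_lengths = {}
    for i, tid in enumerate(te_ids):
        L = int(rng.integers(tspec.te_length_min, tspec.te_length_max + 1))
        te_lengths[tid] = L
        te_seqs[tid] = _random_seq(rng, L)
    shared: dict[str, tuple[str, int]] = {}  # tid -> (partner, block offset)
    if tspec.shared_block > 0:
        for i in range(1, tspec.n_te, 2):
            a, b = te_ids[i - 1], te_ids[i]
            block = tspec.shared_block
            off = min(te_lengths[a], te_lengths[b]) // 2 - block // 2
            seq_a = te_seqs[a]
            te_seqs[b] = (te_seqs[b][:off] + seq_a[off:off + block]
                          + te_seqs[b][off + block:])
            shared[a] = (b, off)
            shared[b] = (a, off)

    # insert TE copies into the genome at reserved, recorded positions
    te_copies: dict[str, list[tuple[str, int]]] = {t: [] for t in te_ids}
    for tid in te_ids:
        for _ in range(tspec.n_genomic_copies):
            contig, start = layout.reserve(te_lengths[tid])
            genome[contig] = (genome[contig][:start] + te_seqs[tid]
                              + genome[contig][start + te_lengths[tid]:])
            te_copies[tid].append((contig, start))

    # --- planted clusters --------------------------------------------------
    rng_struct = np.random.default_rng(struct_ss)
    clusters: list[dict] = []
    for i in range(cspec.n_clusters):
        contig, start = layout.reserve(cspec.cluster_length, margin=1500)
        bidir = rng_struct.random() < cspec.bidirectional_fraction
        strand = "." if bidir else ("+-"[rng_struct.integers(0, 2)])
        clusters.append({
            "cluster_id": f"cluster_{i + 1}",
            "ref_id": contig, "start": start,
            "end": start + cspec.cluster_length,
            "directionality": "bidirectional" if bidir else "unidirectional",
            "strand": strand,
        })

    te_expression = tspec.expression
    if te_expression is None:
        if tspec.n_te == 0:
            te_expression = []
        else:
            te_expression = np.exp(rng_struct.normal(0.0, 1.0, size=tspec.n_te))
            te_expression = list(te_expression / np.sum(te_expression))
    if len(te_expression) != tspec.n_te:
        raise ValueError("expression vector length != n_te")
    te_expr = {t: float(e) for t, e in zip(te_ids, te_expression)}

    species: list[_Species] = []
    used_seqs: set[str] = set()
    sid = 0

    def add(sp: _Species) -> int:
        nonlocal sid
        sp.sid = sid
        species.append(sp)
        used_seqs.add(sp.sequence)
        sid += 1
        return sp.sid

    def pirna_length() -> int:
        ls = sorted(rspec.pirna_length_probs)
        ps = np.array([rspec.pirna_length_probs[L] for L in ls], dtype=float)
        return int(rng_struct.choice(ls, p=ps / ps.sum()))

    def genome_read(contig: str, fp: int, L: int, strand: str,
                    force_u1: bool) -> tuple[str, int, int] | None:
        """Sequence + interval of a read with 5' end at ``fp``; None if OOB."""
        if strand == "+":
            start, end = fp, fp + L
        else:
            start, end = fp - L + 1, fp + 1
        if start < 0 or end > len(genome[contig]):
            return None
        sub = genome[contig][start:end]
        seq = sub if strand == "+" else revcomp(sub)
        if force_u1:
            seq = _force_first_base(seq, rng_struct, rspec.u1_prob)
        return seq, start, end

    # --- cluster + background piRNA species --------------------------------
    n_cluster_sp = int(round(rspec.n_pirna_species * cspec.inside_fraction))
    n_partner = int(round(n_cluster_sp * rspec.pingpong_fraction))
    n_driver = n_cluster_sp - n_partner
    n_bg = rspec.n_pirna_species - n_cluster_sp

    drivers: list[int] = []
    for _ in range(n_driver):
        for _try in range(200):
            cl = clusters[rng_struct.integers(0, len(clusters))]
            if cl["directionality"] == "bidirectional":
                strand = "+-"[rng_struct.integers(0, 2)]
            else:
                strand = cl["strand"]
            L = pirna_length()
            lo = cl["start"] + (L - 1 if strand == "-" else 0)
            hi = cl["end"] - (L if strand == "+" else 1)
            if hi <= lo:
                continue
            fp = int(rng_struct.integers(lo, hi))
            got = genome_read(cl["ref_id"], fp, L, strand, True)
            if got is None or got[0] in used_seqs:
                continue
            seq, start, end = got
            s = _Species(0, seq, f"cluster:{cl['cluster_id']}",
                         genome=[(cl["ref_id"], start, end, strand)],
                         is_pirna=True)
            drivers.append(add(s))
            break
        else:
            raise RuntimeError("failed to place cluster piRNA species")

    # ping-pong responders: minus-strand partner with 5' end at driver 5' + 9
    if n_partner > len(drivers):
        raise ValueError("pingpong_fraction too high for driver count")
    partner_drivers = list(
        rng_struct.choice(np.array(drivers), size=n_partner, replace=False))
    for d_sid in partner_drivers:
        drv = species[int(d_sid)]
        contig, dstart, dend, dstrand = drv.genome[0]
        d_fp = dstart if dstrand == "+" else dend - 1
        p_strand = "-" if dstrand == "+" else "+"
        p_fp = d_fp + 9 if dstrand == "+" else d_fp - 9
        for _try in range(50):
            L = pirna_length()
            got = genome_read(contig, p_fp, L, p_strand, True)
            if got is None or got[0] in used_seqs:
                continue
            seq, start, end = got
            add(_Species(0, seq, drv.origin,
                         genome=[(contig, start, end, p_strand)],
                         is_pirna=True, partner_of=int(d_sid)))
            break

    def in_occupied_te(contig: str, start: int, end: int) -> bool:
        for tid, copies in te_copies.items():
            for c, s in copies:
                if c == contig and start < s + te_lengths[tid] and end > s:
                    return True
        return False

    for _ in range(n_bg):
        for _try in range(200):
            contig = layout.contigs[rng_struct.integers(0, len(layout.contigs))]
            strand = "+-"[rng_struct.integers(0, 2)]
            L = pirna_length()
            fp = int(rng_struct.integers(L, gspec.contig_length - L))
            got = genome_read(contig, fp, L, strand, True)
            if got is None or got[0] in used_seqs:
                continue
            seq, start, end = got
            if in_occupied_te(contig, start, end):
                continue
            add(_Species(0, seq, "background",
                         genome=[(contig, start, end, strand)], is_pirna=True))
            break
        else:
            raise RuntimeError("failed to place background piRNA species")

    # --- TE-derived piRNA species ------------------------------------------
    te_probs = np.array([te_expr[t] * te_lengths[t] for t in te_ids])
    if te_probs.size:
        te_probs = te_probs / te_probs.sum()
    for _ in range(rspec.n_te_species if tspec.n_te else 0):
        for _try in range(200):
            tid = te_ids[int(rng_struct.choice(tspec.n_te, p=te_probs))]
            L = pirna_length()
            off = int(rng_struct.integers(0, te_lengths[tid] - L))
            strand = "+" if rng_struct.random() < tspec.sense_fraction else "-"
            sub = te_seqs[tid][off:off + L]
            seq = sub if strand == "+" else revcomp(sub)
            seq = _force_first_base(seq, rng_struct, rspec.u1_prob)
            if seq in used_seqs:
                continue
            te_pl = [(tid, off, off + L, strand)]
            if tid in shared:
                partner, boff = shared[tid]
                if boff <= off and off + L <= boff + tspec.shared_block:
                    te_pl.append((partner, off, off + L, strand))
            genome_pl = []
            for t2, o2, e2, s2 in te_pl:
                for contig, gstart in te_copies[t2]:
                    genome_pl.append((contig, gstart + o2, gstart + e2, s2))
            sp = _Species(0, seq, f"te:{tid}", genome=genome_pl, te=te_pl,
                          is_pirna=True)
            add(sp)
            break
        else:
            raise RuntimeError("failed to place TE piRNA species")

    # --- miRNA species (exact copies of planted mature sequences) ----------
    mirna_ref: dict[str, str] = {}
    for i in range(rspec.n_mirna):
        mid = f"mli-mir-{i + 1:03d}"
        for _try in range(200):
            contig = layout.contigs[rng_struct.integers(0, len(layout.contigs))]
            strand = "+-"[rng_struct.integers(0, 2)]
            fp = int(rng_struct.integers(22, gspec.contig_length - 22))
            got = genome_read(contig, fp, 22, strand, False)
            if got is None or got[0] in used_seqs:
                continue
            seq, start, end = got
            if in_occupied_te(contig, start, end):
                continue
            mirna_ref[mid] = seq
            add(_Species(0, seq, f"mirna:{mid}",
                         genome=[(contig, start, end, strand)]))
            break
        else:
            raise RuntimeError("failed to place miRNA locus")

    # --- 20-nt background species ------------------------------------------
    for _ in range(rspec.n_bg20_species):
        for _try in range(200):
            contig = layout.contigs[rng_struct.integers(0, len(layout.contigs))]
            strand = "+-"[rng_struct.integers(0, 2)]
            fp = int(rng_struct.integers(20, gspec.contig_length - 20))
            got = genome_read(contig, fp, 20, strand, False)
            if got is None or got[0] in used_seqs:
                continue
            seq, start, end = got
            if in_occupied_te(contig, start, end):
                continue
            add(_Species(0, seq, "bg20",
                         genome=[(contig, start, end, strand)]))
            break
        else:
            raise RuntimeError("failed to place 20-nt background species")

    # --- per-species expected abundance ------------------------------------
    w = rspec.mode_weights
    total_w = sum(w.values())
    class_mass = {
        "pirna_genomic": rspec.total_reads * w.get(30, 0) / total_w
        * (1 - rspec.te_read_fraction),
        "pirna_te": rspec.total_reads * w.get(30, 0) / total_w
        * rspec.te_read_fraction,
        "mirna": rspec.total_reads * w.get(22, 0) / total_w,
        "bg20": rspec.total_reads * w.get(20, 0) / total_w,
    }

    def klass(sp: _Species) -> str:
        if sp.origin.startswith("te:"):
            return "pirna_te"
        if sp.is_pirna:
            return "pirna_genomic"
        if sp.origin.startswith("mirna:"):
            return "mirna"
        return "bg20"

    raw = {sp.sid: float(np.exp(rng_struct.normal(0.0, 1.0))) for sp in species}
    sums = {k: 0.0 for k in class_mass}
    for sp in species:
        sums[klass(sp)] += raw[sp.sid]
    for sp in species:
        k = klass(sp)
        sp.abundance = raw[sp.sid] / sums[k] * class_mass[k] if sums[k] else 0.0

    # --- transcript set -----------------------------------------------------
    transcripts: dict[str, str] = {}
    transcript_placements: dict[str, tuple[str, int, int] | None] = {}
    for cl in clusters:
        tseq = genome[cl["ref_id"]][cl["start"]:cl["end"]]
        transcripts[cl["cluster_id"]] = tseq
        transcript_placements[cl["cluster_id"]] = (
            cl["ref_id"], cl["start"], cl["end"])
    for tid in te_ids:
        transcripts[tid] = te_seqs[tid]
        contig, gstart = te_copies[tid][0]
        transcript_placements[tid] = (contig, gstart, gstart + te_lengths[tid])
    rng_decoy = np.random.default_rng(struct_ss.spawn(1)[0])
    for i in range(20):
        name = f"decoy_{i + 1:02d}"
        transcripts[name] = _random_seq(rng_decoy, 800)
        transcript_placements[name] = None

    # transcript placements of species: cluster reads project onto their
    # cluster transcript; TE reads onto the consensus "transcript"
    cl_by_id = {c["cluster_id"]: c for c in clusters}
    for sp in species:
        if sp.origin.startswith("cluster:"):
            cl = cl_by_id[sp.origin.split(":", 1)[1]]
            contig, start, end, strand = sp.genome[0]
            if cl["start"] <= start and end <= cl["end"]:
                sp.transcript.append(
                    (cl["cluster_id"], start - cl["start"],
                     end - cl["start"], strand))
        elif sp.origin.startswith("te:"):
            sp.transcript = list(sp.te)

    # --- per-replicate copy counts ------------------------------------------
    counts: dict[tuple[str, int], dict[int, int]] = {}
    cond_ss = counts_ss.spawn(len(config.conditions))
    for cond, css in zip(config.conditions, cond_ss):
        rep_ss = css.spawn(cond.n_replicates)
        for rep, rss in enumerate(rep_ss, 1):
            rrng = np.random.default_rng(rss)
            lam = np.array([
                sp.abundance / (cond.pirna_depletion if sp.is_pirna else 1.0)
                for sp in species])
            draw = rrng.poisson(lam)
            counts[(cond.name, rep)] = {
                sp.sid: int(k) for sp, k in zip(species, draw) if k > 0}

    # --- mRNA-level counts (for fold-change comparisons) --------------------
    mrng = np.random.default_rng(mrna_ss)
    gene_ids = [f"gene_{i + 1:03d}" for i in range(50)]
    base = {t: 200.0 * te_expr[t] * tspec.n_te for t in te_ids}
    base.update({g: float(np.exp(mrng.normal(4.0, 0.8))) for g in gene_ids})
    mrna_counts: dict[str, dict[str, float]] = {}
    for cond in config.conditions:
        for rep in range(1, cond.n_replicates + 1):
            key = f"{cond.name}_rep{rep}"
            mrna_counts[key] = {
                f: float(mrng.poisson(
                    base[f] * (cond.te_derepression if f in te_expr else 1.0)))
                for f in sorted(base)}

    # --- truth ---------------------------------------------------------------
    uniq_pirna = [sp for sp in species if sp.is_pirna
                  and len(sp.genome) == 1 and not sp.origin.startswith("te:")]

    def _in_planted(sp: _Species) -> bool:
        contig, start, end, strand = sp.genome[0]
        fp = start if strand == "+" else end - 1
        return any(c["ref_id"] == contig and c["start"] <= fp < c["end"]
                   for c in clusters)

    # realized fraction is geometric: background species falling inside a
    # planted interval count as inside, exactly as a caller would see them
    n_inside = sum(1 for sp in uniq_pirna if _in_planted(sp))
    truth = SimTruth(
        clusters=clusters,
        te_expression=te_expr,
        depletion={c.name: c.pirna_depletion for c in config.conditions},
        derepression={c.name: c.te_derepression for c in config.conditions},
        pingpong_fraction=rspec.pingpong_fraction,
        inside_fraction_planted=cspec.inside_fraction,
        inside_fraction_realized=(n_inside / len(uniq_pirna))
        if uniq_pirna else 0.0,
        mirna_ids=sorted(mirna_ref),
        species_origins={sp.sid: sp.origin for sp in species},
    )
    return SimResult(config, genome, te_seqs, transcripts,
                     transcript_placements, mirna_ref, species, counts,
                     mrna_counts, truth)
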