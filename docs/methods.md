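# Methods

This note documents the models and procedures pirnaflow implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Data model

All analyses run on one representation: a `Library` of alignment records,
each placing a collapsed read (distinct sequence + copy count) on a
reference. Coordinates are 0-based half-open; the 5′ end of a plus-strand
record is `start`, of a minus-strand record `end − 1`. Sequences are held
in the DNA alphabet (U↔T interconverted at the boundaries). Placement
multiplicity `n_hits` is always recomputed over the loaded record set for
the reference collection under analysis — a read unique on the genome can
be a multi-mapper on a transposon-consensus set — and "uniquely mapping"
means `n_hits == 1` on that set. Mismatch counts are carried as metadata
only; no mismatch-based filtering is applied.

## Profiling

The size profile reports, per read length, copy-weighted abundance and
distinct-sequence complexity, both as reads per million total
genome-mapped reads (RPM). The RPM denominator of a filtered library stays
the parent library's total, so curves from different length windows share a
scale; summed over all lengths the abundance curve is exactly 10⁶ RPM.
Positional nucleotide bias is 5′-anchored over positions 1..P (P defaults
to the shortest length considered so every row is fully populated) and by
default counts each distinct sequence once, matching how sequence logos
are usually built from collapsed sets; copy-weighted frequencies are
available. miRNA annotation demands full-length, 100 %-identity string
equality to a mature reference sequence and at least 1 RPM; ties between
identically-sequenced reference entries are broken lexicographically and
reported.

## Cluster discovery

Distinct uniquely-mapping 28–32-nt sequences are assigned to 1-kb windows
tiled every 968 nt by 5′-end containment — unambiguous single assignment;
the 32-nt overlap between consecutive windows equals the longest read, so
no read can evade every window boundary. Windows holding at least 10
sequences are merged when they overlap or abut, and merged bounds are
trimmed to the outermost supporting reads (a `trim=False` option reports
raw window unions). Counting distinct sequences rather than copies makes
the threshold a complexity criterion, robust to PCR jackpots.
Directionality: bidirectional iff the minor strand holds at least 25 % of
supporting reads (parameter `bidir_min_frac`; no community standard
exists, and the classification is monotone in the threshold). Transcripts
overlap the cluster catalogue when ≥ 50 % of the transcript interval is
covered (`min_overlap_frac`).

Properties verified in the suite: equality with an explicit
window-enumeration oracle, per-contig disjointness, and — against the
intuitive expectation — *non*-monotonicity of cluster count in
`min_reads`: lowering the threshold can merge neighbours, so raising it
can split one cluster into several. The true monotone invariants are total
covered length and nesting of stricter clusters inside looser ones, and
those are what the tests assert.

## Ping-pong signature

For every (+,−) record pair on one contig the 5′-overlap is
o = 5′₋ − 5′₊ + 1; pairs contribute to 1 ≤ o ≤ 30 with weight
c₊c₋/(h₊h₋) by default (copy-count product over placement multiplicities;
`min` and `unit` weights are options). The signature statistic is
z₁₀ = (s(10) − mean)/sd over the background overlap set {1..9, 11..20},
with the sample (ddof = 1) standard deviation. Degenerate cases: an empty
selection or an all-equal background with s(10) off that level leaves z₁₀
undefined with a recorded reason; an entirely flat histogram is reported
as z₁₀ = 0 (no enrichment).

**Null calibration.** Under a pair-free null, s(10) is exchangeable with
the 19 background scores, so z₁₀ is not standard normal but scaled-t:
approximately √(1+1/19)·t₁₈ when scores are near-normal. Its |z₁₀| < 2
coverage is therefore ≈ 93 %, not the 95.4 % a N(0,1) would give — we
measure 93–94/100 across seeds and weight schemes. A z₁₀ threshold of 2
on a single library should accordingly be read as suggestive, not as a
5 %-level test; planted signals at 30 % pairing produce z₁₀ > 12 in every
replicate, far from this ambiguity.

## Transposon quantification and comparison

Each placement of a read on the consensus set contributes
copy_count/n_hits, so one read distributes exactly one copy-weighted unit
across its placements and the per-family weighted counts sum exactly to
the aligned total (asserted, not approximated). Expression is normalised
by consensus length (kb) and total genome-mapped reads (millions) —
RPKM-like; strand bias is the weighted sense fraction, masked below 10
weighted counts. Transcripts qualify as piRNA-producing at ≥ 100 RPKM or
≥ 100 RPM of 28–32-nt reads (OR rule; "parts per million" treated as RPM).
Condition comparison is a deliberately simple pseudocount fold change,
log₂((mean_t+ε)/(mean_c+ε)) with ε = 0.5, applied to piRNA counts and
simulated mRNA counts; features are called decreased at log₂FC ≤ −1.
Posterior differential-expression modelling is out of scope by design.

## Synthetic data

The generator is species-based: it first draws a catalogue of distinct
read species — sequence, placements, origin — and then, per condition
replicate, Poisson copy counts around per-species abundances (log-normal
weights, σ = 1). This two-stage design makes complexity statistics follow
the planted fractions directly and every emitted read traceable to exactly
one origin. Defaults emulate the study conditions: three length
populations (20 nt background, 22 nt miRNA, 28–32 nt piRNA centred on
30 nt; weights 0.15/0.25/0.60), 5′-U probability 0.8 (position 1 is U with
exactly that probability, else uniform on A/C/G), five kb-scale clusters
holding 90 % of genomic piRNA species at ~10× background density, 25 % of
piRNA mass from eight transposon families (sense fraction 0.2 —
antisense-dominant), ping-pong responders for 20 % of cluster species
placed at exactly minus-5′ = plus-5′ + 9, and three conditions mirroring a
control and two knockdowns (10× piRNA depletion, 4× TE mRNA derepression,
three replicates each).

Multi-mapping is constructed, not emergent: every TE family is copied to
two recorded genomic positions, and consecutive consensus pairs share an
80-nt central block, so placement counts are known analytically. Knockdown
depletion divides expected piRNA counts before sampling — the library
shrinks rather than re-normalising, the spike-in-normalised view — so raw
weighted counts recover the planted factor as log₂FC ≈ −3.32 directly.
The planted "inside fraction" recorded in the truth is the realized
geometric fraction of unique piRNA species whose 5′ end lies in a planted
interval (background species that land inside count), since that is the
quantity a caller can recover.

Not modelled: adapter/ligation bias, PCR duplication, sequencing error,
real repeat taxonomy or sequence divergence, isomiR variation, and
alignment itself (ground-truth placements are emitted; an aligner would
add mismatch-tolerance effects the simulator bypasses). Tests passing on
these simulations therefore demonstrate algorithmic correctness and
statistical recovery under the planted model, not robustness to those
artefacts.

## Problem sizes and determinism

The recovery studies use desk-scale problems chosen to keep per-window
expected counts in the regime the methods target: cluster recovery uses
5 × 10-kb clusters on a 2 × 100-kb genome at 10× background density
(26 vs 2.6 species/kb — the 10-kb scale matches the kb-scale loci the
caller is meant for and keeps window-threshold edge effects small relative
to cluster mass), ping-pong calibration 100 seeds × 20 k reads, and
quantification checks 10⁵ reads. At exactly 10× density with a 10-read
window threshold, both Poisson tails (a cluster window below threshold → a
split; a background window above it → a merged extension) are small but
not zero, so occasional boundary excursions beyond one window size are
expected over large replicate batches; the acceptance script reports the
maximum observed.

All randomness flows from numpy `SeedSequence` spawning, so one seed fixes
every output byte: FASTA/BED/JSON from the simulator and the pipeline's
`report.json` (which logs parameters and SHA-256 checksums of all inputs)
are reproducible exactly. The pipeline's report schema ships in
`src/pirnaflow/schemas/report.schema.json` and is validated in the tests.
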