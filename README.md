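# pirnaflow

A small-RNA sequencing analysis toolkit for piRNA biology in non-model
animals, built around the analyses used to characterise the piRNA pathway of
flatworm stem cells: size/complexity profiling, 5′-nucleotide bias, miRNA
annotation, sliding-window piRNA-cluster discovery, the ping-pong
5′-overlap signature, multi-mapper-aware transposon quantification, and
knockdown-vs-control comparison. A first-class synthetic-data generator
plants ground truth for every one of these stages, so the whole pipeline is
testable end to end without any sequencing data or aligner.

It is aimed at computational biologists who already have small-RNA
alignments (SAM/BAM, or the simulator's BED dialect) against a genome
draft, a transcript set and/or a transposon-consensus set, and want the
standard desk-scale piRNA analyses as a reusable, tested Python library.

## Methods at a glance

* **Collapsing and profiling.** Reads are collapsed to distinct sequences
  with copy counts. For each length *L*, abundance is
  Σ copies × 10⁶ / N (RPM, N = total genome-mapped reads) and complexity is
  the count of distinct sequences × 10⁶ / N.
* **Cluster calling.** Distinct, uniquely-mapping 28–32-nt sequences are
  counted by 5′ end in 1-kb windows tiled every 968 nt; windows with ≥ 10
  reads are merged (union of overlapping/abutting windows) and trimmed to
  the outermost supporting reads. Clusters are bidirectional when the minor
  strand holds ≥ 25 % of reads.
* **Ping-pong.** A (+,−) pair on one contig contributes to overlap
  *o* = 5′₋ − 5′₊ + 1 with weight c₊c₋ / (h₊h₋) (copy counts over placement
  multiplicities). The signature statistic is
  z₁₀ = (s(10) − mean(s(bg))) / sd(s(bg)) over background overlaps
  bg = {1..9, 11..20}.
* **Transposon quantification.** Each placement counts copy/n_hits; per
  consensus, expression = weighted count / (length_kb × N/10⁶) (RPKM-like),
  with a weighted sense fraction for strand-bias heatmaps. Transcripts with
  ≥ 100 RPKM **or** ≥ 100 RPM of 28–32-nt reads qualify as piRNA-producing.
* **Condition comparison.** Per feature,
  log₂FC = log₂((mean_kd + ε) / (mean_ctrl + ε)), ε = 0.5.
* **Simulation.** A species-based generative model: distinct read species
  (20-nt background, 22-nt miRNA, 28–32-nt piRNA with a planted 5′-U
  probability) are placed in planted clusters, transposon families with
  duplicated genomic copies, or background; per-replicate copy counts are
  Poisson draws, with knockdowns as multiplicative piRNA depletion.

## Worked example

```python
from pirnaflow import call_clusters, summarize_clusters, overlap_histogram
from pirnaflow.simulate import SimConfig, simulate

result = simulate(SimConfig(seed=7))           # planted-truth dataset
library = result.genome_library("luciferase", 1)

clusters = call_clusters(library, window_size=1000, step=968, min_reads=10)
summary = summarize_clusters(clusters, library)
hist = overlap_histogram(library, lo=28, hi=32)
```

Running `python examples/03_call_clusters.py` prints:

```
called clusters:
  contig_1:3327-8627  reads=534  (+426/-108)  unidirectional
  contig_1:36079-41227  reads=512  (+100/-412)  unidirectional
  contig_2:5821-11426  reads=530  (+274/-256)  bidirectional
  contig_2:13066-18111  reads=490  (+100/-390)  unidirectional
  contig_3:39008-44249  reads=510  (+105/-405)  unidirectional

planted: 5, called: 5
median length      : 5241 nt
genome fraction    : 0.1756
unique piRNAs in clusters: 0.926 (planted truth 0.923)
```

All five planted clusters are recovered with their strand structure; 92.6 %
of uniquely-mapping piRNA sequences fall inside called clusters, matching
the planted 92.3 %. `examples/04_pingpong_signature.py` on the same dataset
reports a 10-nt overlap peak with z₁₀ = 27.3 in the control library and a
depleted pair count after the simulated PIWI knockdown; the other examples
cover profiling, transposon quantification (Pearson r = 0.992 against
planted expression) and fold-change recovery (−3.36 observed for a planted
10× depletion, −3.32 expected).

A thin CLI mirrors the library: `pirnaflow simulate`, `pirnaflow run
--config run.yaml`, and per-stage subcommands (`profile`, `clusters`,
`pingpong`, `tequant`, `io validate`, `io collapse`).

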