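"""Generate a synthetic small-RNA dataset with planted ground truth.

Builds a toy genome with planted piRNA clusters, transposon consensus
families with genomic copies, miRNA loci, and control/knockdown read
libraries, then writes everything (FASTA/BED/JSON) to ./scratch_sim.
"""

from pirnaflow.simulate import SimConfig, simulate

config = SimConfig(seed=7)
result = simulate(config)
paths = result.write("scratch_sim")

print(f"contigs           : {len(result.genome)} "
      f"x {config.genome.contig_length / 1000:.0f} kb")
print(f"planted clusters  : {len(result.truth.clusters)} "
      f"({sum(1 for c in result.truth.clusters if c['directionality'] == 'bidirectional')} bidirectional)")
print(f"TE consensus set  : {len(result.te_seqs)} families, "
      f"{config.te.n_genomic_copies} genomic copies each")
print(f"read species      : {len(result.species)} distinct sequences")
print(f"conditions        : "
      + ", ".join(f"{c.name} (x{c.pirna_depletion:g} piRNA depletion)"
                  for c in config.conditions))
print(f"files written     : {len(paths)} (genome.fa, *.bed, truth.json ...)")
# Every emitted read records its true origin (cluster, TE family, miRNA or
# background), so downstream analyses can be scored against planted truth.
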