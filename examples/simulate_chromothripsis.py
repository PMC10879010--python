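"""Simulate a chromothriptic diploid chromosome and inspect its truth labels.

Builds a 1-Mb diploid chromosome with phased het SNPs, shatters hap1 into
~100 fragments with 40% loss, and prints the hallmarks that define
chromothripsis: oscillating copy number, junctions in all four orientations,
and alternating retained/lost heterozygosity.
"""

from collections import Counter

import chromoshard as cs

genome = cs.build_diploid_genome(n_chrom=1, length=1_000_000, snp_rate=1e-3, seed=1)
rec = genome.chromosomes[0]
print(f"chromosome {rec.name}: {rec.length:,} bp, "
      f"{len(rec.snps)} het SNPs in {len(rec.phase_blocks)} phase blocks")

derivative, truth = cs.apply_chromothripsis(
    genome, rec.name, "hap1", region=(0, rec.length),
    n_breakpoints=100, loss_prob=0.4, seed=1,
)

print(f"derivative haplotype: {len(derivative):,} bp "
      f"({len(truth.fragments)} fragments re-ligated, "
      f"{len(truth.lost)} fragments lost)")
print("junction orientation classes:",
      dict(Counter(b.sv_class for b in truth.breakends)))
print("copy-number states in the shattered region:",
      sorted(int(c) for c in truth.cn_segments["cn"].unique()),
      "(CN 1 = LOH: the derivative copy was lost there)")
print(f"LOH tracts: {len(truth.loh_tracts)}, "
      f"total {sum(e - s for s, e in truth.loh_tracts):,} bp")
# All four orientation classes and a 2-state oscillating CN profile are the
# textbook chromothripsis signature the downstream machinery relies on.
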