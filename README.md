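# chromoshard

Haplotype resolution of chromothriptic cancer chromosomes: phase-block
assignment, dual-assembly read arbitration, allele-specific feature
statistics and TAD comparison — with a truth-labelled chromothripsis
simulator so every stage can be scored exactly.

## The problem

Chromothripsis shatters a localized region of **one** parental chromosome
into tens to hundreds of fragments that re-ligate in near-random order and
orientation, leaving the homologous copy largely intact.  If reads can be
split by parental origin, the wild-type homolog becomes an internal control
for everything chromothripsis might reorganise on the derivative copy:
chromatin accessibility, histone marks, transcription and 3-D conformation.
`chromoshard` is for computational biologists building or evaluating that
kind of allele-specific analysis: it implements the resolution machinery and
a simulator that emulates the study design (oscillating copy number,
clustered junctions in all four orientations, alternating retained and lost
heterozygosity) with complete ground truth.

## The models at the core

**Phase-block assignment.**  Each phase block of het SNPs is labelled by
where its allele A lies, with evidence precedence *sv > loh > vaf-depth >
random*: junction-supporting reads are derivative-certified, so their
observed alleles orient the blocks they cover; at SNPs inside a
loss-of-heterozygosity tract the surviving allele is the wild-type one; and
under asymmetric copy number (cn_d : cn_w) the allele-A variant allele
fraction is binomial around cn_d/(cn_d+cn_w) if A is on the derivative,
giving the per-block log-likelihood ratio

    LLR = sum_i [ k_i log(p_D/p_W) + (n_i - k_i) log((1-p_D)/(1-p_W)) ]

decided at |LLR| >= 2.  Blocks with no informative evidence get a seeded,
reproducible random label — exactly what an honest pipeline must do.

**Read arbitration.**  Functional reads aligned to both haplotype
assemblies are resolved by *snp > loh > mapq > distance > random*.  Hi-C
pairs use a weighted-probability contact-distance model: log-binned
empirical separation frequencies with add-one smoothing and a power-law
tail (density ~ d^-alpha), the pair going to the assembly with the higher
likelihood of its mate separation when the log-likelihood ratio clears 1.

**Allele-specific statistics.**  Per-feature imbalance is a two-sided exact
binomial test of derivative vs total counts (CN-adjustable null) with
Benjamini–Hochberg control at q < 0.05; differential features are explained
by a cascade — dosage (CN/LOH imbalance), direct disruption (breakend
inside the feature), else unexplained — whose categories partition the
differential set.  TAD boundaries are prominent local minima of the
insulation score (diamond contact sums, mean-normalised) at a ladder of
resolutions from 150 kb to 1 Mb.

## Worked example

```python
from chromoshard import workflows

study = workflows.simulate_study(seed=1)        # 1-Mb diploid chromosome,
result = workflows.recover_haplotypes(study,    # 100 breakpoints, 40% loss
                                      seed=1)
print(result.basis_counts)
print(f"block accuracy {100*result.block_accuracy:.1f}%  "
      f"read accuracy {100*result.read_accuracy:.1f}%")
```

prints

```
{'sv': 37, 'loh': 9, 'random': 1}
block accuracy 100.0%  read accuracy 100.0%
```

meaning: of 47 phase blocks, 37 were oriented by validated SV junctions, 9
by LOH content, and one block without informative evidence fell back to the
seeded coin flip; every evidence-based block label and every SNP-covering
long read matched the simulator's truth.  The `examples/` directory has one
short script per capability (simulation, block assignment, functional read
resolution, allele-specific statistics, assembly evaluation, TAD
comparison); each prints the numbers it computes and what they mean.  A thin
CLI (`chromoshard simulate|assign-blocks|eval|resolve|allele-stats|tads`)
exposes the same workflows on files.

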