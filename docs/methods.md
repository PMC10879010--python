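# Methods

`chromoshard` implements the haplotype-resolution machinery needed to study
allele-specific regulation on chromothriptic cancer chromosomes, together
with a fully truth-labelled simulator that stands in for the sequencing data
such studies require.  This note records the models, the defaults and the
design decisions, and what the simulator does and does not emulate.

## The problem and the overall design

Chromothripsis shatters a localized region of one parental chromosome into
tens to hundreds of fragments that re-ligate in near-random order and
orientation.  The homologous chromosome is usually left intact, so if reads
can be split by parental origin, the wild-type copy becomes an internal
control for chromatin accessibility, histone modification, transcription and
3-D conformation on the derivative copy.  The package covers the five stages
of that comparison:

1. **simulate** — a diploid toy chromosome with phased het SNPs, a
   chromothriptic haplotype with complete rearrangement truth, long reads,
   Hi-C contact pairs, and per-haplotype feature counts with planted effects;
2. **phase-block assignment** — validating SV junctions against split
   long-read alignments and labelling each phase block of het SNPs as
   derivative or wild-type from SV, LOH and VAF/depth evidence;
3. **assembly evaluation** — N90/L90 contiguity, k-mer segment maps (the
   data behind a dot plot), liftover and reconstruction scoring against
   truth;
4. **functional read arbitration** — assigning ChIP/ATAC/transcript reads
   and Hi-C pairs between the two haplotype assemblies;
5. **allele-specific statistics** — imbalance testing, the mechanism
   cascade, breakend-distance and peak-class-distance comparisons, fusion
   transcripts, and TAD boundary/size comparison.

Coordinates are 0-based half-open throughout; orientations are `+`/`-`;
breakends are `(position, side)` with `side` naming the side of the
breakpoint on which the retained sequence lies.

## The simulator

`build_diploid_genome` draws a uniform-random ACGT sequence, places het SNPs
as i.i.d. Bernoulli(snp_rate) per bp (default study rate 1e-3; the two
haplotypes differ only at SNPs), and partitions the chromosome into phase
blocks with exponential lengths.  Each block's A/B labelling is flipped at
random, as real read-based phasing orients every block arbitrarily; blocks
are sets of SNPs, so intervals containing no SNP are not blocks.  The block
length default (mean 20 kb) is scaled to the toy chromosome the same way the
junction density is: a ~170-Mb chromothriptic chromosome carrying ~900
junctions and Mb-scale phase blocks maps onto a 1-Mb toy with 100 junctions
and ~20-kb blocks, keeping the blocks-per-junction geometry realistic.

`apply_chromothripsis` cuts the target region at `n_breakpoints` uniform
positions, loses each fragment i.i.d. with `loss_prob`, shuffles the
survivors, reverse-complements each with probability 1/2, and concatenates
in place.  The placement model is deliberately the simplest one satisfying
the defining criteria (oscillating 2-state copy number, clustered junctions
in all four orientations, alternating retained/lost heterozygosity); the
fragment-size distribution of real chromothripsis is not known, and the
uniform model is a stand-in, not an inference.  The emitted truth carries
the ordered oriented fragment walk, the breakend list with orientation
classes, the CN step function (wild-type copies plus derivative
multiplicity; {1,2} for pure chromothripsis, 3 only where a duplication
doubles the derivative copy), and the LOH tracts (merged lost fragments).
`colinear_walk()` merges reference-adjacent same-strand fragments — a
shuffled fragment that lands back beside its neighbour creates no junction,
and aligners see one segment there.

Long reads have gamma-distributed lengths (mean 12 kb, matching a
size-selected long-read library), are drawn from molecules proportionally to
weight x length (weight = copy number or subclonal fraction), and receive
i.i.d. substitution errors only.  Indels are omitted on purpose: the
arbitration logic keys on SNP identities and junction adjacency, neither of
which an indel model would exercise at this scale.  Hi-C cis separations
follow a d^-alpha power law (default alpha 1, the classic contact-decay
exponent) sampled by inverse CDF on [d_min, L); both ends of a cis pair come
from the same molecule.  Feature counts follow a gamma-Poisson model in
which the gamma noise multiplier is **shared by the two alleles of a
feature**: biological and technical depth noise affects the locus, not one
allele, so allelic proportions stay binomial around the planted ratio while
totals are negative-binomially overdispersed.  (Independent per-allele noise
would make every allelic-proportion test anticonservative by construction.)

The simulator also ships a truth-based "perfect aligner"
(`truth_alignments`, `read_snp_observations`): split alignments and SNP
pileups computed through the truth coordinate map, with substitution errors
propagated into the observed alleles.  What the simulator does **not**
emulate: realistic error profiles and indels, mappability artefacts,
GC/coverage bias, retrotransposons, extrachromosomal DNA, and real aligner
ambiguity.  Passing tests therefore demonstrate the correctness of the
resolution logic under clean alignments, not robustness to alignment noise.

## Phase-block assignment

`validate_svs` derives one junction per adjacent split-alignment segment
pair, clusters them within a +-50 bp breakend tolerance, and keeps a
candidate when at least `min_support` (default 3) reads support it;
well-supported junctions absent from the candidate list are appended as
*rescued*, unsupported candidates are *removed*.  The tolerance and support
threshold are package defaults — long-read SV validation needs some window
for alignment jitter, and 3 reads is the conventional floor.
`filter_germline_svs` removes junctions called on both haplotypes, matching
a matched-normal call, or with a breakend in a repeat track; it is
idempotent, and a missing repeat track skips that filter with a warning.

A block label states where **allele A** of the block lies; allele B lies on
the homolog.  This convention makes the three evidence channels
self-consistent:

* **sv** — junction-supporting reads are derivative-certified by
  construction, so every het allele they report orients the block they
  cover: a majority of allele-A matches (margin >= 2 votes) puts allele A on
  the derivative.  This read-backed linkage extends to blocks near, not
  only containing, a junction — the same reads cover both.  A junction
  *inside* a block with no orienting votes (possible when the block sits in
  an LOH tract whose edges coincide with junction breakends) defaults to
  derivative only in the absence of counter-evidence.
* **loh** — at SNPs inside an LOH tract the surviving allele is the
  wild-type one; `loh_snps` counts sites (depth >= 3, VAF >= 0.8) where that
  retained allele equals allele A, labelling the block wild-type, and
  `loh_snps_alt` the converse.
* **vaf-depth** — under asymmetric copy number (cn_d derivative, cn_w
  wild-type copies) the allele-A VAF is binomial around cn_d/(cn_d+cn_w) if
  A is derivative and cn_w/(cn_d+cn_w) if not; the summed per-SNP binomial
  log-likelihood ratio decides at |LLR| >= 2.  With balanced copy number
  the LLR is identically zero, which is why asymmetric karyotypes make
  depth informative.

Precedence is sv > loh > vaf-depth > random.  Genuinely contradictory sv
and loh evidence keeps the sv label and flags the block.  Uninformative
blocks get a coin flip keyed by (seed, block id), so random labels are
reproducible and independent of iteration order.  Read partitioning is a
majority vote of each read's observed alleles mapped through the block
labels; ties and SNP-free reads are *unassigned* (a caller writing
per-haplotype read sets should emit them to both, flagged).

## Assembly evaluation

N90/L90 follow the standard definition (lengths sorted descending; L90 the
minimal contig count reaching 90% of the total, N90 that contig's length).
Segment maps chain **unique exact k-mer anchors** (k = 21) on a shared
diagonal and strand into segments, dropping runs under `min_segment`
(100 bp default; 200 in the desk-scale recovery runs).  Exact anchoring is a
desk-scale substitute for identity-threshold alignment: exact on
substitution-free sequence, with segment boundaries that may slide a few bp
where junction sequence coincidentally continues the reference
(micro-homology).  Liftover mirrors positions inside minus segments and
returns multiple hits where reference intervals recur (duplications);
positions in unaligned gaps return nothing.  `reconstruction_accuracy`
matches adjacent-segment junctions against truth breakends (+-50 bp) for
precision/recall, counts planted duplications covered by fewer than two
segment copies as collapsed — the known failure mode of assemblers on long
tandem duplications — and reports unmatched observed junctions as
fragmentation.  The greedy exact-overlap assembler is a test fixture, not a
production tool: it removes contained reads and repeatedly merges the
longest exact suffix-prefix overlap >= `min_overlap`.

## Functional read arbitration

Evidence precedence is snp > loh > mapq > distance > random; the published
workflow lists these evidence types without an order, and this order runs
from most to least specific.  Mapping-quality evidence requires a margin of
10 (a read absent from one assembly scores mapq 0 there).  Hi-C pairs are
aligned as single ends but arbitrated jointly: SNP/LOH evidence is summed
over mates, and otherwise the pair goes to the assembly with the higher
likelihood of its mate separation under the contact-distance model, when
the log-likelihood ratio clears 1.0.

The distance model is a log-binned empirical histogram (30 bins, add-one
smoothing) with a power-law tail fitted on the populated upper half of the
log-log curve; probabilities plus the trans mass sum to one.  Mates landing
on different contigs are scored with the trans mass spread uniformly over
the modelled span, putting discrete trans events and continuous cis
densities on the same per-bp scale — without that scaling a trans
observation would dominate any cis likelihood spuriously.  All tie-breaks
are seeded coin flips keyed by read name.

## Allele-specific statistics

The imbalance test is a two-sided **exact binomial test** of the derivative
count against the total, with a per-feature CN-adjustable null proportion
(default 0.5) and Benjamini-Hochberg control at q < 0.05.  It is the
per-haplotype-count analogue of the count-model Wald tests used on real
data, chosen because the package's inputs are exactly per-haplotype counts;
adapters can ingest externally computed q-values instead.  The p-value is
computed vectorised by the minimum-likelihood rule and agrees with the
scipy reference implementation to floating precision (asserted in the
tests).  Zero-total features are reported as untested, never silently
dropped.

The mechanism cascade classifies each differential feature in order:
**dosage** if its interval overlaps unequal per-haplotype copy number or an
LOH tract; else **direct disruption** if a validated breakend falls inside
it; else **unexplained**.  Dosage precedes disruption so the categories
partition the differential set, and category percentages are quoted over
all resolved features so they sum to the differential percentage.
Distances are half-open-interval distances: zero when a breakend falls
inside a feature, else the gap to the nearest feature edge; the
within-threshold fraction uses 10 kb by default.  Rank-sum comparisons use
the exact two-sided Mann-Whitney distribution for tie-free samples up to
n = 12 per group and the tie-corrected normal approximation otherwise; the
degenerate all-equal case returns p = 1.  Cross-sample stability is Pearson
correlation on log2(count+1) of shared features, with gained (zero then
nonzero) and lost sets reported.  Fusion transcripts are exon chains whose
consecutive lifted exons jump more than 1 Mb on the reference or change
orientation; exons in unaligned gaps make the transcript unresolvable.  For
gene-to-peak-class distances, "active" peaks default to H3K27ac, H3K4me3,
ATAC and CTCF and "inactive" to H3K27me3; CTCF's inclusion among active
marks is configurable since it marks boundaries rather than activity.

## TAD analysis

Cis pairs are binned into symmetric count matrices (upper triangle plus
diagonal conserves the pair count; trans and out-of-range records are
counted and excluded).  The boundary signal is the standard insulation
score: the sum of contacts in a diamond spanning `window_bins` (default 10)
on each side of a bin, normalised to mean 1 over valid bins; bins within a
window of the matrix edge are masked, and the mask edges are filled by
value extension so the mask itself never creates a minimum.  Boundaries are
local minima with prominence >= 0.2 in normalised units.  A boundary whose
insulation plateau touches the masked edge is undetectable by construction
— callers should treat the first and last window of a chromosome as blind.
The default resolution ladder is 150 kb / 250 kb / 500 kb / 750 kb / 1 Mb,
exposing the TAD hierarchy; raw counts are used (no balancing), matching
desk-scale synthetic input, with externally balanced matrices accepted
through the same entry points.  TADs are the gaps between successive
boundaries; haplotype size comparison reports medians and the rank-sum p.

## Problem sizes and reproducibility

The standard study conditions used throughout the tests and the acceptance
script are a 1-Mb diploid chromosome at SNP rate 1e-3, 100 chromothripsis
breakpoints over the whole chromosome (the toy analogue of a chromosome
dispersed with hundreds of junctions) with 40% fragment loss, and 12-kb
reads at 20x per copy with 1% substitution error; structure recovery runs
on a 150-kb reference with 20 breakpoints, the distance-model checks on
5x10^4–10^5 pairs, and calibration on 200 replicates of 1,000 features.
Every stochastic entry point takes a seed, and all per-entity random
decisions are keyed by (seed, entity name), so results are order-independent
and byte-reproducible.

## Known limitations

* Evidence orientation relies on junction-supporting reads observing het
  SNPs; a chromosome with long SNP deserts around its junctions would push
  more blocks to the random fallback.
* The exact binomial imbalance test conditions on total counts and assumes
  allele-shared depth noise; strongly allele-specific technical noise
  (e.g. mapping bias toward the reference allele) would require the
  beta-binomial extension, which is not implemented.
* Exact k-mer anchoring cannot place segments shorter than ~k + min_segment
  or survive high error rates; it is an evaluation tool for the simulator's
  substitution-only sequences, not a general-purpose aligner.
* The insulation caller uses raw counts; on real, unbalanced Hi-C data the
  boundary calls would inherit coverage artefacts.
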