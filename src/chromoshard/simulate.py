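"""Truth-labelled diploid toy genomes with chromothripsis on one haplotype.

The simulator emulates the study design of haplotype-resolved cancer-genome
work: a diploid chromosome carrying phased germline heterozygous SNPs, one
parental copy shattered by chromothripsis (fragments lost, shuffled and
re-ligated in random orientation, producing oscillating copy number, clustered
junctions in all four orientations and alternating retained/lost
heterozygosity), plus long reads, Hi-C contact pairs and allele-resolved
feature counts with planted effects.  Every simulated object carries its truth
label so downstream assignment machinery can be scored exactly.

Coordinates are 0-based half-open throughout; orientations are ``+``/``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import revcomp, stable_rng
from .sv import SvCall, junctions_from_segments

BASES = np.array(list("ACGT"))

GENOMIC_LONG = "genomic-long"
FUNCTIONAL_SHORT = "functional-short"
HIC_END = "hic-end"
TRANSCRIPT = "transcript"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeRecord:
    """One diploid chromosome: two haplotype sequences plus phased SNPs."""

    name: str
    hap1: str
    hap2: str
    snps: pd.DataFrame  # pos, allele_hap1, allele_hap2, block_id
    phase_blocks: pd.DataFrame  # block_id, start, end, hap1_is_A

    @property
    def length(self) -> int:
        return len(self.hap1)


@dataclass
class ToyGenome:
    chromosomes: list[ChromosomeRecord]

    def chromosome(self, name: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")


@dataclass
class RearrangementTruth:
    """Ground truth for one rearranged haplotype.

    ``fragments`` is the ordered, oriented walk of reference intervals that
    concatenate into the derivative sequence (flanks included).  ``lost`` are
    the fragments dropped during re-ligation; on the derivative they are LOH
    tracts.  ``cn_segments`` is the resulting copy-number step function over
    reference coordinates (wild-type copies plus derivative multiplicity).
    """

    chrom: str
    hap: str
    fragments: list[tuple[int, int, str]]  # (start, end, strand)
    lost: list[tuple[int, int]]
    breakends: list[SvCall]
    cn_segments: pd.DataFrame  # start, end, cn
    loh_tracts: list[tuple[int, int]]
    region: tuple[int, int] | None = None
    duplications: list[tuple[int, int]] = field(default_factory=list)

    @property
    def derivative_length(self) -> int:
        return sum(e - s for s, e, _ in self.fragments)

    def colinear_walk(self) -> list[tuple[int, int, str]]:
        """Fragments with reference-adjacent same-strand neighbours merged.

        A shuffled fragment can land back next to its reference neighbour in
        the original orientation; the junction then carries no breakend and
        an aligner sees one contiguous segment.  This is the walk a perfect
        segment map reproduces.
        """
        merged: list[list] = []
        for s, e, o in self.fragments:
            if merged:
                ps, pe, po = merged[-1]
                if o == po == "+" and ps is not None and pe == s:
                    merged[-1][1] = e
                    continue
                if o == po == "-" and e == ps:
                    merged[-1][0] = s
                    continue
            merged.append([s, e, o])
        return [(s, e, o) for s, e, o in merged]

    def derivative_sequence(self, reference: str) -> str:
        parts = []
        for s, e, strand in self.fragments:
            seg = reference[s:e]
            parts.append(seg if strand == "+" else revcomp(seg))
        return "".join(parts)

    def derivative_to_reference(self, pos: int) -> tuple[int, str]:
        """Map one derivative coordinate to (reference position, strand)."""
        off = 0
        for s, e, strand in self.fragments:
            flen = e - s
            if off <= pos < off + flen:
                within = pos - off
                if strand == "+":
                    return s + within, "+"
                return e - 1 - within, "-"
            off += flen
        raise IndexError(f"position {pos} outside derivative of length {off}")

    def read_segments(
        self, start: int, end: int
    ) -> list[tuple[str, int, int, str, int, int]]:
        """Split a derivative interval into oriented reference segments.

        Returns ``(chrom, ref_start, ref_end, strand, read_off_start,
        read_off_end)`` tuples in derivative order — exactly the split
        alignment a perfect aligner would report for a read spanning
        ``[start, end)`` of the derivative.
        """
        out = []
        off = 0
        for s, e, strand in self.fragments:
            flen = e - s
            a, b = max(start, off), min(end, off + flen)
            if a < b:
                if strand == "+":
                    ref_s, ref_e = s + (a - off), s + (b - off)
                else:
                    ref_s, ref_e = e - (b - off), e - (a - off)
                out.append((self.chrom, ref_s, ref_e, strand, a - start, b - start))
            off += flen
        return out


@dataclass
class SimRead:
    name: str
    sequence: str
    haplotype: str  # truth: hap1 or hap2
    source: str  # name of the source sequence it was drawn from
    start: int  # on the source sequence, half-open
    end: int
    datatype: str = GENOMIC_LONG


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def build_diploid_genome(
    n_chrom: int,
    length: int,
    snp_rate: float,
    block_len_mean: int = 20_000,
    seed: int = 0,
) -> ToyGenome:
    """Random diploid genome with phased het SNPs partitioned into blocks.

    The two haplotypes differ only at SNP positions.  Phase blocks partition
    each chromosome into contiguous intervals with exponentially distributed
    lengths (mean ``block_len_mean``), emulating read-based phasing output;
    each block's internal A/B labelling is flipped at random, as real phasing
    orients every block arbitrarily.
    """
    if n_chrom <= 0:
        raise ValueError("n_chrom must be positive")
    if length < 10_000:
        raise ValueError("chromosome length must be at least 10 kb")
    if not 0 <= snp_rate < 0.1:
        raise ValueError("snp_rate must lie in [0, 0.1)")
    if block_len_mean <= 0:
        raise ValueError("block_len_mean must be positive")

    chroms = []
    for i in range(n_chrom):
        name = f"chr{i + 1}"
        rng = stable_rng(seed, "genome", name)
        seq = rng.choice(BASES, size=length)
        hap1 = "".join(seq)

        snp_mask = rng.random(length) < snp_rate if snp_rate > 0 else np.zeros(length, bool)
        snp_pos = np.flatnonzero(snp_mask)
        hap2_arr = seq.copy()
        # alternate allele: shift within ACGT by 1-3 so it always differs
        shifts = rng.integers(1, 4, size=snp_pos.size)
        base_idx = np.searchsorted(BASES, seq[snp_pos])
        hap2_arr[snp_pos] = BASES[(base_idx + shifts) % 4]
        hap2 = "".join(hap2_arr)

        # phase-block partition
        cuts = [0]
        while cuts[-1] < length:
            cuts.append(cuts[-1] + max(1, int(rng.exponential(block_len_mean))))
        cuts[-1] = length
        blocks = pd.DataFrame(
            {
                "block_id": [f"{name}_b{j}" for j in range(len(cuts) - 1)],
                "start": cuts[:-1],
                "end": cuts[1:],
                "hap1_is_A": rng.random(len(cuts) - 1) < 0.5,
            }
        )
        block_of = np.searchsorted(blocks["end"].to_numpy(), snp_pos, side="right")
        snps = pd.DataFrame(
            {
                "pos": snp_pos,
                "allele_hap1": [hap1[p] for p in snp_pos],
                "allele_hap2": [hap2[p] for p in snp_pos],
                "block_id": blocks["block_id"].to_numpy()[block_of],
            }
        )
        # phase blocks are sets of het SNPs; intervals without any SNP are
        # not blocks at all
        blocks = blocks[blocks["block_id"].isin(snps["block_id"])].reset_index(
            drop=True
        )
        chroms.append(ChromosomeRecord(name, hap1, hap2, snps, blocks))
    return ToyGenome(chroms)


# ---------------------------------------------------------------------------
# rearrangement
# ---------------------------------------------------------------------------


def _cn_segments(
    length: int,
    region: tuple[int, int],
    retained: list[tuple[int, int]],
    multiplicity: dict[tuple[int, int], int] | None = None,
    wt_copies: int = 1,
) -> pd.DataFrame:
    """Copy-number step function: wild-type copies + derivative multiplicity."""
    bounds = {0, length, region[0], region[1]}
    for s, e in retained:
        bounds.update((s, e))
    edges = sorted(b for b in bounds if 0 <= b <= length)
    rows = []
    for s, e in zip(edges, edges[1:]):
        if s == e:
            continue
        mid = (s + e) // 2
        if region[0] <= mid < region[1]:
            mult = sum(
                (multiplicity or {}).get((fs, fe), 1)
                for fs, fe in retained
                if fs <= mid < fe
            )
        else:
            mult = 1
        rows.append((s, e, wt_copies + mult))
    out = pd.DataFrame(rows, columns=["start", "end", "cn"])
    # merge adjacent equal-CN segments
    merged = []
    for row in out.itertuples(index=False):
        if merged and merged[-1][2] == row.cn and merged[-1][1] == row.start:
            merged[-1][1] = row.end
        else:
            merged.append([row.start, row.end, row.cn])
    return pd.DataFrame(merged, columns=["start", "end", "cn"])


def apply_chromothripsis(
    genome: ToyGenome,
    chrom: str,
    hap: str,
    region: tuple[int, int],
    n_breakpoints: int,
    loss_prob: float,
    seed: int = 0,
    wt_copies: int = 1,
    permute: bool = True,
    invert: bool = True,
) -> tuple[str, RearrangementTruth]:
    """Shatter one haplotype within ``region`` and re-ligate at random.

    The region is cut at ``n_breakpoints`` uniform positions; each fragment is
    lost independently with probability ``loss_prob``; the survivors are
    shuffled, each reverse-complemented with probability 1/2, and concatenated
    in place.  ``permute``/``invert`` can be switched off to force the identity
    rearrangement (useful for degenerate checks).  Returns the derivative
    haplotype sequence and a complete :class:`RearrangementTruth`.
    """
    rec = genome.chromosome(chrom)
    start, end = region
    if not (0 <= start < end <= rec.length):
        raise ValueError(f"region {region} outside chromosome of length {rec.length}")
    if n_breakpoints < 1:
        raise ValueError("n_breakpoints must be >= 1")
    if not 0 <= loss_prob <= 1:
        raise ValueError("loss_prob must be a probability")

    rng = stable_rng(seed, "chromothripsis", chrom, hap)
    cuts: np.ndarray = np.array([], dtype=int)
    while cuts.size < n_breakpoints:
        extra = rng.integers(start + 1, end, size=n_breakpoints - cuts.size)
        cuts = np.unique(np.concatenate([cuts, extra]))
    edges = [start, *sorted(int(c) for c in cuts), end]
    pieces = list(zip(edges[:-1], edges[1:]))

    keep_mask = rng.random(len(pieces)) >= loss_prob
    retained = [p for p, k in zip(pieces, keep_mask) if k]
    lost = [p for p, k in zip(pieces, keep_mask) if not k]

    order = rng.permutation(len(retained)) if permute else np.arange(len(retained))
    flips = rng.random(len(retained)) < 0.5 if invert else np.zeros(len(retained), bool)
    shuffled = [
        (retained[i][0], retained[i][1], "-" if flips[j] else "+")
        for j, i in enumerate(order)
    ]

    fragments: list[tuple[int, int, str]] = []
    if start > 0:
        fragments.append((0, start, "+"))
    fragments.extend(shuffled)
    if end < rec.length:
        fragments.append((end, rec.length, "+"))

    walk = [(chrom, s, e, o) for s, e, o in fragments]
    breakends = [
        SvCall(b1, b2, haplotype=hap, status="truth")
        for b1, b2 in junctions_from_segments(walk)
    ]

    # merge adjacent lost pieces into LOH tracts
    loh: list[list[int]] = []
    for s, e in lost:
        if loh and loh[-1][1] == s:
            loh[-1][1] = e
        else:
            loh.append([s, e])

    truth = RearrangementTruth(
        chrom=chrom,
        hap=hap,
        fragments=fragments,
        lost=lost,
        breakends=breakends,
        cn_segments=_cn_segments(rec.length, region, retained, wt_copies=wt_copies),
        loh_tracts=[tuple(t) for t in loh],
        region=region,
    )
    source = rec.hap1 if hap == "hap1" else rec.hap2
    return truth.derivative_sequence(source), truth


def apply_simple_sv(
    genome: ToyGenome,
    chrom: str,
    hap: str,
    sv_spec,
) -> tuple[list[tuple[str, float]], RearrangementTruth]:
    """Apply simple SVs (deletion / inversion / tandem-duplication).

    ``sv_spec`` is one ``(sv_class, (start, end), subclonal_fraction)`` tuple
    or a list of them; intervals must not overlap.  Returns sequence variants
    as ``(sequence, mixing_fraction)`` pairs — two versions when any event is
    subclonal — plus the truth for the fully rearranged version.
    """
    rec = genome.chromosome(chrom)
    specs = sv_spec if isinstance(sv_spec, list) else [sv_spec]
    ivals = sorted((s, e) for _, (s, e), _ in specs)
    for (s, e) in ivals:
        if not (0 <= s < e <= rec.length):
            raise ValueError(f"interval ({s}, {e}) outside chromosome")
    for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
        if e1 > s2:
            raise ValueError("overlapping SV intervals")

    L = rec.length
    fragments: list[tuple[int, int, str]] = []
    lost: list[tuple[int, int]] = []
    dups: list[tuple[int, int]] = []
    retained_region: list[tuple[int, int]] = []
    mult: dict[tuple[int, int], int] = {}
    cursor = 0
    min_frac = 1.0
    for cls, (s, e), frac in sorted(specs, key=lambda x: x[1][0]):
        if not 0 < frac <= 1:
            raise ValueError("subclonal_fraction must lie in (0, 1]")
        min_frac = min(min_frac, frac)
        if cursor < s:
            fragments.append((cursor, s, "+"))
        if cls == "deletion":
            lost.append((s, e))
        elif cls == "inversion":
            fragments.append((s, e, "-"))
            retained_region.append((s, e))
        elif cls == "tandem-duplication":
            fragments.append((s, e, "+"))
            fragments.append((s, e, "+"))
            dups.append((s, e))
            retained_region.append((s, e))
            mult[(s, e)] = 2
        else:
            raise ValueError(f"unknown simple SV class {cls!r}")
        cursor = e
    if cursor < L:
        fragments.append((cursor, L, "+"))

    walk = [(chrom, s, e, o) for s, e, o in fragments]
    breakends = [
        SvCall(b1, b2, haplotype=hap, status="truth")
        for b1, b2 in junctions_from_segments(walk)
    ]
    region = (min(s for s, _ in ivals), max(e for _, e in ivals))
    # fragments inside the affected region only (for CN computation)
    inner = [
        (s, e)
        for s, e, _ in fragments
        if region[0] <= s < region[1] and not (s, e) in mult
    ]
    cn_retained = sorted(set(retained_region) | set(inner))
    truth = RearrangementTruth(
        chrom=chrom,
        hap=hap,
        fragments=fragments,
        lost=lost,
        breakends=breakends,
        cn_segments=_cn_segments(L, region, cn_retained, multiplicity=mult),
        loh_tracts=list(lost),
        region=region,
        duplications=dups,
    )
    source = rec.hap1 if hap == "hap1" else rec.hap2
    edited = truth.derivative_sequence(source)
    if min_frac < 1:
        return [(edited, min_frac), (source, 1 - min_frac)], truth
    return [(edited, 1.0)], truth


# ---------------------------------------------------------------------------
# read / contact / count simulation
# ---------------------------------------------------------------------------


_BASE_BYTES = b"ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_BYTES)}


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n = rng.binomial(len(seq), error_rate)
    if n == 0:
        return seq
    buf = bytearray(seq, "ascii")
    pos = rng.choice(len(seq), size=n, replace=False)
    shifts = rng.integers(1, 4, size=n)
    for p, s in zip(pos, shifts):
        buf[p] = _BASE_BYTES[(_BASE_INDEX[buf[p]] + s) % 4]
    return buf.decode("ascii")


def simulate_long_reads(
    sources: list[tuple[str, str, str, float]],
    depth: float,
    mean_len: int = 12_000,
    error_rate: float = 0.0,
    seed: int = 0,
    datatype: str = GENOMIC_LONG,
) -> list[SimRead]:
    """Draw substitution-error long reads from weighted haplotype sequences.

    ``sources`` is a list of ``(name, sequence, truth_haplotype, weight)``;
    the weight is the copy number or subclonal mixing fraction of that
    molecule, so a CN-2 haplotype receives about twice the reads of a CN-1
    haplotype.  ``depth`` is per-copy fold coverage; total simulated bases are
    about ``depth * sum(weight_i * len_i)``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not sources:
        raise ValueError("empty sequence set")
    names = [s[0] for s in sources]
    lens = np.array([len(s[1]) for s in sources], float)
    weights = np.array([s[3] for s in sources], float)
    mass = lens * weights
    n_reads = int(round(depth * mass.sum() / mean_len))
    rng = stable_rng(seed, "long-reads")
    src_idx = rng.choice(len(sources), size=n_reads, p=mass / mass.sum())
    reads = []
    for i, si in enumerate(src_idx):
        name, seq, hap, _ = sources[si]
        L = len(seq)
        rlen = int(np.clip(rng.gamma(10.0, mean_len / 10.0), 200, L))
        start = int(rng.integers(0, L - rlen + 1))
        rseq = _inject_errors(seq[start : start + rlen], error_rate, rng)
        reads.append(
            SimRead(f"read{i:06d}", rseq, hap, name, start, start + rlen, datatype)
        )
    return reads


def simulate_hic_pairs(
    sources: list[tuple[str, str, str, float]],
    n_pairs: int,
    alpha: float = 1.0,
    trans_prob: float = 0.0,
    seed: int = 0,
    d_min: int = 1_000,
) -> pd.DataFrame:
    """Hi-C contact pairs with power-law cis separations.

    Cis separations follow density proportional to ``d**-alpha`` on
    ``[d_min, L)``; both ends of a cis pair come from the same haplotype
    molecule.  Trans pairs (probability ``trans_prob``) draw their two ends
    from independently chosen molecules at uniform positions.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = stable_rng(seed, "hic")
    names = np.array([s[0] for s in sources])
    haps = np.array([s[2] for s in sources])
    lens = np.array([len(s[1]) for s in sources], float)
    weights = np.array([s[3] for s in sources], float)
    mass = lens * weights
    p = mass / mass.sum()

    is_trans = rng.random(n_pairs) < trans_prob
    a = rng.choice(len(sources), size=n_pairs, p=p)
    b = a.copy()
    b[is_trans] = rng.choice(len(sources), size=int(is_trans.sum()), p=p)
    La = lens[a]
    # inverse-CDF sampling of the d**-alpha cis separation law
    u = rng.random(n_pairs)
    if abs(alpha - 1.0) < 1e-9:
        d = d_min * (La / d_min) ** u
    else:
        lo, hi = d_min ** (1 - alpha), La ** (1 - alpha)
        d = (lo + u * (hi - lo)) ** (1 / (1 - alpha))
    d = np.clip(d.astype(int), d_min, (La - 1).astype(int))
    pos1 = (rng.random(n_pairs) * (La - d)).astype(int)
    pos2 = pos1 + d
    # trans ends are uniform on their own molecules
    pos1[is_trans] = (rng.random(int(is_trans.sum())) * La[is_trans]).astype(int)
    pos2[is_trans] = (rng.random(int(is_trans.sum())) * lens[b[is_trans]]).astype(int)

    df = pd.DataFrame(
        {
            "name": [f"pair{i:06d}" for i in range(n_pairs)],
            "source1": names[a],
            "pos1": pos1,
            "source2": names[b],
            "pos2": pos2,
            "haplotype": haps[a],
            "is_trans": is_trans,
        }
    )
    df["separation"] = np.where(
        df["is_trans"], np.nan, np.abs(df["pos2"] - df["pos1"])
    )
    return df


def simulate_feature_counts(
    features: pd.DataFrame,
    planted_lfc,
    dispersion: float = 0.1,
    mean_depth: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-haplotype feature counts with planted log2 fold changes.

    Counts follow a gamma-Poisson (negative-binomial-like) model: haplotype
    means ``mean_depth * 2**(+-lfc/2)`` with multiplicative gamma noise of the
    given dispersion.  ``truth_differential`` marks features with nonzero
    planted effect.  Features must be non-overlapping within a kind.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    req = {"feature_id", "kind", "start", "end"}
    if not req.issubset(features.columns):
        raise ValueError(f"features table needs columns {sorted(req)}")
    for kind, grp in features.groupby("kind"):
        g = grp.sort_values("start")
        if (g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]).any():
            raise ValueError(f"overlapping features within kind {kind!r}")
    lfc = np.asarray(planted_lfc, float)
    if lfc.shape[0] != len(features):
        raise ValueError("planted_lfc length must match features")
    rng = stable_rng(seed, "feature-counts")
    mu1 = mean_depth * np.power(2.0, lfc / 2)
    mu2 = mean_depth * np.power(2.0, -lfc / 2)
    # one gamma multiplier per feature: biological/technical noise is shared
    # by the two alleles of a feature, so allelic proportions stay binomial
    # around the planted ratio while totals are NB-overdispersed
    if dispersion > 0:
        noise = rng.gamma(1.0 / dispersion, dispersion, size=lfc.size)
    else:
        noise = np.ones(lfc.size)
    out = features.copy().reset_index(drop=True)
    out["count_hap1"] = rng.poisson(noise * mu1)
    out["count_hap2"] = rng.poisson(noise * mu2)
    out["planted_lfc"] = lfc
    out["truth_differential"] = np.abs(lfc) > 0
    out["truth_mechanism"] = None
    return out


# ---------------------------------------------------------------------------
# truth-based "perfect aligner" plumbing
# ---------------------------------------------------------------------------


def truth_alignments(
    reads: list[SimRead],
    source_map: dict[str, tuple[str, RearrangementTruth | None]],
) -> pd.DataFrame:
    """Split-alignment records a perfect aligner would emit for each read.

    ``source_map`` maps source-sequence names to ``(chromosome, truth)`` where
    truth is None for unrearranged haplotypes.  Output columns: read,
    seg_index, chrom, start, end, strand (reference coordinates).
    """
    rows = []
    for r in reads:
        chrom, truth = source_map[r.source]
        if truth is None:
            rows.append((r.name, 0, chrom, r.start, r.end, "+"))
        else:
            for i, (c, s, e, o, _, _) in enumerate(truth.read_segments(r.start, r.end)):
                rows.append((r.name, i, c, s, e, o))
    return pd.DataFrame(
        rows, columns=["read", "seg_index", "chrom", "start", "end", "strand"]
    )


def read_snp_observations(
    reads: list[SimRead],
    genome: ToyGenome,
    source_map: dict[str, tuple[str, RearrangementTruth | None]],
) -> pd.DataFrame:
    """Alleles each read reports at catalogued het-SNP positions.

    Observed bases come from the read sequence itself (so substitution errors
    propagate); minus-strand segments are complemented back to reference
    orientation.  Output columns: read, chrom, pos, allele, truth_hap.
    """
    comp = str.maketrans("ACGT", "TGCA")
    rows = []
    snp_cache: dict[str, np.ndarray] = {}
    for r in reads:
        chrom, truth = source_map[r.source]
        if chrom not in snp_cache:
            snp_cache[chrom] = genome.chromosome(chrom).snps["pos"].to_numpy()
        snp_pos = snp_cache[chrom]
        if truth is None:
            segs = [(chrom, r.start, r.end, "+", 0, r.end - r.start)]
        else:
            segs = truth.read_segments(r.start, r.end)
        for _, ref_s, ref_e, strand, off_s, off_e in segs:
            lo = np.searchsorted(snp_pos, ref_s, side="left")
            hi = np.searchsorted(snp_pos, ref_e, side="left")
            for p in snp_pos[lo:hi]:
                if strand == "+":
                    off = off_s + (p - ref_s)
                    base = r.sequence[off]
                else:
                    off = off_s + (ref_e - 1 - p)
                    base = r.sequence[off].translate(comp)
                rows.append((r.name, chrom, int(p), base, r.haplotype))
    return pd.DataFrame(rows, columns=["read", "chrom", "pos", "allele", "truth_hap"])
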