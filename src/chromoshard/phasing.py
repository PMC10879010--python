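"""Phase-block assignment: the machinery that splits a diploid chromosome
into its derivative (chromothriptic) and wild-type copies.

The workflow mirrors haplotype-aware cancer assembly: candidate SV junctions
are validated against split long-read alignments (unsupported calls removed,
novel well-supported junctions rescued), germline junctions are filtered, and
each phase block of het SNPs is then scored for three kinds of evidence —

* **sv** — the block spans validated chromothriptic junctions; the alleles
  carried by the junction-supporting reads orient the block, since those
  reads come from the derivative chromosome;
* **loh** — the block contains SNPs inside loss-of-heterozygosity tracts; the
  allele still observed there is the wild-type one, because the derivative
  copy of the tract was lost;
* **vaf-depth** — under asymmetric copy number the variant-allele fraction of
  allele A is binomially distributed around cn_A / (cn_A + cn_B), giving a
  likelihood ratio between "allele A sits on the derivative" and "allele A
  sits on the wild-type".

Blocks with no informative evidence are assigned at random (seeded, keyed by
block id so the outcome is order-independent).  A block label always states
where **allele A** of that block lies; allele B lies on the other haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import stable_rng
from .simulate import ToyGenome
from .sv import SvCall, junctions_from_segments

DERIVATIVE = "derivative"
WILD_TYPE = "wild-type"
UNASSIGNED = "unassigned"


@dataclass
class PhaseBlock:
    """A phase set of het SNPs with per-SNP allele-A VAF and local depth."""

    block_id: str
    chrom: str
    start: int
    end: int
    snps: pd.DataFrame  # pos, allele_A, allele_B, vaf_A, depth

    def __post_init__(self):
        if not self.snps.empty:
            pos = self.snps["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                self.snps = self.snps.sort_values("pos").reset_index(drop=True)
            inside = (self.snps["pos"] >= self.start) & (self.snps["pos"] < self.end)
            if not inside.all():
                raise ValueError(f"block {self.block_id}: SNPs outside interval")


@dataclass
class BlockEvidence:
    block_id: str
    spans_sv: bool = False
    sv_junctions: int = 0
    sv_votes_a: int = 0  # junction-read alleles matching allele_A
    sv_votes_b: int = 0
    loh_snps: int = 0  # LOH SNPs whose retained allele equals allele_A
    loh_snps_alt: int = 0  # ... equals allele_B
    mean_vaf_a: float = float("nan")
    depth_ratio: float = float("nan")
    vaf_llr: float = 0.0  # >0 favours allele_A on the derivative
    informative: bool = False


# ---------------------------------------------------------------------------
# SV validation and germline filtering
# ---------------------------------------------------------------------------

_ALIGN_COLS = ("read", "seg_index", "chrom", "start", "end", "strand")


def _read_junctions(alignments: pd.DataFrame):
    """Yield (read, breakend-pair) for every adjacent split-alignment pair."""
    missing = [c for c in _ALIGN_COLS if c not in alignments.columns]
    if missing:
        raise ValueError(f"malformed alignment table: missing columns {missing}")
    bad = ~alignments["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"malformed alignment record at line {int(np.flatnonzero(bad)[0])}: "
            f"strand must be +/-"
        )
    for read, grp in alignments.groupby("read", sort=False):
        segs = [
            (r.chrom, int(r.start), int(r.end), r.strand)
            for r in grp.sort_values("seg_index").itertuples(index=False)
        ]
        for pair in junctions_from_segments(segs):
            yield read, pair


def validate_svs(
    candidates: list[SvCall],
    alignments: pd.DataFrame,
    min_support: int = 3,
    tol: int = 50,
) -> list[SvCall]:
    """Validate candidate junctions against split long-read alignments.

    A candidate is *validated* when at least ``min_support`` reads carry
    adjacent aligned segments matching both breakends within ``tol`` bp;
    otherwise it is *removed*.  Junctions observed in at least ``min_support``
    reads but absent from the candidate list are appended as *rescued*.
    Supporting read names are attached to each kept call.
    """
    observed: list[tuple[SvCall, set]] = []
    for read, (b1, b2) in _read_junctions(alignments):
        call = SvCall(b1, b2)
        for existing, reads in observed:
            if existing.matches(call, tol=tol):
                reads.add(read)
                break
        else:
            observed.append((call, {read}))

    out: list[SvCall] = []
    used = [False] * len(observed)
    for cand in candidates:
        support: set = set()
        for i, (obs, reads) in enumerate(observed):
            if cand.matches(obs, tol=tol):
                support |= reads
                used[i] = True
        status = "validated" if len(support) >= min_support else "removed"
        kept = cand.with_status(status, support=len(support))
        kept.supporting_reads = sorted(support)
        out.append(kept)
    for flag, (obs, reads) in zip(used, observed):
        if not flag and len(reads) >= min_support:
            rescued = obs.with_status("rescued", support=len(reads))
            rescued.supporting_reads = sorted(reads)
            out.append(rescued)
    return out


def filter_germline_svs(
    svs: list[SvCall],
    matched_normal_svs: list[SvCall] | None = None,
    repeat_regions: list[tuple[str, int, int]] | None = None,
    tol: int = 50,
) -> list[SvCall]:
    """Drop germline junctions, keeping the somatic remainder.

    A junction is germline when it is called on both haplotypes, matches a
    matched-normal call within ``tol``, or has a breakend inside a repeat
    region.  A missing repeat track skips that filter with a warning.  The
    operation is idempotent.
    """
    if repeat_regions is None:
        warnings.warn("no repeat track supplied; skipping repeat-region filter")
        repeat_regions = []

    def in_repeat(call: SvCall) -> bool:
        for chrom, s, e in repeat_regions:
            for b in (call.breakend1, call.breakend2):
                if b.chrom == chrom and s <= b.pos < e:
                    return True
        return False

    somatic = []
    for call in svs:
        on_both = any(
            call.matches(other, tol=tol)
            and other.haplotype is not None
            and call.haplotype is not None
            and other.haplotype != call.haplotype
            for other in svs
        )
        in_normal = any(
            call.matches(n, tol=tol) for n in (matched_normal_svs or [])
        )
        if not (on_both or in_normal or in_repeat(call)):
            somatic.append(call)
    return somatic


# ---------------------------------------------------------------------------
# per-block evidence and assignment
# ---------------------------------------------------------------------------


def phase_blocks_from_observations(
    genome: ToyGenome, chrom: str, observations: pd.DataFrame
) -> list[PhaseBlock]:
    """Build PhaseBlocks with VAF/depth pileups from read SNP observations.

    ``observations`` has columns read/chrom/pos/allele (truth columns are
    ignored); the genome supplies the catalogued het sites and the emulated
    phasing orientation (which haplotype's allele is 'A' in each block).
    """
    rec = genome.chromosome(chrom)
    obs = observations[observations["chrom"] == chrom]
    pile = (
        obs.groupby(["pos", "allele"]).size().unstack(fill_value=0)
        if not obs.empty
        else pd.DataFrame()
    )
    blocks = []
    for b in rec.phase_blocks.itertuples(index=False):
        snps = rec.snps[rec.snps["block_id"] == b.block_id]
        rows = []
        for s in snps.itertuples(index=False):
            a_allele = s.allele_hap1 if b.hap1_is_A else s.allele_hap2
            b_allele = s.allele_hap2 if b.hap1_is_A else s.allele_hap1
            if not pile.empty and s.pos in pile.index:
                counts = pile.loc[s.pos]
                depth = int(counts.sum())
                vaf_a = counts.get(a_allele, 0) / depth if depth else np.nan
            else:
                depth, vaf_a = 0, np.nan
            rows.append((s.pos, a_allele, b_allele, vaf_a, depth))
        blocks.append(
            PhaseBlock(
                b.block_id,
                chrom,
                int(b.start),
                int(b.end),
                pd.DataFrame(
                    rows, columns=["pos", "allele_A", "allele_B", "vaf_A", "depth"]
                ),
            )
        )
    return blocks


def _binomial_llr(k: np.ndarray, n: np.ndarray, p1: float, p2: float) -> float:
    """Sum of per-site binomial log-likelihood ratios of p1 vs p2."""
    if abs(p1 - p2) < 1e-12:
        return 0.0
    p1 = min(max(p1, 1e-9), 1 - 1e-9)
    p2 = min(max(p2, 1e-9), 1 - 1e-9)
    return float(
        np.sum(k * (np.log(p1) - np.log(p2)) + (n - k) * (np.log1p(-p1) - np.log1p(-p2)))
    )


def score_block_evidence(
    block: PhaseBlock,
    svs: list[SvCall],
    loh_tracts: list[tuple[int, int]],
    expected_cn: tuple[float, float] = (1.0, 1.0),
    llr_threshold: float = 2.0,
    read_obs: pd.DataFrame | None = None,
    loh_vaf_margin: float = 0.8,
    min_loh_depth: int = 3,
    min_sv_votes: int = 2,
) -> BlockEvidence:
    """Collect SV / LOH / VAF-depth evidence for one phase block.

    ``expected_cn`` is ``(derivative copies, wild-type copies)``.  ``read_obs``
    (read/pos/allele) lets junction-supporting reads vote on which allele of
    the block is the derivative one.  Degenerate blocks simply come back
    uninformative; this never raises.
    """
    ev = BlockEvidence(block_id=block.block_id)
    if block.snps.empty:
        return ev
    snps = block.snps

    # --- SV evidence -----------------------------------------------------
    # A block spans an SV when a validated junction falls inside it.  The
    # orienting votes come from junction-supporting reads: such reads are
    # derivative-certified by construction, so every het allele they report
    # — in this block or a neighbouring one they also cover — says which
    # allele of the block sits on the derivative (read-backed linkage).
    confirmed = [s for s in svs if s.status in ("validated", "rescued", "truth")]
    spanning = [
        s
        for s in confirmed
        if any(
            b.chrom == block.chrom and block.start <= b.pos < block.end
            for b in (s.breakend1, s.breakend2)
        )
    ]
    ev.sv_junctions = len(spanning)
    ev.spans_sv = bool(spanning)
    if read_obs is not None and confirmed:
        support = set()
        for s in confirmed:
            support |= set(s.supporting_reads)
        if support:
            sub = read_obs[read_obs["read"].isin(support)]
            sub = sub.merge(
                snps[["pos", "allele_A", "allele_B"]], on="pos", how="inner"
            )
            ev.sv_votes_a = int((sub["allele"] == sub["allele_A"]).sum())
            ev.sv_votes_b = int((sub["allele"] == sub["allele_B"]).sum())

    # --- LOH evidence ----------------------------------------------------
    in_loh = np.zeros(len(snps), bool)
    for s, e in loh_tracts:
        in_loh |= (snps["pos"] >= s) & (snps["pos"] < e)
    loh_snps = snps[in_loh & (snps["depth"] >= min_loh_depth)]
    ev.loh_snps = int((loh_snps["vaf_A"] >= loh_vaf_margin).sum())
    ev.loh_snps_alt = int((loh_snps["vaf_A"] <= 1 - loh_vaf_margin).sum())

    # --- VAF / depth evidence -------------------------------------------
    het = snps[~in_loh & (snps["depth"] > 0)]
    if not het.empty:
        ev.mean_vaf_a = float(het["vaf_A"].mean())
        n = het["depth"].to_numpy(float)
        k = np.rint(het["vaf_A"].to_numpy(float) * n)
        cn_d, cn_w = expected_cn
        total = cn_d + cn_w
        if total > 0:
            p_der = cn_d / total  # VAF of allele A if A sits on the derivative
            p_wt = cn_w / total
            ev.vaf_llr = _binomial_llr(k, n, p_der, p_wt)
        exp_depth = getattr(block, "expected_depth", None)
        if exp_depth:
            ev.depth_ratio = float(het["depth"].mean()) / exp_depth

    ev.informative = (
        ev.spans_sv
        or abs(ev.sv_votes_a - ev.sv_votes_b) >= min_sv_votes
        or (ev.loh_snps + ev.loh_snps_alt) > 0
        or abs(ev.vaf_llr) >= llr_threshold
    )
    return ev


def assign_blocks(
    evidence: list[BlockEvidence],
    llr_threshold: float = 2.0,
    min_sv_votes: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Label every block derivative/wild-type with evidence precedence
    sv > loh > vaf-depth > random.

    The label states where allele A of the block lies.  SV-spanning blocks go
    to the derivative (oriented by junction-read allele votes when present);
    blocks whose LOH SNPs retain allele A go to the wild-type.  Contradictory
    sv and loh evidence keeps the sv label and flags the block.  Uninformative
    blocks get a reproducible random label keyed by (seed, block id).
    """
    rows = []
    for ev in evidence:
        label = basis = None
        conflicted = False
        sv_label = loh_label = None
        if ev.loh_snps != ev.loh_snps_alt:
            loh_label = WILD_TYPE if ev.loh_snps > ev.loh_snps_alt else DERIVATIVE
        vote_margin = ev.sv_votes_a - ev.sv_votes_b
        if abs(vote_margin) >= min_sv_votes:
            sv_label = DERIVATIVE if vote_margin > 0 else WILD_TYPE
        elif ev.spans_sv and loh_label is None:
            # a junction inside the block with no orienting allele votes:
            # derivative by default, but only without counter-evidence
            sv_label = DERIVATIVE
        if sv_label is not None:
            label, basis = sv_label, "sv"
            if loh_label is not None and loh_label != sv_label:
                conflicted = True
                warnings.warn(
                    f"block {ev.block_id}: conflicting sv and loh evidence; "
                    f"keeping sv label"
                )
        elif loh_label is not None:
            label, basis = loh_label, "loh"
        elif abs(ev.vaf_llr) >= llr_threshold:
            label = DERIVATIVE if ev.vaf_llr > 0 else WILD_TYPE
            basis = "vaf-depth"
        else:
            rng = stable_rng(seed, "assign-block", ev.block_id)
            label = DERIVATIVE if rng.random() < 0.5 else WILD_TYPE
            basis = "random"
        rows.append((ev.block_id, label, basis, conflicted))
    return pd.DataFrame(rows, columns=["block_id", "label", "basis", "conflicted"])


def partition_long_reads(
    observations: pd.DataFrame,
    blocks: list[PhaseBlock],
    assignment: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Partition reads by majority vote over the het SNPs they cover.

    Each observation at a block SNP votes for the haplotype its allele maps
    to under the block's label (allele A -> the block label, allele B -> the
    complement).  Reads with tied or no votes are returned as *unassigned* —
    a caller emitting per-haplotype read sets should include them in both,
    flagged.  Observations at unknown positions are ignored; their count is
    returned alongside the table.
    """
    label_of = dict(zip(assignment["block_id"], assignment["label"]))
    lut = {}
    for b in blocks:
        lab = label_of.get(b.block_id)
        if lab is None:
            continue
        comp = WILD_TYPE if lab == DERIVATIVE else DERIVATIVE
        for s in b.snps.itertuples(index=False):
            lut[s.pos] = (s.allele_A, s.allele_B, lab, comp)

    votes: dict[str, list[int]] = {}
    n_unknown = 0
    for o in observations.itertuples(index=False):
        entry = lut.get(o.pos)
        if entry is None:
            n_unknown += 1
            continue
        allele_a, allele_b, lab, comp = entry
        tally = votes.setdefault(o.read, [0, 0])  # [derivative, wild-type]
        if o.allele == allele_a:
            tally[0 if lab == DERIVATIVE else 1] += 1
        elif o.allele == allele_b:
            tally[0 if comp == DERIVATIVE else 1] += 1
    rows = []
    for read in observations["read"].unique():
        d, w = votes.get(read, (0, 0))
        if d > w:
            label = DERIVATIVE
        elif w > d:
            label = WILD_TYPE
        else:
            label = UNASSIGNED
        rows.append((read, label, d, w))
    return (
        pd.DataFrame(rows, columns=["read", "label", "votes_derivative", "votes_wildtype"]),
        n_unknown,
    )
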