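"""End-to-end workflows tying the simulator to the resolution machinery.

These are the package's own study designs: simulate a chromothriptic diploid
chromosome with full truth labels, run SV validation, block assignment and
read partitioning, and score every stage against the truth; or lay out a
feature landscape with planted mechanism classes to exercise the
differential/mechanism cascade with known category counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phasing, simulate
from .sv import Breakend, SvCall


@dataclass
class ChromothripsisStudy:
    """A simulated diploid chromosome with chromothripsis on hap1."""

    genome: simulate.ToyGenome
    derivative: str
    truth: simulate.RearrangementTruth
    sources: list
    source_map: dict
    reads: list
    observations: pd.DataFrame
    alignments: pd.DataFrame

    @property
    def chrom(self):
        return self.genome.chromosomes[0]

    def block_truth_labels(self) -> dict[str, str]:
        """Truth label per block: where allele A (hap1 when hap1_is_A) lies.

        Chromothripsis is applied to hap1, so a block whose allele A is the
        hap1 allele belongs to the derivative chromosome.
        """
        pb = self.chrom.phase_blocks
        return dict(
            zip(
                pb["block_id"],
                np.where(pb["hap1_is_A"], phasing.DERIVATIVE, phasing.WILD_TYPE),
            )
        )

    def read_truth_labels(self) -> dict[str, str]:
        return {
            r.name: phasing.DERIVATIVE if r.haplotype == "hap1" else phasing.WILD_TYPE
            for r in self.reads
        }


def simulate_study(
    seed: int,
    length: int = 1_000_000,
    snp_rate: float = 1e-3,
    n_breakpoints: int = 100,
    loss_prob: float = 0.4,
    region: tuple[int, int] | None = None,
    depth: float = 20.0,
    mean_len: int = 12_000,
    error_rate: float = 0.01,
    wt_weight: float = 1.0,
) -> ChromothripsisStudy:
    """Simulate the standard study: hap1 shattered, long reads from both.

    By default the whole chromosome is the shattered region, the toy analogue
    of a chromosome carrying many hundreds of dispersed rearrangements;
    ``wt_weight`` sets the wild-type copy number for asymmetric-CN designs.
    """
    genome = simulate.build_diploid_genome(1, length, snp_rate, seed=seed)
    rec = genome.chromosomes[0]
    if region is None:
        region = (0, rec.length)
    derivative, truth = simulate.apply_chromothripsis(
        genome, rec.name, "hap1", region, n_breakpoints, loss_prob, seed=seed
    )
    sources = [
        (f"{rec.name}_hap1_der", derivative, "hap1", 1.0),
        (f"{rec.name}_hap2", rec.hap2, "hap2", wt_weight),
    ]
    source_map = {sources[0][0]: (rec.name, truth), sources[1][0]: (rec.name, None)}
    reads = simulate.simulate_long_reads(
        sources, depth, mean_len=mean_len, error_rate=error_rate, seed=seed
    )
    observations = simulate.read_snp_observations(reads, genome, source_map)
    alignments = simulate.truth_alignments(reads, source_map)
    return ChromothripsisStudy(
        genome, derivative, truth, sources, source_map, reads, observations, alignments
    )


@dataclass
class RecoveryResult:
    svs: list
    blocks: list
    evidence: list
    assignment: pd.DataFrame
    partition: pd.DataFrame
    n_unknown_obs: int
    block_accuracy: float
    sv_loh_block_accuracy: float
    read_accuracy: float
    n_reads_scored: int
    basis_counts: dict = field(default_factory=dict)


def recover_haplotypes(
    study: ChromothripsisStudy,
    min_support: int = 3,
    expected_cn: tuple[float, float] = (1.0, 1.0),
    withhold_candidates: int = 5,
    seed: int = 0,
) -> RecoveryResult:
    """Run SV validation, block assignment and read partitioning; score vs truth.

    ``withhold_candidates`` drops that many truth junctions from the
    candidate list so the rescue path (junctions found only in the raw reads)
    is exercised on every run.
    """
    rec = study.chrom
    candidates = [
        SvCall(b.breakend1, b.breakend2) for b in study.truth.breakends
    ]
    if withhold_candidates:
        candidates = candidates[:-withhold_candidates] or candidates
    svs = phasing.validate_svs(
        candidates, study.alignments, min_support=min_support
    )
    confirmed = [s for s in svs if s.status in ("validated", "rescued")]
    blocks = phasing.phase_blocks_from_observations(
        study.genome, rec.name, study.observations
    )
    evidence = [
        phasing.score_block_evidence(
            b,
            confirmed,
            study.truth.loh_tracts,
            expected_cn,
            read_obs=study.observations,
        )
        for b in blocks
    ]
    assignment = phasing.assign_blocks(evidence, seed=seed)
    partition, n_unknown = phasing.partition_long_reads(
        study.observations, blocks, assignment, seed=seed
    )

    truth_of = study.block_truth_labels()
    merged = assignment.assign(truth=assignment["block_id"].map(truth_of))
    ok = merged["label"] == merged["truth"]
    ev_basis = merged["basis"].isin(["sv", "loh"])
    read_truth = study.read_truth_labels()
    scored = partition[partition["label"] != phasing.UNASSIGNED]
    read_ok = scored["label"] == scored["read"].map(read_truth)
    return RecoveryResult(
        svs=svs,
        blocks=blocks,
        evidence=evidence,
        assignment=assignment,
        partition=partition,
        n_unknown_obs=n_unknown,
        block_accuracy=float(ok.mean()),
        sv_loh_block_accuracy=float(ok[ev_basis].mean()) if ev_basis.any() else 1.0,
        read_accuracy=float(read_ok.mean()),
        n_reads_scored=int(len(scored)),
        basis_counts=merged["basis"].value_counts().to_dict(),
    )


def planted_mechanism_scenario(
    n_dosage: int,
    n_disruption: int,
    n_unexplained: int,
    n_balanced: int,
    kind: str = "peak",
    feature_width: int = 1_000,
    spacing: int = 3_000,
    diff_counts: tuple[int, int] = (150, 50),
    balanced_counts: tuple[int, int] = (100, 100),
) -> dict:
    """Feature landscape with known mechanism-category counts.

    Four zones of non-overlapping features: dosage features under an
    unbalanced copy-number segment, disruption features each containing one
    breakend of an SV (partner breakend in a feature-free zone), unexplained
    differential features in balanced SV-free territory, and non-differential
    features with symmetric counts.  Differential features get strongly
    imbalanced deterministic counts so the imbalance test recovers exactly
    the planted sets.
    """
    rows = []
    cursor = 0
    zones = {}
    for zone, n in (
        ("dosage", n_dosage),
        ("disruption", n_disruption),
        ("unexplained", n_unexplained),
        ("balanced", n_balanced),
    ):
        zone_start = cursor
        for i in range(n):
            s = cursor
            e = s + feature_width
            c1, c2 = diff_counts if zone != "balanced" else balanced_counts
            rows.append(
                {
                    "feature_id": f"{zone}_{i}",
                    "kind": kind,
                    "start": s,
                    "end": e,
                    "count_hap1": c1,
                    "count_hap2": c2,
                    "zone": zone,
                }
            )
            cursor += spacing
        zones[zone] = (zone_start, cursor)
        cursor += 10 * spacing  # buffer between zones
    junk_start = cursor + 10 * spacing

    features = pd.DataFrame(rows)
    cn_segments = pd.DataFrame(
        [
            {
                "start": zones["dosage"][0],
                "end": zones["dosage"][1],
                "cn_derivative": 2,
                "cn_wildtype": 1,
            }
        ]
        if n_dosage
        else [],
        columns=["start", "end", "cn_derivative", "cn_wildtype"],
    )
    svs = []
    disruption = features[features["zone"] == "disruption"]
    for j, f in enumerate(disruption.itertuples(index=False)):
        mid = (f.start + f.end) // 2
        svs.append(
            SvCall(
                Breakend("chr1", mid, "left"),
                Breakend("chr1", junk_start + j * spacing, "right"),
                status="validated",
                haplotype="hap1",
            )
        )
    return {
        "features": features,
        "cn_segments": cn_segments,
        "loh_tracts": [],
        "svs": svs,
    }
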