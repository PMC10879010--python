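"""Assembly evaluation: contiguity statistics, dot-plot segment maps,
coordinate liftover and reconstruction scoring against simulator truth.

Segment maps are built from unique exact k-mer anchors chained into maximal
colinear runs — a desk-scale substitute for identity-threshold alignment that
is exact on substitution-free sequence and the data structure behind both the
dot plot and the liftover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import revcomp
from .sv import SvCall, junctions_from_segments

TO_REFERENCE = "to-reference"
TO_CONTIG = "to-contig"


# ---------------------------------------------------------------------------
# contiguity
# ---------------------------------------------------------------------------


def nx_lx(lengths, fraction: float) -> tuple[int, int]:
    """Nx/Lx contiguity of a set of contig lengths.

    Lx is the smallest number of contigs (taken longest-first) whose summed
    length reaches ``fraction`` of the total; Nx is the length of the last
    contig needed.  N90/L90 use ``fraction=0.9``.
    """
    lens = sorted((int(x) for x in lengths), reverse=True)
    if not lens:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lens):
        raise ValueError("contig lengths must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    target = fraction * sum(lens)
    acc = 0
    for k, x in enumerate(lens, start=1):
        acc += x
        if acc >= target - 1e-9:
            return x, k
    return lens[-1], len(lens)  # pragma: no cover


# ---------------------------------------------------------------------------
# segment maps
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    contig_start: int
    contig_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # + or -

    @property
    def contig_len(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class SegmentMap:
    """Ordered oriented reference segments composing one contig."""

    contig: str
    contig_length: int
    chrom: str
    segments: list[Segment] = field(default_factory=list)

    def gaps(self) -> list[tuple[int, int]]:
        """Contig intervals not covered by any segment."""
        out = []
        cursor = 0
        for s in sorted(self.segments, key=lambda s: s.contig_start):
            if s.contig_start > cursor:
                out.append((cursor, s.contig_start))
            cursor = max(cursor, s.contig_end)
        if cursor < self.contig_length:
            out.append((cursor, self.contig_length))
        return out

    def walk(self) -> list[tuple[str, int, int, str]]:
        """(chrom, ref_start, ref_end, strand) in contig order."""
        return [
            (s.chrom, s.ref_start, s.ref_end, s.strand)
            for s in sorted(self.segments, key=lambda s: s.contig_start)
        ]


def build_segment_map(
    contig: str,
    reference: str,
    anchor_k: int = 21,
    min_segment: int = 100,
    max_gap: int = 200,
    contig_name: str = "contig",
    ref_name: str = "ref",
) -> SegmentMap:
    """Chain unique exact k-mer anchors into colinear oriented segments.

    K-mers occurring more than once in the reference are discarded, so every
    anchor is unambiguous; anchors on the same diagonal and strand, with
    contig gaps at most ``max_gap``, merge into one segment.  Runs shorter
    than ``min_segment`` on the contig are dropped.
    """
    if anchor_k < 11:
        raise ValueError("anchor_k must be at least 11")
    k = anchor_k
    index: dict[str, int] = {}
    dupes = set()
    for j in range(len(reference) - k + 1):
        km = reference[j : j + k]
        if km in dupes:
            continue
        if km in index:
            del index[km]
            dupes.add(km)
        else:
            index[km] = j

    # anchors: (contig pos, ref pos, strand)
    anchors: list[tuple[int, int, str]] = []
    for i in range(len(contig) - k + 1):
        km = contig[i : i + k]
        j = index.get(km)
        if j is not None:
            anchors.append((i, j, "+"))
            continue
        j = index.get(revcomp(km))
        if j is not None:
            anchors.append((i, j, "-"))

    smap = SegmentMap(contig_name, len(contig), ref_name)
    if not anchors:
        warnings.warn("no unique anchors between contig and reference")
        return smap

    def close_run(run: list[tuple[int, int, str]]):
        i0, j0, strand = run[0]
        i1, j1, _ = run[-1]
        if i1 + k - i0 < min_segment:
            return
        if strand == "+":
            seg = Segment(i0, i1 + k, ref_name, j0, j1 + k, "+")
        else:
            seg = Segment(i0, i1 + k, ref_name, j1, j0 + k, "-")
        smap.segments.append(seg)

    run = [anchors[0]]
    for a in anchors[1:]:
        i, j, strand = a
        pi, pj, pstrand = run[-1]
        diag_ok = (
            strand == pstrand
            and (
                (strand == "+" and j - i == pj - pi and i > pi)
                or (strand == "-" and j + i == pj + pi and i > pi)
            )
        )
        if diag_ok and i - pi <= max_gap:
            run.append(a)
        else:
            close_run(run)
            run = [a]
    close_run(run)
    smap.segments.sort(key=lambda s: s.contig_start)
    return smap


def lift_position(smap: SegmentMap, pos: int, direction: str) -> list[int]:
    """Lift one coordinate across a segment map.

    ``to-reference`` maps a contig position to reference position(s);
    ``to-contig`` maps a reference position back (possibly multiple hits when
    reference intervals occur in several segments, e.g. duplications).  Minus
    segments mirror within the segment.  Positions in unmapped gaps return an
    empty list.
    """
    hits = []
    for s in smap.segments:
        if direction == TO_REFERENCE:
            if s.contig_start <= pos < s.contig_end:
                off = pos - s.contig_start
                hits.append(
                    s.ref_start + off if s.strand == "+" else s.ref_end - 1 - off
                )
        elif direction == TO_CONTIG:
            if s.ref_start <= pos < s.ref_end:
                if s.strand == "+":
                    hits.append(s.contig_start + (pos - s.ref_start))
                else:
                    hits.append(s.contig_start + (s.ref_end - 1 - pos))
        else:
            raise ValueError(f"direction must be {TO_REFERENCE!r} or {TO_CONTIG!r}")
    return hits


def lift_with_orientation(smap: SegmentMap, pos: int) -> list[tuple[int, str]]:
    """Like :func:`lift_position` (to-reference) but keeping segment strand."""
    out = []
    for s in smap.segments:
        if s.contig_start <= pos < s.contig_end:
            off = pos - s.contig_start
            ref = s.ref_start + off if s.strand == "+" else s.ref_end - 1 - off
            out.append((ref, s.strand))
    return out


# ---------------------------------------------------------------------------
# reconstruction accuracy
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionReport:
    junction_precision: float
    junction_recall: float
    n_truth_junctions: int
    n_observed_junctions: int
    collapsed_duplications: int
    fragmentation: int  # observed junctions matching no truth junction


def reconstruction_accuracy(smap: SegmentMap, truth, tol: int = 50) -> ReconstructionReport:
    """Score a segment map against simulator rearrangement truth.

    Observed junctions are the breakend pairs implied by adjacent segments;
    they are matched to the truth breakend list within ``tol`` bp.  A planted
    tandem duplication whose interval is covered by fewer than two segment
    copies counts as collapsed.
    """
    walk = [(truth.chrom, s, e, o) for (_, s, e, o) in smap.walk()]
    observed = [SvCall(b1, b2) for b1, b2 in junctions_from_segments(walk)]
    truth_calls = list(truth.breakends)

    matched_truth = np.zeros(len(truth_calls), bool)
    matched_obs = np.zeros(len(observed), bool)
    for i, obs in enumerate(observed):
        for j, tc in enumerate(truth_calls):
            if obs.matches(tc, tol=tol):
                matched_obs[i] = True
                matched_truth[j] = True
    precision = float(matched_obs.mean()) if observed else 1.0
    recall = float(matched_truth.mean()) if truth_calls else 1.0

    collapsed = 0
    for ds, de in getattr(truth, "duplications", []):
        mid = (ds + de) // 2
        copies = sum(
            1 for s in smap.segments if s.ref_start <= mid < s.ref_end
        )
        if copies < 2:
            collapsed += 1

    return ReconstructionReport(
        junction_precision=precision,
        junction_recall=recall,
        n_truth_junctions=len(truth_calls),
        n_observed_junctions=len(observed),
        collapsed_duplications=collapsed,
        fragmentation=int((~matched_obs).sum()),
    )


# ---------------------------------------------------------------------------
# toy greedy assembler (test fixture)
# ---------------------------------------------------------------------------


@dataclass
class ContigSet:
    contigs: list[tuple[str, int, str]]  # (name, length, sequence)

    @property
    def lengths(self) -> list[int]:
        return [l for _, l, _ in self.contigs]


def toy_greedy_assemble(reads: list[str], min_overlap: int = 500) -> ContigSet:
    """Greedy maximal exact suffix-prefix overlap merging of error-free reads.

    A deliberately simple assembler used as a pipeline fixture: contained
    reads are removed, then the longest exact overlap at least ``min_overlap``
    is merged repeatedly.  Deterministic for a given input order (reads are
    pre-sorted).  Reads shorter than ``min_overlap`` or without overlaps come
    back unmerged.
    """
    seqs = sorted(set(reads))
    # drop reads contained in another read
    keep = []
    for i, r in enumerate(seqs):
        contained = any(r in other for j, other in enumerate(seqs) if i != j)
        if not contained:
            keep.append(r)
    seqs = keep

    mo = min_overlap

    def prefix_index(items: list[str]) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for t, s in enumerate(items):
            if len(s) >= mo:
                idx.setdefault(s[:mo], []).append(t)
        return idx

    merged = True
    while merged and len(seqs) > 1:
        merged = False
        idx = prefix_index(seqs)
        for a_i, a in enumerate(seqs):
            if len(a) < mo:
                continue
            # scan from the largest possible overlap down
            for start in range(max(0, len(a) - max(len(s) for s in seqs)), len(a) - mo + 1):
                if start == 0:
                    continue  # full containment handled above
                for b_i in idx.get(a[start : start + mo], []):
                    if b_i == a_i:
                        continue
                    b = seqs[b_i]
                    ov = len(a) - start
                    if ov <= len(b) and a[start:] == b[:ov]:
                        new = a + b[ov:]
                        seqs = [
                            s for t, s in enumerate(seqs) if t not in (a_i, b_i)
                        ]
                        seqs.append(new)
                        seqs.sort()
                        merged = True
                        break
                if merged:
                    break
            if merged:
                break

    seqs.sort(key=len, reverse=True)
    return ContigSet([(f"contig{i}", len(s), s) for i, s in enumerate(seqs)])
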