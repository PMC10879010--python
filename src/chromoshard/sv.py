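"""Structural-variant junction model shared by the simulator and the callers.

A junction joins two *breakends*.  Each breakend is an oriented chromosome
position: ``side`` says on which side of the position the retained (joined)
sequence lies.  In strand notation a ``left`` breakend is ``+`` (sequence runs
up to the breakpoint from the left) and a ``right`` breakend is ``-``.

The four intra-chromosomal orientation classes follow the usual cancer-genomics
convention once the two breakends are sorted by position:

========  =========================
sides     class
========  =========================
left/right   deletion
right/left   tandem-duplication
left/left    head-to-head inversion
right/right  tail-to-tail inversion
========  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

LEFT = "left"
RIGHT = "right"

DELETION = "deletion"
TANDEM_DUP = "tandem-duplication"
HEAD_TO_HEAD = "head-to-head inversion"
TAIL_TO_TAIL = "tail-to-tail inversion"
TRANSLOCATION = "translocation"

SV_CLASSES = (DELETION, TANDEM_DUP, HEAD_TO_HEAD, TAIL_TO_TAIL, TRANSLOCATION)


@dataclass(frozen=True, order=True)
class Breakend:
    chrom: str
    pos: int
    side: str  # LEFT or RIGHT

    def __post_init__(self):
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"breakend side must be left/right, got {self.side!r}")
        if self.pos < 0:
            raise ValueError("breakend position must be non-negative")


def classify_junction(b1: Breakend, b2: Breakend) -> str:
    """Orientation class of the junction joining two breakends."""
    if b1.chrom != b2.chrom:
        return TRANSLOCATION
    lo, hi = sorted((b1, b2), key=lambda b: (b.pos, b.side))
    pair = (lo.side, hi.side)
    return {
        (LEFT, RIGHT): DELETION,
        (RIGHT, LEFT): TANDEM_DUP,
        (LEFT, LEFT): HEAD_TO_HEAD,
        (RIGHT, RIGHT): TAIL_TO_TAIL,
    }[pair]


@dataclass
class SvCall:
    """A somatic or germline structural-variant call (one junction)."""

    breakend1: Breakend
    breakend2: Breakend
    sv_class: str = ""
    support: int = 0
    status: str = "candidate"  # candidate|validated|rescued|removed|germline
    haplotype: str | None = None  # which haplotype the call was made on
    clonal_fraction: float = 1.0
    supporting_reads: list = field(default_factory=list)

    def __post_init__(self):
        if not self.sv_class:
            self.sv_class = classify_junction(self.breakend1, self.breakend2)
        if self.support < 0:
            raise ValueError("support must be non-negative")
        # normalise breakend order for stable matching
        if (self.breakend2.chrom, self.breakend2.pos, self.breakend2.side) < (
            self.breakend1.chrom,
            self.breakend1.pos,
            self.breakend1.side,
        ):
            self.breakend1, self.breakend2 = self.breakend2, self.breakend1

    @property
    def size(self) -> int | None:
        """|pos2 - pos1| for intra-chromosomal junctions, else None."""
        if self.breakend1.chrom != self.breakend2.chrom:
            return None
        return abs(self.breakend2.pos - self.breakend1.pos)

    def key(self) -> tuple:
        return (
            self.breakend1.chrom,
            self.breakend1.pos,
            self.breakend1.side,
            self.breakend2.chrom,
            self.breakend2.pos,
            self.breakend2.side,
        )

    def matches(self, other: "SvCall", tol: int = 50) -> bool:
        """Same junction up to ``tol`` bp per breakend (sides must agree)."""
        a1, a2, b1, b2 = self.breakend1, self.breakend2, other.breakend1, other.breakend2
        return (
            a1.chrom == b1.chrom
            and a2.chrom == b2.chrom
            and a1.side == b1.side
            and a2.side == b2.side
            and abs(a1.pos - b1.pos) <= tol
            and abs(a2.pos - b2.pos) <= tol
        )

    def with_status(self, status: str, support: int | None = None) -> "SvCall":
        new = replace(self)
        new.status = status
        if support is not None:
            new.support = support
        return new


def junctions_from_segments(
    segments: Sequence[tuple[str, int, int, str]]
) -> list[tuple[Breakend, Breakend]]:
    """Breakend pairs implied by an ordered, oriented segment walk.

    ``segments`` is a list of ``(chrom, start, end, strand)`` with half-open
    coordinates, in the order they occur along a derivative sequence (or along
    one read's split alignment).  Reference-adjacent same-strand neighbours do
    not create a junction.
    """
    out: list[tuple[Breakend, Breakend]] = []
    for (c1, s1, e1, o1), (c2, s2, e2, o2) in zip(segments, segments[1:]):
        if c1 == c2 and o1 == o2 == "+" and e1 == s2:
            continue
        if c1 == c2 and o1 == o2 == "-" and e2 == s1:
            continue
        b1 = Breakend(c1, e1, LEFT) if o1 == "+" else Breakend(c1, s1, RIGHT)
        b2 = Breakend(c2, s2, RIGHT) if o2 == "+" else Breakend(c2, e2, LEFT)
        out.append((b1, b2))
    return out


def dedupe_junctions(
    junctions: Iterable[tuple[Breakend, Breakend]], tol: int = 0
) -> list[SvCall]:
    """Collapse a junction stream into SvCalls with per-junction support counts."""
    calls: list[SvCall] = []
    for b1, b2 in junctions:
        cand = SvCall(b1, b2, support=1)
        for existing in calls:
            if existing.matches(cand, tol=tol):
                existing.support += 1
                break
        else:
            calls.append(cand)
    return calls
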