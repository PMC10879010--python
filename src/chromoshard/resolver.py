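"""Dual-assembly arbitration of functional reads (ChIP/ATAC/Hi-C/transcript).

Every read (or read pair) is aligned to both haplotype assemblies; the
resolver decides which haplotype it came from using, in order of precedence:

1. **snp** — het-site base matches favouring one assembly;
2. **loh** — mapping into a loss-of-heterozygosity region present on only
   one haplotype;
3. **mapq** — a mapping-quality difference of at least ``mapq_margin``
   (a read absent from one assembly scores mapq 0 there);
4. **distance** — for Hi-C pairs, a weighted-probability contact-distance
   model: the mate separation is scored under an empirical log-binned
   distribution with a power-law tail, and the read pair goes to the assembly
   with the higher likelihood when the log-likelihood ratio clears a
   threshold (mates landing on different contigs score the trans mass);
5. **random** — identical evidence on both assemblies; the label is a seeded
   coin flip keyed by read name, so it is reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import stable_rng

HAP_A = "hapA"
HAP_B = "hapB"


@dataclass
class AssemblyHit:
    """One read's alignment record against one assembly."""

    present: bool = True
    position: int | None = None
    blocks: list[tuple[int, int]] = field(default_factory=list)  # spliced ok
    mapq: int = 60
    snp_matches: int = 0  # het sites where the read base equals this assembly
    snp_sites: int = 0
    in_loh: bool = False
    mate_separation: float | None = None  # pairs; None = mates on different contigs


@dataclass
class DualAlignment:
    read: str
    datatype: str
    hap_a: AssemblyHit | None = None
    hap_b: AssemblyHit | None = None

    @staticmethod
    def _present(hit: AssemblyHit | None) -> bool:
        return hit is not None and hit.present


@dataclass
class ReadAssignment:
    read: str
    datatype: str
    label: str | None  # hapA / hapB / None for error records
    basis: str  # snp | loh | mapq | distance | random | error
    score: float = 0.0


@dataclass
class DistanceModel:
    """Empirical log-binned cis-separation distribution with power-law tail."""

    edges: np.ndarray  # n_bins + 1 log-spaced bin edges
    probs: np.ndarray  # per-bin probability; sums to 1 - trans_prob
    tail_alpha: float
    trans_prob: float

    def log_prob(self, separation: float | None) -> float:
        """Log density of one mate separation (None/NaN = trans).

        The trans mass is spread uniformly over the modelled span so that
        trans events and cis separations are scored on the same (per-bp
        density) scale.
        """
        if separation is None or (isinstance(separation, float) and np.isnan(separation)):
            return float(np.log(max(self.trans_prob, 1e-12) / self.edges[-1]))
        d = float(separation)
        widths = np.diff(self.edges)
        if d < self.edges[0]:
            return float(np.log(self.probs[0] / widths[0]))
        if d >= self.edges[-1]:
            # power-law extrapolation from the last bin centre
            c = float(np.sqrt(self.edges[-2] * self.edges[-1]))
            dens = self.probs[-1] / widths[-1]
            dens *= (d / c) ** (-self.tail_alpha)
            return float(np.log(max(dens, 1e-300)))
        i = int(np.searchsorted(self.edges, d, side="right") - 1)
        return float(np.log(self.probs[i] / widths[i]))


def fit_contact_distance_model(
    separations,
    n_bins: int = 30,
    trans_prob: float = 0.05,
    min_bin_count: int = 5,
    edges: np.ndarray | None = None,
) -> DistanceModel:
    """Fit the weighted-probability contact-distance model from cis pairs.

    Separations are histogrammed in log-spaced bins with add-one smoothing;
    the power-law tail exponent comes from a log-log regression of bin
    density against bin centre over the well-populated upper half of the
    distribution.  Probabilities sum to 1 together with the trans mass.
    """
    seps = np.asarray([s for s in np.asarray(separations, float) if np.isfinite(s)])
    if seps.size == 0:
        raise ValueError("no cis separations to fit")
    if not 0 <= trans_prob < 1:
        raise ValueError("trans_prob must lie in [0, 1)")
    if edges is None:
        d_min = max(1.0, seps.min())
        d_max = seps.max() * (1 + 1e-9)
        edges = np.geomspace(d_min, d_max, n_bins + 1)
    else:
        edges = np.asarray(edges, float)
        n_bins = edges.size - 1
    counts, _ = np.histogram(seps, bins=edges)
    smoothed = counts + 1.0
    probs = smoothed / smoothed.sum() * (1 - trans_prob)

    centers = np.sqrt(edges[:-1] * edges[1:])
    widths = np.diff(edges)
    dens = smoothed / smoothed.sum() / widths
    populated = np.flatnonzero(counts >= min_bin_count)
    fit_idx = populated[len(populated) // 2 :] if populated.size >= 4 else populated
    if fit_idx.size >= 2:
        slope = np.polyfit(np.log(centers[fit_idx]), np.log(dens[fit_idx]), 1)[0]
        alpha = float(-slope)
    else:
        alpha = 1.0
    return DistanceModel(edges=edges, probs=probs, tail_alpha=alpha, trans_prob=trans_prob)


# ---------------------------------------------------------------------------
# arbitration
# ---------------------------------------------------------------------------


def _coin(seed: int, read: str) -> str:
    return HAP_A if stable_rng(seed, "resolve", read).random() < 0.5 else HAP_B


def _snp_loh_mapq(
    d: DualAlignment, mapq_margin: int
) -> tuple[str, str, float] | None:
    a, b = d.hap_a, d.hap_b
    pa, pb = DualAlignment._present(a), DualAlignment._present(b)
    ma = a.snp_matches if pa else 0
    mb = b.snp_matches if pb else 0
    if ma != mb:
        return (HAP_A if ma > mb else HAP_B, "snp", float(ma - mb))
    la = pa and a.in_loh
    lb = pb and b.in_loh
    if la != lb:
        return (HAP_A if la else HAP_B, "loh", 0.0)
    qa = a.mapq if pa else 0
    qb = b.mapq if pb else 0
    if abs(qa - qb) >= mapq_margin:
        return (HAP_A if qa > qb else HAP_B, "mapq", float(qa - qb))
    return None


def resolve_read(
    d: DualAlignment, mapq_margin: int = 10, seed: int = 0
) -> ReadAssignment:
    """Arbitrate a single read: snp > loh > mapq > random.

    A read absent from both assemblies yields an error record (label None,
    basis ``error``), which :func:`assignment_rates` excludes.
    """
    if not DualAlignment._present(d.hap_a) and not DualAlignment._present(d.hap_b):
        return ReadAssignment(d.read, d.datatype, None, "error")
    hit = _snp_loh_mapq(d, mapq_margin)
    if hit is not None:
        label, basis, score = hit
        return ReadAssignment(d.read, d.datatype, label, basis, score)
    return ReadAssignment(d.read, d.datatype, _coin(seed, d.read), "random")


def resolve_hic_pair(
    d: DualAlignment,
    model: DistanceModel,
    llr_threshold: float = 1.0,
    mapq_margin: int = 10,
    seed: int = 0,
) -> ReadAssignment:
    """Arbitrate a Hi-C pair: snp/loh first, then the distance model.

    The pair's per-assembly hits carry SNP matches summed over both mates and
    the mate separation on that assembly (None when the mates land on
    different contigs, scored as trans).  The label goes to the assembly with
    the higher separation likelihood when |log LR| >= ``llr_threshold``; an
    exact tie of all evidence falls through to a seeded random label.
    """
    if not DualAlignment._present(d.hap_a) and not DualAlignment._present(d.hap_b):
        return ReadAssignment(d.read, d.datatype, None, "error")
    hit = _snp_loh_mapq(d, mapq_margin)
    if hit is not None and hit[1] in ("snp", "loh"):
        label, basis, score = hit
        return ReadAssignment(d.read, d.datatype, label, basis, score)
    sep_a = d.hap_a.mate_separation if DualAlignment._present(d.hap_a) else None
    sep_b = d.hap_b.mate_separation if DualAlignment._present(d.hap_b) else None
    llr = model.log_prob(sep_a) - model.log_prob(sep_b)
    if abs(llr) >= llr_threshold:
        label = HAP_A if llr > 0 else HAP_B
        return ReadAssignment(d.read, d.datatype, label, "distance", float(llr))
    return ReadAssignment(d.read, d.datatype, _coin(seed, d.read), "random", float(llr))


def resolve_reads(
    alignments: list[DualAlignment],
    model: DistanceModel | None = None,
    mapq_margin: int = 10,
    llr_threshold: float = 1.0,
    seed: int = 0,
) -> list[ReadAssignment]:
    """Arbitrate a batch, routing Hi-C pairs through the distance model."""
    out = []
    for d in alignments:
        has_sep = any(
            h is not None and h.mate_separation is not None for h in (d.hap_a, d.hap_b)
        )
        if model is not None and (d.datatype == "hic-end" or has_sep):
            out.append(resolve_hic_pair(d, model, llr_threshold, mapq_margin, seed))
        else:
            out.append(resolve_read(d, mapq_margin, seed))
    return out


def assignment_rates(assignments: list[ReadAssignment]) -> pd.DataFrame:
    """Fraction of reads assigned on real evidence (basis != random) per datatype."""
    rows = [
        (a.datatype, a.basis)
        for a in assignments
        if a.basis != "error" and a.label is not None
    ]
    df = pd.DataFrame(rows, columns=["datatype", "basis"])
    if df.empty:
        return pd.DataFrame(columns=["datatype", "n", "n_assigned", "rate"])
    out = (
        df.assign(assigned=df["basis"] != "random")
        .groupby("datatype")
        .agg(n=("basis", "size"), n_assigned=("assigned", "sum"))
        .reset_index()
    )
    out["rate"] = out["n_assigned"] / out["n"]
    pooled = pd.DataFrame(
        [
            {
                "datatype": "all",
                "n": out["n"].sum(),
                "n_assigned": out["n_assigned"].sum(),
                "rate": out["n_assigned"].sum() / out["n"].sum(),
            }
        ]
    )
    return pd.concat([out, pooled], ignore_index=True)
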