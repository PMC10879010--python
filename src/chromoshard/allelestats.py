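"""Allele-specific feature statistics.

Peaks and genes carry read counts for the two parental haplotypes.  This
module tests each feature for allelic imbalance (exact binomial test with
Benjamini-Hochberg control, the per-haplotype-count stand-in for a
count-model Wald test), explains differential features through a mechanism
cascade (dosage from copy-number/LOH imbalance, then direct disruption by a
breakend inside the feature, then unexplained), and provides the downstream
comparisons: nearest-breakend distances per direction group, SV size
summaries, cross-sample stability correlation, fusion-transcript detection on
the derivative assembly, and gene-to-peak-class distances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import SegmentMap, lift_with_orientation

ACTIVE_MARKS = ("H3K27ac", "H3K4me3", "ATAC", "CTCF")
INACTIVE_MARKS = ("H3K27me3",)

STRONGER = "stronger-on-derivative"
WEAKER = "weaker-on-derivative"
NONE = "none"

DOSAGE = "dosage"
DIRECT_DISRUPTION = "direct_disruption"
UNEXPLAINED = "unexplained"


# ---------------------------------------------------------------------------
# imbalance testing
# ---------------------------------------------------------------------------


def exact_binom_pvalues(k, n, p=0.5) -> np.ndarray:
    """Vectorised two-sided exact binomial p-values (minimum-likelihood rule).

    The p-value sums P(X=j) over all j whose probability does not exceed the
    observed one (with the customary 1+1e-7 relative guard), the same
    definition the scipy reference test uses; results agree with
    ``scipy.stats.binomtest`` to floating precision.
    """
    k = np.asarray(k, int)
    n = np.asarray(n, int)
    p = np.broadcast_to(np.asarray(p, float), k.shape).copy()
    out = np.empty(k.shape, float)
    for (ni, pi) in set(zip(n.tolist(), p.tolist())):
        sel = (n == ni) & (p == pi)
        pmf = stats.binom.pmf(np.arange(ni + 1), ni, pi)
        thresh = pmf[k[sel]] * (1 + 1e-7)
        out[sel] = (pmf[None, :] * (pmf[None, :] <= thresh[:, None])).sum(axis=1)
    return np.minimum(out, 1.0)


def allelic_imbalance_test(
    counts: pd.DataFrame,
    fdr_q: float = 0.05,
    derivative: str = "hap1",
) -> pd.DataFrame:
    """Per-feature allelic-imbalance test with BH correction.

    ``counts`` needs ``feature_id``, ``count_hap1`` and ``count_hap2``; an
    optional ``expected_p`` column gives the CN-adjusted null proportion of
    derivative-haplotype reads (default 0.5).  Features with zero total count
    are skipped (``tested=False``) and reported, not dropped.  ``differential``
    is q < ``fdr_q``; ``direction`` is relative to the derivative haplotype
    (``derivative`` names its count column suffix).
    """
    for col in ("feature_id", "count_hap1", "count_hap2"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    neg = (counts["count_hap1"] < 0) | (counts["count_hap2"] < 0)
    if neg.any():
        raise ValueError("counts must be non-negative integers")
    out = counts.copy().reset_index(drop=True)
    der_col = f"count_{derivative}"
    other_col = "count_hap2" if derivative == "hap1" else "count_hap1"
    k = out[der_col].to_numpy(int)
    n = (out[der_col] + out[other_col]).to_numpy(int)
    p0 = (
        out["expected_p"].to_numpy(float)
        if "expected_p" in out.columns
        else np.full(len(out), 0.5)
    )
    tested = n > 0
    pvals = np.full(len(out), np.nan)
    if tested.any():
        pvals[tested] = exact_binom_pvalues(k[tested], n[tested], p0[tested])
    qvals = np.full(len(out), np.nan)
    if tested.any():
        qvals[tested] = stats.false_discovery_control(pvals[tested])
    out["tested"] = tested
    out["p_value"] = pvals
    out["q_value"] = qvals
    out["differential"] = tested & (qvals < fdr_q)
    with np.errstate(invalid="ignore"):
        frac = np.divide(k, n, out=np.full(len(out), np.nan), where=n > 0)
    out["direction"] = np.where(
        out["differential"], np.where(frac > p0, STRONGER, WEAKER), NONE
    )
    return out


# ---------------------------------------------------------------------------
# mechanism cascade
# ---------------------------------------------------------------------------


def _overlaps(starts, ends, s, e) -> np.ndarray:
    return (starts < e) & (ends > s)


def classify_mechanism(
    features: pd.DataFrame,
    cn_segments: pd.DataFrame | None = None,
    loh_tracts: list[tuple[int, int]] | None = None,
    svs=None,
) -> pd.DataFrame:
    """Explain each differential feature, in cascade order.

    1. **dosage** — the feature overlaps a region of unequal per-haplotype
       copy number (``cn_segments`` columns start/end/cn_derivative/
       cn_wildtype) or an LOH tract;
    2. **direct_disruption** — a breakend of a validated SV lies inside the
       feature interval;
    3. **unexplained** — neither applies.

    Only rows with ``differential`` true are classified; the categories are
    mutually exclusive and partition the differential set.
    """
    diff = features[features["differential"]].copy()
    if cn_segments is None:
        warnings.warn("no copy-number track supplied; skipping dosage step")
        unbalanced = pd.DataFrame(columns=["start", "end"])
    else:
        unbalanced = cn_segments[
            cn_segments["cn_derivative"] != cn_segments["cn_wildtype"]
        ]
    loh = loh_tracts or []
    breakends = []
    for call in svs or []:
        if call.status in ("validated", "rescued", "truth", "candidate"):
            breakends.extend([call.breakend1.pos, call.breakend2.pos])
    breakends = np.asarray(sorted(breakends))

    mechanisms = []
    ub_s = unbalanced["start"].to_numpy()
    ub_e = unbalanced["end"].to_numpy()
    for f in diff.itertuples(index=False):
        dosage = bool(_overlaps(ub_s, ub_e, f.start, f.end).any()) or any(
            s < f.end and e > f.start for s, e in loh
        )
        if dosage:
            mechanisms.append(DOSAGE)
            continue
        if breakends.size:
            i = np.searchsorted(breakends, f.start, side="left")
            inside = i < breakends.size and breakends[i] < f.end
        else:
            inside = False
        mechanisms.append(DIRECT_DISRUPTION if inside else UNEXPLAINED)
    return pd.DataFrame({"feature_id": diff["feature_id"], "mechanism": mechanisms})


def differential_summary(features: pd.DataFrame, mechanisms: pd.DataFrame) -> dict:
    """Counts and percentages of the differential set over resolved features.

    Percentages are of the resolved (tested) denominator, matching how
    mechanism categories are usually reported: each category's share of all
    resolved features, so that category percentages sum to the differential
    percentage.
    """
    n_resolved = int(features["tested"].sum()) if "tested" in features else len(features)
    n_diff = int(features["differential"].sum())
    counts = mechanisms["mechanism"].value_counts().to_dict()
    out = {
        "n_resolved": n_resolved,
        "n_differential": n_diff,
        "pct_differential": 100.0 * n_diff / n_resolved if n_resolved else float("nan"),
    }
    for cat in (DOSAGE, DIRECT_DISRUPTION, UNEXPLAINED):
        c = int(counts.get(cat, 0))
        out[f"n_{cat}"] = c
        out[f"pct_{cat}"] = 100.0 * c / n_resolved if n_resolved else float("nan")
    return out


# ---------------------------------------------------------------------------
# distance analyses
# ---------------------------------------------------------------------------


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (no_ties and max(x.size, y.size) <= 12) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _interval_point_distance(start, end, pos) -> int:
    if pos < start:
        return start - pos
    if pos > end - 1:
        return pos - (end - 1)
    return 0


def nearest_breakend_distances(features: pd.DataFrame, svs) -> np.ndarray:
    """Distance of each feature to its nearest SV breakend (0 when inside)."""
    breakends = sorted(
        b.pos for call in svs for b in (call.breakend1, call.breakend2)
    )
    if not breakends:
        raise ValueError("no SVs: distances undefined")
    bp = np.asarray(breakends)
    out = np.empty(len(features), int)
    for i, f in enumerate(features.itertuples(index=False)):
        j1 = np.searchsorted(bp, f.start, side="left")
        j2 = np.searchsorted(bp, f.end, side="left")
        if j2 > j1:  # a breakend falls inside the feature
            out[i] = 0
            continue
        cands = []
        if j1 > 0:
            cands.append(int(bp[j1 - 1]))
        if j1 < bp.size:
            cands.append(int(bp[j1]))
        out[i] = min(_interval_point_distance(f.start, f.end, p) for p in cands)
    return out


def nearest_breakend_analysis(
    features: pd.DataFrame,
    svs,
    threshold_bp: int = 10_000,
    group_col: str = "direction",
) -> dict:
    """Per-direction-group distance-to-nearest-breakend comparison.

    Returns group medians, the fraction of each group within ``threshold_bp``
    of a breakend, and two-sided rank-sum p-values for every group pair.
    """
    dist = nearest_breakend_distances(features, svs)
    feats = features.copy()
    feats["_dist"] = dist
    groups = {g: grp["_dist"].to_numpy() for g, grp in feats.groupby(group_col)}
    per_group = {
        g: {
            "n": int(v.size),
            "median": float(np.median(v)),
            "frac_within": float((v < threshold_bp).mean()),
        }
        for g, v in groups.items()
    }
    names = sorted(groups)
    pairwise = {
        (g1, g2): rank_sum_test(groups[g1], groups[g2])
        for i, g1 in enumerate(names)
        for g2 in names[i + 1 :]
    }
    return {"groups": per_group, "pairwise_p": pairwise, "distances": groups}


def sv_summary(svs) -> pd.DataFrame:
    """Per-haplotype SV counts and size-class fractions.

    Size classes follow the usual reporting: the fraction of intra-chromosomal
    junctions whose breakends are separated by more than 1 Mb, and the
    fraction under 1 kb.  Fractions are NaN for haplotypes without sized
    calls.
    """
    rows = []
    by_hap: dict[str, list] = {}
    for call in svs:
        by_hap.setdefault(call.haplotype or "unknown", []).append(call)
    for hap, calls in sorted(by_hap.items()):
        sizes = np.asarray([c.size for c in calls if c.size is not None], float)
        rows.append(
            {
                "haplotype": hap,
                "n": len(calls),
                "n_intra": sizes.size,
                "frac_over_1mb": float((sizes > 1e6).mean()) if sizes.size else np.nan,
                "frac_under_1kb": float((sizes < 1e3).mean()) if sizes.size else np.nan,
                "median_size": float(np.median(sizes)) if sizes.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def correlate_shared_features(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    id_col: str = "feature_id",
    count_col: str | None = None,
) -> dict:
    """Cross-sample stability of shared features.

    Pearson r and p on log2(count+1) over features present in both tables,
    plus the gained (zero in A, nonzero in B) and lost (converse) sets.
    """

    def values(df):
        if count_col is not None:
            return df[count_col]
        if "count" in df.columns:
            return df["count"]
        return df["count_hap1"] + df["count_hap2"]

    a = table_a.set_index(id_col)
    b = table_b.set_index(id_col)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared features")
    va = values(a.loc[shared]).to_numpy(float)
    vb = values(b.loc[shared]).to_numpy(float)
    r, p = stats.pearsonr(np.log2(va + 1), np.log2(vb + 1))
    gained = [str(i) for i, x, y in zip(shared, va, vb) if x == 0 and y > 0]
    lost = [str(i) for i, x, y in zip(shared, va, vb) if x > 0 and y == 0]
    return {
        "r": float(r),
        "p": float(p),
        "n_shared": int(len(shared)),
        "gained": gained,
        "lost": lost,
    }


# ---------------------------------------------------------------------------
# fusion transcripts and peak-class distances
# ---------------------------------------------------------------------------


def detect_fusion_transcripts(
    transcripts: list[tuple[str, list[tuple[int, int]]]],
    smap: SegmentMap,
    min_jump: int = 1_000_000,
) -> tuple[pd.DataFrame, list[str]]:
    """Find transcripts whose exon chains straddle rearrangement junctions.

    Each transcript is ``(name, [(exon_start, exon_end), ...])`` in derivative
    assembly coordinates.  Consecutive exons are lifted to the reference; a
    fusion is called when the lifted positions jump more than ``min_jump`` or
    change orientation.  Transcripts with an exon in an unaligned gap are
    returned separately as unresolvable.
    """
    calls = []
    unresolvable = []
    for name, exons in transcripts:
        lifted = []
        ok = True
        for s, e in exons:
            h1 = lift_with_orientation(smap, s)
            h2 = lift_with_orientation(smap, e - 1)
            if not h1 or not h2:
                ok = False
                break
            lifted.append((h1[0], h2[0]))
        if not ok:
            unresolvable.append(name)
            continue
        for i in range(len(lifted) - 1):
            (_, (end_pos, end_strand)) = lifted[i]
            ((start_pos, start_strand), _) = lifted[i + 1]
            jump = abs(start_pos - end_pos)
            flip = end_strand != start_strand
            if jump > min_jump or flip:
                calls.append(
                    {
                        "transcript": name,
                        "exon_index": i,
                        "ref_pos1": int(end_pos),
                        "ref_pos2": int(start_pos),
                        "jump": int(jump),
                        "orientation_change": bool(flip),
                    }
                )
    cols = ["transcript", "exon_index", "ref_pos1", "ref_pos2", "jump",
            "orientation_change"]
    return pd.DataFrame(calls, columns=cols), unresolvable


def _interval_distance(s1, e1, s2, e2) -> int:
    return max(0, max(s1, s2) - min(e1, e2))


def gene_to_peak_class_distance(
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    active_marks=ACTIVE_MARKS,
    group_col: str = "direction",
) -> dict:
    """Distance from gene groups to the nearest active / inactive peak.

    Peak classes partition the differential peaks by mark (active: e.g.
    H3K27ac/H3K4me3/ATAC/CTCF; inactive: H3K27me3).  For each class, gene
    groups (by ``group_col``) are compared pairwise with the rank-sum test.
    Empty classes are skipped.
    """
    diff_peaks = peaks[peaks["differential"]]
    classes = {
        "active": diff_peaks[diff_peaks["mark"].isin(active_marks)],
        "inactive": diff_peaks[~diff_peaks["mark"].isin(active_marks)],
    }
    out = {}
    for cls, pk in classes.items():
        if pk.empty:
            continue
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        dists = np.array(
            [
                min(
                    _interval_distance(g.start, g.end, int(s), int(e))
                    for s, e in zip(ps, pe)
                )
                for g in genes.itertuples(index=False)
            ]
        )
        feats = genes.copy()
        feats["_dist"] = dists
        groups = {g: grp["_dist"].to_numpy() for g, grp in feats.groupby(group_col)}
        names = sorted(groups)
        out[cls] = {
            "medians": {g: float(np.median(v)) for g, v in groups.items()},
            "pairwise_p": {
                (g1, g2): rank_sum_test(groups[g1], groups[g2])
                for i, g1 in enumerate(names)
                for g2 in names[i + 1 :]
            },
            "distances": groups,
        }
    return out
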