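"""Contact-matrix binning, insulation-style boundary signal, TAD boundary
calls at multiple resolutions, and haplotype TAD-size comparison.

The boundary signal is the standard insulation score: for each bin, the sum
of contacts in a diamond spanning ``window_bins`` on each side of the bin,
normalised to mean 1 over the valid (non-edge) bins.  Topological domain
boundaries are local minima of that score with a prominence threshold;
domains are the regions between successive boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .allelestats import rank_sum_test

DEFAULT_RESOLUTIONS = (150_000, 250_000, 500_000, 750_000, 1_000_000)


@dataclass
class ContactMatrix:
    chrom: str
    resolution: int
    matrix: np.ndarray  # symmetric counts
    n_cis: int
    n_trans: int = 0
    n_rejected: int = 0

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def bin_pairs(
    pairs: pd.DataFrame,
    resolution: int,
    chrom_length: int,
    chrom: str = "chr1",
) -> ContactMatrix:
    """Bin cis contact pairs into a symmetric count matrix.

    ``pairs`` needs columns source1/pos1/source2/pos2 (or chrom1/chrom2
    aliases).  Trans pairs (different source) are excluded and counted;
    records with positions beyond ``chrom_length`` are rejected and counted.
    The upper triangle plus diagonal sums to the number of cis pairs kept.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    df = pairs.rename(columns={"chrom1": "source1", "chrom2": "source2"})
    n_bins = int(np.ceil(chrom_length / resolution))
    mat = np.zeros((n_bins, n_bins), dtype=np.int64)
    trans = df["source1"] != df["source2"]
    n_trans = int(trans.sum())
    cis = df[~trans]
    p1 = cis["pos1"].to_numpy(int)
    p2 = cis["pos2"].to_numpy(int)
    bad = (p1 < 0) | (p2 < 0) | (p1 >= chrom_length) | (p2 >= chrom_length)
    n_rejected = int(bad.sum())
    b1 = p1[~bad] // resolution
    b2 = p2[~bad] // resolution
    np.add.at(mat, (b1, b2), 1)
    off = b1 != b2
    np.add.at(mat, (b2[off], b1[off]), 1)
    return ContactMatrix(chrom, resolution, mat, int((~bad).sum()), n_trans, n_rejected)


def boundary_signal(matrix: np.ndarray, window_bins: int = 10) -> np.ndarray:
    """Insulation score per bin, mean-normalised; edge bins are NaN-masked.

    The score for bin *i* sums contacts between the ``window_bins`` bins to
    its left and the ``window_bins`` bins to its right (the "diamond"), so a
    bin separating two dense blocks with few cross-contacts scores low.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    m = np.asarray(matrix, float)
    n = m.shape[0]
    if n < 2 * window_bins + 1:
        raise ValueError("matrix smaller than twice the window")
    sig = np.full(n, np.nan)
    w = window_bins
    for i in range(w, n - w):
        sig[i] = m[i - w : i, i + 1 : i + 1 + w].sum()
    valid = ~np.isnan(sig)
    mean = np.nanmean(sig)
    if mean > 0:
        sig[valid] = sig[valid] / mean
    return sig


def call_boundaries(
    signal: np.ndarray,
    prominence: float = 0.2,
    resolution: int | None = None,
) -> pd.DataFrame:
    """Local minima of the insulation signal with at least the given prominence."""
    sig = np.asarray(signal, float)
    valid = ~np.isnan(sig)
    if not valid.any():
        return pd.DataFrame(columns=["bin", "signal", "resolution"])
    # extend the nearest valid value over the masked edges so the mask
    # itself never creates (or destroys) a minimum
    filled = sig.copy()
    first, last = np.flatnonzero(valid)[[0, -1]]
    filled[:first] = sig[first]
    filled[last + 1 :] = sig[last]
    inner = np.isnan(filled)
    if inner.any():
        good = np.flatnonzero(~inner)
        filled[inner] = np.interp(np.flatnonzero(inner), good, filled[good])
    idx, _ = find_peaks(-filled, prominence=prominence)
    idx = idx[valid[idx]]
    return pd.DataFrame(
        {"bin": idx, "signal": sig[idx], "resolution": resolution}
    )


def call_boundaries_multi(
    pairs: pd.DataFrame,
    chrom_length: int,
    resolutions=DEFAULT_RESOLUTIONS,
    window_bins: int = 10,
    prominence: float = 0.2,
    chrom: str = "chr1",
) -> dict[int, pd.DataFrame]:
    """Boundary calls at several resolutions to expose the TAD hierarchy."""
    out = {}
    for res in resolutions:
        cm = bin_pairs(pairs, res, chrom_length, chrom=chrom)
        if cm.n_bins < 2 * window_bins + 1:
            out[res] = pd.DataFrame(columns=["bin", "signal", "resolution"])
            continue
        sig = boundary_signal(cm.matrix, window_bins)
        out[res] = call_boundaries(sig, prominence, resolution=res)
    return out


def tad_size_comparison(
    boundaries_a: pd.DataFrame,
    boundaries_b: pd.DataFrame,
    resolution: int,
) -> dict:
    """Compare TAD sizes between two haplotypes at one resolution.

    TADs are the regions between successive boundary calls; sizes are the
    boundary gaps times the resolution.  Returns sizes, medians and the
    two-sided rank-sum p-value (None when a haplotype has fewer than two
    boundaries, as sizes are then undefined).
    """

    def sizes(b: pd.DataFrame):
        bins = np.sort(b["bin"].to_numpy())
        if bins.size < 2:
            return None
        return np.diff(bins) * resolution

    sa, sb = sizes(boundaries_a), sizes(boundaries_b)
    out = {
        "sizes_a": None if sa is None else sa.tolist(),
        "sizes_b": None if sb is None else sb.tolist(),
        "median_a": None if sa is None else float(np.median(sa)),
        "median_b": None if sb is None else float(np.median(sb)),
        "p": None,
    }
    if sa is not None and sb is not None:
        out["p"] = rank_sum_test(sa, sb)
    return out
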