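"""Call TAD boundaries on both haplotypes and compare domain sizes.

Simulates Hi-C pairs with planted domains — larger on the "derivative"
haplotype — bins them into contact matrices, computes the insulation-style
boundary signal, calls boundaries as prominent local minima, and tests the
domain-size difference with the rank-sum test.
"""

import numpy as np
import pandas as pd

from chromoshard import tads

L = 10_000_000
rng = np.random.default_rng(4)


def planted_pairs(tad_size, n_pairs):
    rows = []
    n_tads = L // tad_size
    for _ in range(n_pairs):
        t = rng.integers(0, n_tads)
        a, b = rng.integers(t * tad_size, (t + 1) * tad_size, size=2)
        rows.append(("chr", int(a), "chr", int(b)))
    return pd.DataFrame(rows, columns=["source1", "pos1", "source2", "pos2"])


res = 100_000
boundaries = {}
for hap, tad_size in (("wild-type", 500_000), ("derivative", 1_000_000)):
    cm = tads.bin_pairs(planted_pairs(tad_size, 200_000), res, L)
    sig = tads.boundary_signal(cm.matrix, window_bins=2)
    calls = tads.call_boundaries(sig, prominence=0.2, resolution=res)
    boundaries[hap] = calls
    print(f"{hap}: {cm.n_cis:,} cis pairs -> {len(calls)} boundaries at "
          f"{res // 1000}-kb bins")

cmp = tads.tad_size_comparison(
    boundaries["derivative"], boundaries["wild-type"], res
)
print(f"median TAD size: derivative {cmp['median_a'] / 1e6:.1f} Mb vs "
      f"wild-type {cmp['median_b'] / 1e6:.1f} Mb (rank-sum p = {cmp['p']:.2g})")
# A significantly larger derivative median mirrors the loss of fine-grained
# domain structure expected when rearrangement shuffles boundary elements.
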