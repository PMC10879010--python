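"""Shared helpers: seeded, order-independent randomness and interval arithmetic."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def stable_rng(seed: int, *keys) -> np.random.Generator:
    """Generator keyed by a global seed plus arbitrary string/int keys.

    The same (seed, keys) always yields the same stream regardless of call
    order, so per-block / per-read random decisions are reproducible even when
    the iteration order changes.
    """
    material = ":".join(str(k) for k in keys).encode()
    sub = zlib.crc32(material) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & MAX_SEED, sub])


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the overlap between two half-open intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def point_to_interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from a point to a half-open interval (0 when inside)."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


REVCOMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]
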