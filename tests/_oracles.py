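"""Independent reference implementations used only by the tests.

Each function here recomputes a quantity by a route deliberately different
from the package's: direct definitions, exhaustive enumeration, or exact
rational arithmetic. They are slow and simple on purpose.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from ndrscape import ChromSizes, OccupancyTrack, TssRecord


def brute_calls(x: np.ndarray, window: int) -> np.ndarray:
    """Direct transcription of the local-maximum contract, O(n*w)."""
    h = window // 2
    n = len(x)
    out = []
    for p in range(h, n - h):
        if x[p] <= 0:
            continue
        if np.any(x[p - h : p + h + 1] > x[p]):
            continue
        if np.any(x[p - h : p] >= x[p]):
            continue
        out.append(p)
    return np.array(out, dtype=np.int64)


def midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks for tied magnitudes, computed by sorting positions."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def enumerate_signed_rank(deltas, alternative="two-sided"):
    """Exact one-sample signed-rank p by literal enumeration of sign vectors."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = masks @ ranks
    p_less = np.count_nonzero(w_all <= w_obs) / 2**n
    p_greater = np.count_nonzero(w_all >= w_obs) / 2**n
    if alternative == "less":
        return w_obs, p_less
    if alternative == "greater":
        return w_obs, p_greater
    return w_obs, min(1.0, 2.0 * min(p_less, p_greater))


def hypergeom_tail_fraction(a: int, big_n: int, big_k: int, n: int) -> Fraction:
    """P(X >= a) as an exact rational number."""
    hi = min(n, big_k)
    total = comb(big_n, n)
    acc = Fraction(0)
    for i in range(max(a, max(0, n + big_k - big_n)), hi + 1):
        acc += Fraction(comb(big_k, i) * comb(big_n - big_k, n - i), total)
    return acc


def mirror_genome(
    track: OccupancyTrack, sizes: ChromSizes, tss: list[TssRecord]
) -> tuple[OccupancyTrack, list[TssRecord]]:
    """Reverse every chromosome and flip every strand."""
    mirrored = OccupancyTrack({c: v[::-1].copy() for c, v in track.data.items()})
    flipped = [
        TssRecord(
            g.gene_id, g.chrom, sizes[g.chrom] - 1 - g.tss,
            "-" if g.strand == "+" else "+",
        )
        for g in tss
    ]
    return mirrored, flipped
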