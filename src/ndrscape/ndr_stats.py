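"""Nucleosome calling and promoter NDR-length statistics.

Nucleosome positions are windowed local maxima of the occupancy track: a base
p is a call iff its occupancy is positive, no base within ±window/2 exceeds
it, and every base in the left half-window is strictly below it (so a flat
plateau yields exactly its leftmost base). Positions within window/2 of a
chromosome end are not callable.

The promoter NDR length of a gene is the distance in bases between the first
called nucleosome strictly before the TSS and the first call at or after it,
both required within a search limit of the TSS. Per-gene mutant − wild-type
NDR-length differences are tested against a zero median with a one-sample
Wilcoxon signed-rank test: exact by enumeration of the 2^n sign assignments
for n ≤ 20 (midranks for tied magnitudes), otherwise the normal approximation
with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.stats import norm, rankdata

from .errors import NdrscapeError, ValidationError
from .io_formats import OccupancyTrack, TssRecord

__all__ = [
    "NucleosomeCalls",
    "NdrRecord",
    "WilcoxonResult",
    "EXACT_LIMIT",
    "call_nucleosomes",
    "ndr_lengths",
    "delta_ndr",
    "wilcoxon_one_sample",
    "summarize_boxplot",
]

EXACT_LIMIT = 20  # exact signed-rank enumeration up to this many nonzero deltas


@dataclass
class NucleosomeCalls:
    """Sorted called dyad positions with their occupancy, per chromosome."""

    positions: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    window: int


@dataclass(frozen=True)
class NdrRecord:
    """Flanking nucleosome positions and NDR length for one gene."""

    gene_id: str
    chrom: str
    tss: int
    up_pos: int  # first call strictly before the TSS
    down_pos: int  # first call at or after the TSS
    length: int

    def __post_init__(self):
        if not (self.up_pos < self.tss <= self.down_pos):
            raise ValidationError(
                f"{self.gene_id}: flanking calls {self.up_pos},{self.down_pos} "
                f"do not bracket TSS {self.tss}"
            )
        if self.length != self.down_pos - self.up_pos or self.length <= 0:
            raise ValidationError(f"{self.gene_id}: inconsistent NDR length")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = sum of ranks of positive differences
    pvalue: float
    n_used: int  # nonzero differences
    method: str  # "exact" or "approx"


def call_nucleosomes(track: OccupancyTrack, maxima_window: int = 100) -> NucleosomeCalls:
    """Windowed local maxima of occupancy (see module docstring for the exact
    contract). O(n) per chromosome via running window maxima."""
    if maxima_window < 2 or maxima_window % 2:
        raise ValidationError("maxima_window must be even and >= 2")
    h = maxima_window // 2
    positions: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    for chrom, x in track.data.items():
        n = len(x)
        if n <= 2 * h:
            positions[chrom] = np.empty(0, dtype=np.int64)
            values[chrom] = np.empty(0)
            continue
        # cov[j] = max x[j .. j+h-1] (missing bases count as -inf)
        cov = maximum_filter1d(
            x, size=h, mode="constant", cval=-np.inf,
            origin=-(h - 1 - (h - 1) // 2),
        )
        left = np.full(n, -np.inf)
        left[h:] = cov[:-h]  # max over [p-h, p-1]
        right = np.full(n, -np.inf)
        right[:-1] = cov[1:]  # max over [p+1, p+h]
        ok = (x > 0) & (x > left) & (x >= right)
        ok[:h] = False
        ok[n - h:] = False
        pos = np.flatnonzero(ok).astype(np.int64)
        positions[chrom] = pos
        values[chrom] = x[pos]
    return NucleosomeCalls(positions, values, maxima_window)


def ndr_lengths(
    calls: NucleosomeCalls,
    tss: Sequence[TssRecord],
    search_limit: int = 1000,
) -> tuple[list[NdrRecord], dict[str, str]]:
    """Flanking-call positions and NDR length per gene.

    up = the largest call < TSS, down = the smallest call >= TSS, each
    required within ``search_limit`` bp of the TSS. Genes failing either bound
    are omitted and reported in the returned side map (gene_id -> reason);
    strand plays no role in the length.
    """
    records: list[NdrRecord] = []
    omitted: dict[str, str] = {}
    for gene in tss:
        pos = calls.positions.get(gene.chrom)
        if pos is None:
            omitted[gene.gene_id] = f"no calls on chromosome {gene.chrom}"
            continue
        i = int(np.searchsorted(pos, gene.tss, side="left"))
        if i == 0:
            omitted[gene.gene_id] = "no call upstream of TSS"
            continue
        if i == len(pos):
            omitted[gene.gene_id] = "no call downstream of TSS"
            continue
        up, down = int(pos[i - 1]), int(pos[i])
        if gene.tss - up > search_limit:
            omitted[gene.gene_id] = f"nearest upstream call {gene.tss - up} bp away"
            continue
        if down - gene.tss > search_limit:
            omitted[gene.gene_id] = f"nearest downstream call {down - gene.tss} bp away"
            continue
        records.append(
            NdrRecord(gene.gene_id, gene.chrom, gene.tss, up, down, down - up)
        )
    return records, omitted


def delta_ndr(mutant: Sequence[NdrRecord], wt: Sequence[NdrRecord]) -> pd.DataFrame:
    """Inner-join per-gene NDR lengths; delta = mutant − wild type (bp)."""
    mut = {r.gene_id: r.length for r in mutant}
    ref = {r.gene_id: r.length for r in wt}
    common = sorted(set(mut) & set(ref))
    if not common:
        raise NdrscapeError("no gene has an NDR record in both conditions")
    return pd.DataFrame(
        {
            "gene_id": common,
            "wt_length": [ref[g] for g in common],
            "mutant_length": [mut[g] for g in common],
            "delta": [mut[g] - ref[g] for g in common],
        }
    )


def _exact_signed_rank(ranks2: np.ndarray, w2: int, alternative: str) -> float:
    """Exact p over all 2^n sign assignments via subset-sum counting.

    ``ranks2`` are doubled ranks (integers even with midranks); counts are
    exact integers in float64 for n <= 20.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[:-r].copy()
    n_cases = 2.0 ** len(ranks2)
    p_less = counts[: w2 + 1].sum() / n_cases
    p_greater = counts[w2:].sum() / n_cases
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def _approx_signed_rank(
    ranks: np.ndarray, w: float, n: int, alternative: str
) -> float:
    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if alternative == "greater":
        return float(norm.sf((w - mn - 0.5) / sd))
    if alternative == "less":
        return float(norm.cdf((w - mn + 0.5) / sd))
    d = 0.5 * np.sign(w - mn)
    z = (w - mn - d) / sd
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_one_sample(
    deltas: Sequence[float], alternative: str = "two-sided"
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test of a zero median.

    Zeros are dropped; magnitudes are ranked with midranks for ties; the
    statistic W is the rank sum of the positive differences. For n <= 20
    nonzero values the p-value is exact (full sign-assignment null,
    tie-aware); beyond that, normal approximation with tie and continuity
    corrections.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    d = np.asarray(deltas, dtype=float)
    if d.size == 0 or not np.all(np.isfinite(d)):
        raise NdrscapeError("deltas must be a non-empty finite sequence")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise NdrscapeError("no nonzero differences")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        w2 = int(np.rint(2 * w))
        p = _exact_signed_rank(ranks2, w2, alternative)
        method = "exact"
    else:
        p = _approx_signed_rank(ranks, w, n, alternative)
        method = "approx"
    return WilcoxonResult(statistic=w, pvalue=float(p), n_used=n, method=method)


def summarize_boxplot(deltas_by_pair: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey box-plot summary per strain pair.

    Quartiles by linear interpolation; whiskers at the most extreme data
    points within 1.5×IQR of the quartiles.
    """
    rows = []
    for pair, deltas in deltas_by_pair.items():
        d = np.asarray(deltas, dtype=float)
        if d.size == 0:
            raise NdrscapeError(f"empty delta list for {pair!r}")
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        rows.append(
            {
                "pair": pair,
                "n": int(d.size),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": d[d >= lo_fence].min(),
                "whisker_high": d[d <= hi_fence].max(),
            }
        )
    return pd.DataFrame(rows)
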