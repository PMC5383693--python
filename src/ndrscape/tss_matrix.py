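"""Gene × position log2 occupancy-ratio matrices around the TSS, and k-means
grouping of remodeling responses.

The central quantity is, per gene g and position x in [−flank, +flank]
oriented 5'→3':

    value[g, x] = log2( (treatment[g, x] + pseudocount) / (control[g, x] + pseudocount) )

computed on depth-normalized tracks with a pseudocount (default +1) in both
numerator and denominator so bare regions do not divide by zero. Positive
values are a gain of nucleosome signal in the treatment (mutant), negative a
loss. Genes are grouped by Euclidean k-means (default k=5) and cluster labels
are canonically renumbered by decreasing mean ratio over the upstream
half-window so "cluster 1" means the same thing across seeds and machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import NdrscapeError, ValidationError, WindowOutOfBounds
from .io_formats import ChromSizes, OccupancyTrack, TssRecord

__all__ = [
    "AnalysisParams",
    "RatioMatrix",
    "ClusterAssignment",
    "extract_window",
    "ratio_matrix",
    "kmeans_cluster",
    "order_for_heatmap",
    "save_heatmap",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the TSS-anchored differential analysis.

    flank: half-width of the TSS window in bp.
    pseudocount: added to numerator and denominator of every ratio.
    k: number of k-means clusters.
    maxima_window: width of the local-maximum window for nucleosome calling.
    ndr_search_limit: how far from the TSS a flanking nucleosome may be.
    downreg_threshold: log2 fold-change below which a gene counts as
        downregulated.
    """

    flank: int = 750
    pseudocount: float = 1.0
    k: int = 5
    maxima_window: int = 100
    ndr_search_limit: int = 1000
    downreg_threshold: float = -0.5
    seed: int = 0

    def __post_init__(self):
        if self.flank < 1:
            raise ValidationError("flank must be >= 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.maxima_window < 2 or self.maxima_window % 2:
            raise ValidationError("maxima_window must be even and >= 2")
        if self.ndr_search_limit < 1:
            raise ValidationError("ndr_search_limit must be >= 1")


@dataclass
class RatioMatrix:
    """Genes × positions matrix of log2 ratios, 5'→3' per row."""

    gene_ids: list[str]
    flank: int
    values: np.ndarray  # shape (n_genes, 2*flank+1)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.shape != (len(self.gene_ids), 2 * self.flank + 1):
            raise ValidationError("matrix shape does not match gene_ids and flank")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite ratio values")

    @property
    def coords(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.coords)
        df.insert(0, "gene_id", self.gene_ids)
        return df


@dataclass
class ClusterAssignment:
    """gene_id → cluster label in 1..k, labels canonically ordered."""

    labels: dict[str, int]
    k: int
    upstream_means: dict[int, float]  # label -> mean ratio over [-500, 0]

    def __post_init__(self):
        got = sorted(set(self.labels.values()))
        if got != list(range(1, self.k + 1)):
            raise ValidationError(f"labels must cover 1..{self.k}, got {got}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.labels), "cluster": list(self.labels.values())}
        )


def extract_window(track: OccupancyTrack, gene: TssRecord, flank: int) -> np.ndarray:
    """Per-base window [tss−flank, tss+flank], reversed for − strand genes so
    index 0 is −flank in the direction of transcription.

    Raises WindowOutOfBounds when the window crosses a chromosome boundary;
    callers drop the gene and record it.
    """
    vec = track.data.get(gene.chrom)
    if vec is None:
        raise ValidationError(f"gene {gene.gene_id!r}: unknown chromosome {gene.chrom!r}")
    lo, hi = gene.tss - flank, gene.tss + flank + 1
    if lo < 0 or hi > len(vec):
        raise WindowOutOfBounds(
            f"gene {gene.gene_id!r}: window [{lo},{hi}) outside chromosome of length {len(vec)}"
        )
    window = vec[lo:hi]
    return window[::-1].copy() if gene.strand == "-" else window.copy()


def ratio_matrix(
    treatment: OccupancyTrack,
    control: OccupancyTrack,
    tss: list[TssRecord],
    params: AnalysisParams,
) -> RatioMatrix:
    """log2((treatment + pc) / (control + pc)) per gene over the TSS window.

    Both tracks should already be depth-normalized; the pseudocount is applied
    to the values as given. Genes with out-of-bounds windows are dropped and
    listed in ``RatioMatrix.excluded``.
    """
    gene_ids, rows, excluded = [], [], []
    pc = params.pseudocount
    for gene in tss:
        try:
            t = extract_window(treatment, gene, params.flank)
            c = extract_window(control, gene, params.flank)
        except WindowOutOfBounds:
            excluded.append(gene.gene_id)
            continue
        # difference of logs, not log of quotient: keeps ratio(A,B) == -ratio(B,A)
        # exact in floating point
        rows.append(np.log2(t + pc) - np.log2(c + pc))
        gene_ids.append(gene.gene_id)
    if not rows:
        raise NdrscapeError("no usable genes: every TSS window is out of bounds")
    return RatioMatrix(gene_ids, params.flank, np.vstack(rows), excluded)


def _upstream_mask(flank: int) -> np.ndarray:
    coords = np.arange(-flank, flank + 1)
    lo = -min(flank, 500)
    return (coords >= lo) & (coords <= 0)


def kmeans_cluster(matrix: RatioMatrix, params: AnalysisParams) -> ClusterAssignment:
    """Euclidean k-means on matrix rows, deterministic given the seed.

    Ten k-means++ restarts, up to 300 iterations. Raw labels are arbitrary, so
    they are renumbered 1..k by decreasing cluster mean ratio over the
    upstream half-window [−500, 0]: cluster 1 is always the strongest
    upstream occupancy gain.
    """
    n = len(matrix.gene_ids)
    if n < params.k:
        raise NdrscapeError(f"cannot form {params.k} clusters from {n} rows")
    km = KMeans(
        n_clusters=params.k,
        n_init=10,
        max_iter=300,
        tol=1e-6,
        init="k-means++",
        random_state=params.seed % (2**32),
    )
    raw = km.fit_predict(matrix.values)
    mask = _upstream_mask(matrix.flank)
    raw_means = {
        r: float(matrix.values[raw == r][:, mask].mean()) for r in range(params.k)
    }
    # decreasing upstream mean; break exact ties by raw label for determinism
    ordering = sorted(raw_means, key=lambda r: (-raw_means[r], r))
    relabel = {r: i + 1 for i, r in enumerate(ordering)}
    labels = {g: relabel[r] for g, r in zip(matrix.gene_ids, raw)}
    upstream_means = {relabel[r]: raw_means[r] for r in raw_means}
    return ClusterAssignment(labels, params.k, upstream_means)


def order_for_heatmap(
    matrix: RatioMatrix, clusters: ClusterAssignment
) -> tuple[list[str], list[int]]:
    """Row order for a clustered heatmap.

    Rows are grouped by cluster label ascending and, within a cluster, sorted
    by mean row value descending (ties broken by gene_id so the order does not
    depend on input row order). Returns (ordered gene_ids, cluster boundaries
    as cumulative row counts after each cluster except the last).
    """
    missing = set(matrix.gene_ids) - set(clusters.labels)
    if missing:
        raise ValidationError(f"clusters missing for {len(missing)} matrix rows")
    row_mean = {g: float(m) for g, m in zip(matrix.gene_ids, matrix.values.mean(axis=1))}
    ordered = sorted(
        matrix.gene_ids, key=lambda g: (clusters.labels[g], -row_mean[g], g)
    )
    boundaries, count = [], 0
    for label in range(1, clusters.k):
        count += sum(1 for g in matrix.gene_ids if clusters.labels[g] == label)
        boundaries.append(count)
    return ordered, boundaries


def save_heatmap(
    matrix: RatioMatrix,
    clusters: ClusterAssignment,
    path,
    vlim: float | None = None,
) -> None:
    """Render the clustered ratio matrix as an image.

    Diverging palette with blue = gain of occupancy in the treatment and red =
    loss; white separators at cluster boundaries.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered, boundaries = order_for_heatmap(matrix, clusters)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    data = matrix.values[[index[g] for g in ordered]]
    if vlim is None:
        vlim = float(np.percentile(np.abs(data), 99)) or 1.0
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(
        data, aspect="auto", cmap="RdBu", vmin=-vlim, vmax=vlim,
        extent=(-matrix.flank, matrix.flank, len(ordered), 0), interpolation="nearest",
    )
    for b in boundaries:
        ax.axhline(b, color="white", linewidth=1)
    ax.axvline(0, color="black", linewidth=0.5, linestyle="--")
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel(f"genes (n={len(ordered)}, {clusters.k} clusters)")
    fig.colorbar(im, ax=ax, label="log2 treatment/control occupancy")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
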