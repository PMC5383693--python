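"""Synthetic MNase-seq landscapes with a known ground truth.

The generator emulates the promoter architecture the pipeline is built to
measure: per gene, a nucleosome-depleted region (NDR) flanked by a −1 and a +1
nucleosome from which phased arrays emanate, and a mutant condition in which
the flanking nucleosomes encroach on the NDR — each boundary moves toward the
TSS by half the shrink — dragging their arrays with them (rigid translation,
no nucleosome insertion). Occupancy peaks are Gaussian; sequencing noise is
modelled as Poisson fragment counts per nucleosome with normally jittered
midpoints and a fixed 147 bp mononucleosome footprint.

This is a stand-in generative model for testing: real MNase-seq has digestion
bias, variable fragment sizes and sequence-dependent nucleosome affinity, none
of which are modelled here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import CapacityError, ValidationError
from .io_formats import ChromSizes, FragmentSet, OccupancyTrack, TssRecord, write_table, read_table

__all__ = [
    "SimParams",
    "GeneTruth",
    "SimTruth",
    "CONDITIONS",
    "sample_genome",
    "render_occupancy",
    "sample_fragments",
    "export_truth",
    "read_truth",
    "simulate_all",
]

CONDITIONS = ("wt", "mutant")
CHROM = "chr_sim"
FRAGMENT_LENGTH = 147

# fixed sub-seed tags so every random stream derives from the one user seed
_GENOME_STREAM = 11
_FRAGMENT_STREAM = 23


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic nucleosome landscape.

    Defaults describe a budding-yeast-like promoter: 165 bp nucleosome repeat
    length (154 bp is typical of fission yeast), a 280 ± 20 bp NDR measured
    dyad-to-dyad between the −1 and +1 nucleosomes (i.e. ~130 bp of free DNA
    plus one 147 bp footprint; truncated at 60 bp), three positioned
    nucleosomes per flank, 25 bp peak spread, and a remodeler-mutant
    condition in which every NDR narrows by 40 bp.
    """

    n_genes: int = 200
    chrom_length: int | None = None  # None: just large enough
    ndr_width_mean: float = 280.0
    ndr_width_sd: float = 20.0
    spacing: int = 165
    n_array: int = 3
    peak_sd: float = 25.0
    peak_height: float = 1.0
    mutant_shrink: int = 40
    depth: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.ndr_width_mean <= 0:
            raise ValidationError("ndr_width_mean must be > 0")
        if self.spacing < 147:
            raise ValidationError("spacing must be >= 147 (one nucleosome footprint)")
        if self.mutant_shrink < 0:
            raise ValidationError("mutant_shrink must be >= 0")
        if self.mutant_shrink >= 60:
            raise ValidationError(
                "mutant_shrink must be < 60 (minimum NDR width) so the TSS stays inside the NDR"
            )
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if self.peak_sd < 0 or self.ndr_width_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_array < 1:
            raise ValidationError("n_array must be >= 1")

    # geometry helpers -----------------------------------------------------
    @property
    def edge_margin(self) -> int:
        """Clearance at chromosome ends and between genes: flank array extent,
        the ±750 bp analysis window, and Gaussian tail room."""
        return int(self.n_array * self.spacing + 750 + math.ceil(5 * self.peak_sd))

    @property
    def min_separation(self) -> int:
        return 2 * (self.n_array * self.spacing + 750)

    @property
    def pitch(self) -> int:
        # TSS-to-TSS distance; min_separation plus NDR allowance
        return self.min_separation + 2 * int(self.ndr_width_mean + 4 * self.ndr_width_sd)

    def required_length(self) -> int:
        return 2 * self.edge_margin + (self.n_genes - 1) * self.pitch + 1


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth promoter layout for one gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    wt_up: float  # genomic-left boundary nucleosome center (wt)
    wt_down: float  # genomic-right boundary nucleosome center (wt)
    mut_up: float
    mut_down: float
    centers: dict[str, np.ndarray] = field(repr=False)  # condition -> sorted centers

    @property
    def wt_ndr_length(self) -> float:
        return self.wt_down - self.wt_up

    @property
    def mut_ndr_length(self) -> float:
        return self.mut_down - self.mut_up


@dataclass
class SimTruth:
    genes: list[GeneTruth]
    params: SimParams

    def validate(self, sizes: ChromSizes) -> None:
        for g in self.genes:
            if not math.isclose(g.wt_ndr_length - g.mut_ndr_length, self.params.mutant_shrink):
                raise ValidationError(f"{g.gene_id}: NDR shrink != mutant_shrink")
            for cond, centers in g.centers.items():
                if np.any(np.diff(centers) <= 0):
                    raise ValidationError(f"{g.gene_id}/{cond}: centers not sorted")
                if centers[0] < 0 or centers[-1] >= sizes[g.chrom]:
                    raise ValidationError(f"{g.gene_id}/{cond}: center out of bounds")


def sample_genome(params: SimParams) -> tuple[ChromSizes, list[TssRecord], SimTruth]:
    """Lay out ``n_genes`` promoters on one synthetic chromosome.

    Genes are placed on a regular lattice with alternating strand, separated
    by at least twice the flank-array extent plus the 750 bp analysis window,
    so neighbouring genes never share signal. NDR widths are drawn per gene
    from a normal distribution truncated at 60 bp and rounded to integers; the
    TSS sits ``ceil(width/2)`` inside the NDR from its transcription-upstream
    boundary, which keeps it strictly between both boundary nucleosomes in the
    wild type and in the mutant for any shrink < 60 bp.

    Deterministic given ``params.seed``.
    """
    length = params.required_length() if params.chrom_length is None else params.chrom_length
    if params.required_length() > length:
        raise CapacityError(
            f"{params.n_genes} genes need {params.required_length()} bp "
            f"but chrom_length is {length}"
        )
    sizes = ChromSizes({CHROM: length})
    rng = np.random.default_rng([params.seed, _GENOME_STREAM])

    widths = np.empty(params.n_genes)
    remaining = np.arange(params.n_genes)
    while remaining.size:  # truncated normal by resampling
        draw = rng.normal(params.ndr_width_mean, params.ndr_width_sd, remaining.size)
        widths[remaining] = np.rint(draw)
        remaining = remaining[widths[remaining] < 60]
    s2 = params.mutant_shrink / 2.0

    genes: list[GeneTruth] = []
    tss_records: list[TssRecord] = []
    n_digits = len(str(params.n_genes))
    for i in range(params.n_genes):
        tss = params.edge_margin + i * params.pitch
        strand = "+" if i % 2 == 0 else "-"
        w = int(widths[i])
        up_off = math.ceil(w / 2)  # TSS offset from the transcription-upstream boundary
        if strand == "+":
            left, right = tss - up_off, tss - up_off + w
        else:
            left, right = tss + up_off - w, tss + up_off
        flank_left = left - params.spacing * np.arange(params.n_array)
        flank_right = right + params.spacing * np.arange(params.n_array)
        centers = {
            "wt": np.sort(np.concatenate([flank_left, flank_right])).astype(float),
            "mutant": np.sort(
                np.concatenate([flank_left + s2, flank_right - s2])
            ).astype(float),
        }
        gene_id = f"g{i:0{n_digits}d}"
        genes.append(
            GeneTruth(
                gene_id=gene_id,
                chrom=CHROM,
                strand=strand,
                tss=tss,
                wt_up=float(left),
                wt_down=float(right),
                mut_up=float(left + s2),
                mut_down=float(right - s2),
                centers=centers,
            )
        )
        tss_records.append(TssRecord(gene_id, CHROM, tss, strand))

    truth = SimTruth(genes, params)
    truth.validate(sizes)
    return sizes, tss_records, truth


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}, got {condition!r}")


def render_occupancy(
    truth: SimTruth, condition: str, params: SimParams, sizes: ChromSizes
) -> OccupancyTrack:
    """Noise-free occupancy: a Gaussian bump of height ``peak_height`` and
    spread ``peak_sd`` at every nucleosome center (evaluated within ±5 sd)."""
    _check_condition(condition)
    track = OccupancyTrack.zeros(sizes)
    radius = max(1, math.ceil(5 * params.peak_sd))
    for g in truth.genes:
        vec = track.data[g.chrom]
        for c in g.centers[condition]:
            if params.peak_sd == 0:
                vec[int(round(c))] += params.peak_height
                continue
            lo = max(0, int(math.floor(c - radius)))
            hi = min(len(vec), int(math.ceil(c + radius)) + 1)
            x = np.arange(lo, hi)
            vec[lo:hi] += params.peak_height * np.exp(
                -((x - c) ** 2) / (2 * params.peak_sd**2)
            )
    return track


def sample_fragments(truth: SimTruth, condition: str, params: SimParams) -> FragmentSet:
    """Noisy mononucleosome fragments.

    Each nucleosome yields ``Poisson(depth)`` fragments of length 147 bp whose
    midpoints are the center plus rounded Normal(0, peak_sd) jitter, clipped to
    the chromosome. The wild-type and mutant streams are independent but both
    derive deterministically from ``params.seed``.
    """
    _check_condition(condition)
    rng = np.random.default_rng(
        [params.seed, _FRAGMENT_STREAM, CONDITIONS.index(condition)]
    )
    length = (
        params.required_length()
        if params.chrom_length is None
        else params.chrom_length
    )
    all_centers = np.concatenate(
        [g.centers[condition] for g in truth.genes]
    ) if truth.genes else np.empty(0)
    if params.depth == 0 or all_centers.size == 0:
        return FragmentSet(pd.DataFrame({"chrom": [], "start": [], "end": []}))
    counts = rng.poisson(params.depth, all_centers.size)
    mids = np.repeat(all_centers, counts)
    if params.peak_sd > 0:
        mids = mids + np.rint(rng.normal(0.0, params.peak_sd, mids.size))
    mids = np.rint(mids).astype(np.int64)
    half = FRAGMENT_LENGTH // 2
    starts = np.clip(mids - half, 0, length)
    ends = np.clip(mids - half + FRAGMENT_LENGTH, 0, length)
    keep = starts < ends
    starts, ends = starts[keep], ends[keep]
    order = np.argsort(starts, kind="stable")
    frame = pd.DataFrame(
        {"chrom": CHROM, "start": starts[order], "end": ends[order]}
    )
    return FragmentSet(frame)


# ---------------------------------------------------------------------------
# truth table I/O

_TRUTH_COLUMNS = [
    "gene_id", "chrom", "strand", "tss",
    "wt_up", "wt_down", "mut_up", "mut_down",
    "wt_ndr_length", "mut_ndr_length",
]


def export_truth(truth: SimTruth, path) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand, "tss": g.tss,
            "wt_up": g.wt_up, "wt_down": g.wt_down,
            "mut_up": g.mut_up, "mut_down": g.mut_down,
            "wt_ndr_length": g.wt_ndr_length, "mut_ndr_length": g.mut_ndr_length,
        }
        for g in truth.genes
    ]
    write_table(pd.DataFrame(rows, columns=_TRUTH_COLUMNS), path)


def read_truth(path) -> pd.DataFrame:
    return read_table(path, required=_TRUTH_COLUMNS)


def simulate_all(params: SimParams, outdir) -> dict[str, str]:
    """Run the whole generator and write every artifact to ``outdir``.

    Writes chrom.sizes, tss.bed, per-condition noise-free bedGraph tracks and
    fragment BEDs, and truth.tsv. Returns the path map.
    """
    from pathlib import Path
    from .io_formats import write_track, write_tss_bed, write_fragments_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes, tss, truth = sample_genome(params)
    paths = {"chrom_sizes": outdir / "chrom.sizes", "tss": outdir / "tss.bed",
             "truth": outdir / "truth.tsv"}
    sizes.write(paths["chrom_sizes"])
    write_tss_bed(tss, paths["tss"])
    export_truth(truth, paths["truth"])
    for cond in CONDITIONS:
        track = render_occupancy(truth, cond, params, sizes)
        paths[f"{cond}_track"] = outdir / f"{cond}.bedgraph"
        write_track(track, paths[f"{cond}_track"])
        frags = sample_fragments(truth, cond, params)
        paths[f"{cond}_fragments"] = outdir / f"{cond}.fragments.bed"
        write_fragments_bed(frags, paths[f"{cond}_fragments"])
    return {k: str(v) for k, v in paths.items()}
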