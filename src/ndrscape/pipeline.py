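"""End-to-end orchestration: simulate (or load) → occupancy → ratio matrix →
clusters → nucleosome calls → NDR statistics → enrichment, with a
machine-readable run report.

A run is configured by a YAML file with exactly one of a ``simulate`` block
(synthetic data, see :class:`ndrscape.synthetic.SimParams`) or an ``inputs``
block (paths to real chrom sizes, TSS BED6, and per-condition tracks or
fragment BEDs). A single ``seed`` drives every random stage. Repeated runs
with the same config produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, NdrscapeError
from .io_formats import (
    ChromSizes,
    OccupancyTrack,
    read_chrom_sizes,
    read_fragments_bed,
    read_table,
    read_track,
    read_tss_bed,
    write_table,
    write_track,
    write_tss_bed,
    write_fragments_bed,
)
from .occupancy import average_profile, compute_occupancy, normalize_track
from .tss_matrix import (
    AnalysisParams,
    kmeans_cluster,
    order_for_heatmap,
    ratio_matrix,
    save_heatmap,
)
from .ndr_stats import (
    call_nucleosomes,
    delta_ndr,
    ndr_lengths,
    summarize_boxplot,
    wilcoxon_one_sample,
)
from .enrichment import cluster_enrichment, label_downregulated
from .synthetic import CONDITIONS, SimParams, export_truth, render_occupancy, sample_fragments, sample_genome

__all__ = ["RunConfig", "validate_config", "run_all"]

log = logging.getLogger("ndrscape")

_ANALYSIS_KEYS = {f.name for f in dataclasses.fields(AnalysisParams)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimParams)}
_INPUT_KEYS = {
    "chrom_sizes", "tss",
    "treatment_track", "control_track",
    "treatment_fragments", "control_fragments",
}
_TOP_KEYS = {"seed", "outdir", "analysis", "simulate", "inputs", "expression"}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    analysis: AnalysisParams
    simulate: SimParams | None = None
    inputs: dict[str, Path] | None = None
    expression: Path | None = None


def _reject_unknown(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config, filling defaults.

    Exactly one of ``simulate`` / ``inputs`` must be present; all referenced
    paths must exist. Defaults: flank 750, pseudocount 1, k 5, window 100.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, str(path))
    seed = int(raw.get("seed", 0))
    outdir = Path(raw.get("outdir", "ndrscape_out"))

    analysis_block = raw.get("analysis") or {}
    _reject_unknown(analysis_block, _ANALYSIS_KEYS, f"{path}:analysis")
    analysis = AnalysisParams(**{**analysis_block, "seed": seed})

    has_sim = "simulate" in raw and raw["simulate"] is not None
    has_inputs = "inputs" in raw and raw["inputs"] is not None
    if has_sim == has_inputs:
        raise ConfigError(
            f"{path}: exactly one of 'simulate' or 'inputs' must be given"
        )

    sim = None
    inputs = None
    if has_sim:
        block = raw["simulate"] if isinstance(raw["simulate"], dict) else {}
        _reject_unknown(block, _SIM_KEYS, f"{path}:simulate")
        sim = SimParams(**{"seed": seed, **block})
    else:
        block = raw["inputs"]
        _reject_unknown(block, _INPUT_KEYS, f"{path}:inputs")
        for req in ("chrom_sizes", "tss"):
            if req not in block:
                raise ConfigError(f"{path}:inputs: missing required key {req!r}")
        for cond in ("treatment", "control"):
            has_track = f"{cond}_track" in block
            has_frags = f"{cond}_fragments" in block
            if has_track == has_frags:
                raise ConfigError(
                    f"{path}:inputs: give exactly one of {cond}_track / {cond}_fragments"
                )
        inputs = {}
        for key, value in block.items():
            p = Path(value)
            if not p.exists():
                raise ConfigError(f"{path}:inputs:{key}: no such file: {p}")
            inputs[key] = p

    expression = None
    if raw.get("expression") is not None:
        expression = Path(raw["expression"])
        if not expression.exists():
            raise ConfigError(f"{path}:expression: no such file: {expression}")

    return RunConfig(seed=seed, outdir=outdir, analysis=analysis,
                     simulate=sim, inputs=inputs, expression=expression)


def _load_condition_track(
    inputs: dict[str, Path], cond: str, sizes: ChromSizes
) -> OccupancyTrack:
    if f"{cond}_track" in inputs:
        return read_track(inputs[f"{cond}_track"], sizes)
    frags = read_fragments_bed(inputs[f"{cond}_fragments"], sizes)
    return compute_occupancy(frags, sizes)


def run_all(config: RunConfig) -> dict:
    """Run every stage and write all outputs under ``config.outdir``.

    Returns the run report (also written as report.json): parameters, gene
    exclusion counts, the Wilcoxon summary, per-cluster enrichment, and
    library versions. Deterministic for a fixed config.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "ndrscape_version": __version__,
        "seed": config.seed,
        "analysis_params": dataclasses.asdict(config.analysis),
        "stages": {},
    }

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulate is not None:
            params = config.simulate
            report["sim_params"] = dataclasses.asdict(params)
            sizes, tss, truth = sample_genome(params)
            sizes.write(out / "chrom.sizes")
            write_tss_bed(tss, out / "tss.bed")
            export_truth(truth, out / "truth.tsv")
            raw = {}
            for cond in CONDITIONS:
                frags = sample_fragments(truth, cond, params)
                write_fragments_bed(frags, out / f"{cond}.fragments.bed")
                raw[cond] = compute_occupancy(frags, sizes)
            control_raw, treatment_raw = raw["wt"], raw["mutant"]
        else:
            sizes = read_chrom_sizes(config.inputs["chrom_sizes"])
            tss = read_tss_bed(config.inputs["tss"], sizes)
            treatment_raw = _load_condition_track(config.inputs, "treatment", sizes)
            control_raw = _load_condition_track(config.inputs, "control", sizes)
    except NdrscapeError as err:
        raise NdrscapeError(f"stage inputs: {err}") from err
    report["stages"]["inputs"] = {"n_genes": len(tss)}
    log.info("inputs: %d genes, %d chromosomes", len(tss), len(sizes.names()))

    # ---- stage: occupancy ---------------------------------------------
    try:
        treatment = normalize_track(treatment_raw)
        control = normalize_track(control_raw)
        write_track(treatment, out / "treatment.norm.bedgraph")
        write_track(control, out / "control.norm.bedgraph")
        profile = average_profile(control, tss, flank=config.analysis.flank)
        write_table(
            pd.DataFrame({"position": profile.coords, "mean_occupancy": profile.values}),
            out / "metagene.control.tsv",
        )
    except NdrscapeError as err:
        raise NdrscapeError(f"stage occupancy: {err}") from err
    report["stages"]["occupancy"] = {"metagene_genes_used": profile.n_genes_used}

    # ---- stage: matrix + clusters --------------------------------------
    try:
        matrix = ratio_matrix(treatment, control, tss, config.analysis)
        clusters = kmeans_cluster(matrix, config.analysis)
        ordered, boundaries = order_for_heatmap(matrix, clusters)
        index = {g: i for i, g in enumerate(matrix.gene_ids)}
        ordered_frame = matrix.to_frame().iloc[[index[g] for g in ordered]]
        write_table(ordered_frame, out / "matrix.tsv")
        write_table(clusters.to_frame(), out / "clusters.tsv")
        save_heatmap(matrix, clusters, out / "heatmap.png")
    except NdrscapeError as err:
        raise NdrscapeError(f"stage matrix: {err}") from err
    cluster_sizes = {
        str(label): sum(1 for v in clusters.labels.values() if v == label)
        for label in range(1, clusters.k + 1)
    }
    report["stages"]["matrix"] = {
        "n_genes_in_matrix": len(matrix.gene_ids),
        "n_excluded_out_of_bounds": len(matrix.excluded),
        "ratio_direction": "treatment_over_control",
        "cluster_sizes": cluster_sizes,
        "cluster_upstream_means": {
            str(k): v for k, v in sorted(clusters.upstream_means.items())
        },
        "heatmap_boundaries": boundaries,
    }
    log.info("matrix: %d genes, %d excluded", len(matrix.gene_ids), len(matrix.excluded))

    # ---- stage: NDR statistics -----------------------------------------
    try:
        treat_calls = call_nucleosomes(treatment, config.analysis.maxima_window)
        ctrl_calls = call_nucleosomes(control, config.analysis.maxima_window)
        treat_ndrs, treat_omit = ndr_lengths(
            treat_calls, tss, config.analysis.ndr_search_limit
        )
        ctrl_ndrs, ctrl_omit = ndr_lengths(
            ctrl_calls, tss, config.analysis.ndr_search_limit
        )
        _write_ndr_table(treat_ndrs, out / "ndr.treatment.tsv")
        _write_ndr_table(ctrl_ndrs, out / "ndr.control.tsv")
        deltas = delta_ndr(treat_ndrs, ctrl_ndrs)
        write_table(deltas, out / "delta_ndr.tsv")
        wilcoxon = wilcoxon_one_sample(deltas["delta"])
        box = summarize_boxplot({"treatment_vs_control": deltas["delta"]})
        write_table(box, out / "boxplot_summary.tsv")
    except NdrscapeError as err:
        raise NdrscapeError(f"stage ndr: {err}") from err
    report["stages"]["ndr"] = {
        "n_treatment_ndrs": len(treat_ndrs),
        "n_control_ndrs": len(ctrl_ndrs),
        "n_omitted_treatment": len(treat_omit),
        "n_omitted_control": len(ctrl_omit),
        "n_pairs": int(len(deltas)),
        "median_delta_bp": float(deltas["delta"].median()),
        "wilcoxon_W": wilcoxon.statistic,
        "wilcoxon_p": wilcoxon.pvalue,
        "wilcoxon_n_used": wilcoxon.n_used,
        "wilcoxon_method": wilcoxon.method,
        "down_pos_convention": "first call at or after the TSS",
    }
    log.info(
        "ndr: %d gene pairs, median delta %.1f bp, Wilcoxon p=%.3g",
        len(deltas), deltas["delta"].median(), wilcoxon.pvalue,
    )

    # ---- stage: enrichment ---------------------------------------------
    if config.expression is not None:
        try:
            expr = read_table(config.expression, required=["gene_id", "log2fc"])
            down = label_downregulated(expr, config.analysis.downreg_threshold)
            enrich = cluster_enrichment(clusters, down, expr["gene_id"])
            write_table(enrich, out / "enrichment.tsv")
        except NdrscapeError as err:
            raise NdrscapeError(f"stage enrichment: {err}") from err
        report["stages"]["enrichment"] = {
            "n_downregulated": len(down),
            "universe_size": enrich.attrs["universe_size"],
            "n_missing_expression": enrich.attrs["n_missing_expression"],
            "pvalues": {
                str(int(r.cluster)): float(r.pvalue) for r in enrich.itertuples()
            },
            "frequencies": {
                str(int(r.cluster)): float(r.frequency_down)
                for r in enrich.itertuples()
            },
        }
    else:
        report["stages"]["enrichment"] = {"skipped": "no expression table given"}
        log.info("enrichment: skipped (no expression table)")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _write_ndr_table(records, path) -> None:
    write_table(
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "chrom": r.chrom,
                    "tss": r.tss,
                    "up_pos": r.up_pos,
                    "down_pos": r.down_pos,
                    "length": r.length,
                }
                for r in records
            ],
            columns=["gene_id", "chrom", "tss", "up_pos", "down_pos", "length"],
        ),
        path,
    )
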