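# ndrscape

Analysis of promoter nucleosome architecture from MNase-seq occupancy, built
around one question: how do chromatin-remodeler mutants reshape the
nucleosome-depleted regions (NDRs) that sit upstream of most transcription
start sites?

Most eukaryotic promoters show a stereotyped layout — an NDR flanked by a
positioned −1 and +1 nucleosome from which phased arrays emanate. RSC-family
remodelers help keep the NDR open; when they are impaired, the flanking
nucleosomes encroach and the NDR shrinks. `ndrscape` quantifies that
phenotype from 1 bp-resolution occupancy tracks:

- **Ratio matrices** — per gene g and position x ∈ [−750, +750] around the
  TSS, oriented 5′→3′:
  `R[g, x] = log2((treat[g,x] + 1) / (ctrl[g,x] + 1))`
  on depth-normalized tracks (pseudocount +1 in numerator and denominator),
  with k-means grouping (k = 5) of the per-gene response and heatmap export
  (blue = occupancy gain, red = loss).
- **Nucleosome calling** — local maxima of occupancy in a 100 bp window.
- **NDR length** — per gene, the distance in bp between the first called
  nucleosome before the TSS and the first at/after it; per-gene
  mutant − wild-type differences are tested against a zero median with a
  one-sample Wilcoxon signed-rank test (exact by full sign-assignment
  enumeration for n ≤ 20).
- **Metagene profiles** — average occupancy over genes aligned at the TSS.
- **Enrichment** — per cluster, a one-sided Fisher exact test (exact
  hypergeometric tail) for over-representation of downregulated genes
  (log2 fold change < −0.5).
- **Synthetic data** — a generator of promoter landscapes with known ground
  truth (NDR bounds, array spacing, per-condition nucleosome centers) and
  Poisson/Gaussian fragment noise, so every stage is verifiable without any
  external download.

## Worked example

`examples/ndr_shrinkage.py` simulates 200 genes whose NDRs all shrink by
40 bp in the mutant (fragment noise: Poisson depth 50 per nucleosome, 25 bp
midpoint jitter), then re-measures the effect from the noisy data:

```
wt: 200 NDRs called, 0 genes omitted
mutant: 200 NDRs called, 0 genes omitted

median delta NDR: -45.0 bp (truth: -40)
Wilcoxon signed-rank: W=1700.5, p=3.62e-24 (n=199, approx)
        pair   n  median     q1     q3  whisker_low  whisker_high
mutant_vs_wt 200   -45.0 -62.25 -25.75       -116.0          23.0
```

The recovered median difference is within sampling noise of the planted
−40 bp, and the signed-rank test firmly rejects a zero median: the mutant
NDRs are shorter. The other example scripts cover simulation
(`simulate_landscape.py`), metagene profiles (`metagene_profile.py`),
clustered heatmaps (`cluster_heatmap.py`), and expression enrichment
(`expression_enrichment.py`); each prints a few numbers and says what they
mean.

## Command line

Every stage is also a subcommand of `ndrscape`
(simulate / occupancy / profile / matrix / cluster / ndr / ndr-diff /
enrich), and `ndrscape run --config cfg.yaml` drives the whole pipeline from
one YAML file (either a `simulate:` block or an `inputs:` block with
bedGraph/wiggle tracks, BED6 TSS annotation and a chrom-sizes file), writing
all tables plus a deterministic `report.json`.

## File conventions

Internal coordinates are 0-based, half-open everywhere; wiggle's 1-based
convention is converted at the file boundary. The TSS of a −-strand BED6
feature is `end − 1`. Tracks are read from bedGraph or fixedStep wiggle and
written as run-length-merged bedGraph (zero runs omitted); uncovered bases
read as 0. All tables are TSV with a header.
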