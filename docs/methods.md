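# Methods

## Scope and model

`ndrscape` measures how a treatment condition (typically a chromatin-remodeler
mutant) reshapes promoter nucleosome architecture relative to a control, from
1 bp-resolution nucleosome occupancy. The pipeline assumes occupancy tracks
are given (or derived from mononucleosome fragment intervals); it does not
align reads or call nucleosome positions with a model-based tool. The
occupancy operator is deliberately minimal and exact: each fragment adds one
count to every base within `footprint // 2` (default 73) bp of its midpoint,
clipped at chromosome ends. This conserves mass and is sufficient for all
downstream statistics, which only require a dense per-base profile.

Tracks are made comparable across sequencing depths by scaling to a
genome-wide mean of 1 before ratios are formed. Whether to normalize between
samples before forming ratios is a genuinely open design point; mean-1
scaling was chosen because it makes the pseudocount's magnitude (one unit =
the genome-average occupancy) independent of depth. The pseudocount is
applied after normalization for the same reason.

## Ratio matrices and clustering

For each gene, the window [TSS − flank, TSS + flank] (default flank 750 bp)
is extracted at 1 bp resolution and reversed for minus-strand genes so the
axis always runs 5′→3′. The matrix entry is
`log2(treat + pc) − log2(ctrl + pc)` with pseudocount pc = 1; the
difference-of-logs form makes the antisymmetry `R(A,B) = −R(B,A)` exact in
floating point. Genes whose window crosses a chromosome end are dropped and
counted, never zero-padded — padding would distort both column means and
clustering distances.

Clustering is Euclidean k-means (k = 5 by default) via scikit-learn with ten
k-means++ restarts, tolerance 1e−6, up to 300 iterations, and a fixed seed.
Raw k-means labels are arbitrary, so they are renumbered 1..k by decreasing
cluster mean ratio over the upstream half-window [−500, 0]: "cluster 1" is
always the strongest upstream occupancy gain, which keeps enrichment reports
comparable across seeds and machines. Heatmap rows are grouped by cluster
and sorted within a cluster by mean row value (ties broken by gene id so the
ordering is independent of input row order).

## Nucleosome calling and NDR lengths

A base p is called a nucleosome position iff occupancy(p) > 0, no base
within ±window/2 (default ±50 bp) exceeds it, and every base in the left
half-window is strictly below it. The one-sided strictness makes a flat
plateau yield exactly its leftmost base; requiring it on the left (rather
than the right) is what actually produces that leftmost-of-plateau behavior.
Positions within window/2 of a chromosome end are not callable, so a
constant track yields no calls. Two calls are automatically ≥ window/2
apart. The implementation is O(n) per chromosome (running window maxima)
and is checked exactly against a direct O(n·w) scan on randomized tracks.

A "local maximum in a w bp window" could alternatively mean non-overlapping
tiling windows; the centered sliding-window reading is implemented because
it is translation-equivariant and unambiguous. A tiled compatibility mode
would be straightforward future work.

The promoter NDR length is the distance in bases between the largest call
strictly before the TSS and the smallest call at or after it (a call exactly
at the TSS counts as downstream; the convention is recorded in the run
report). Both calls must lie within a search limit (default 1000 bp) of the
TSS; genes failing the bound are omitted and counted rather than assigned
absurd lengths from call-poor regions. Strand never enters the length.

## Differential test

Per-gene differences Δ = NDR_mutant − NDR_wt are tested against a zero
median with a one-sample Wilcoxon signed-rank test. Zeros are dropped,
magnitudes are ranked with midranks for ties, and W is the rank sum of
positive differences. For n ≤ 20 nonzero values the null distribution is
computed exactly over all 2^n sign assignments (by subset-sum counting over
doubled ranks, which is the same distribution as literal enumeration but
O(n·Σr)); beyond that, the normal approximation with tie and continuity
corrections is used, matching the standard large-sample treatment. The test
is two-sided by default — the direction of the effect is reported via the
median's sign — since claims of shrinkage versus growth should not be baked
into the p-value. Box summaries use linearly interpolated quartiles and
1.5·IQR whiskers.

## Enrichment

Genes with log2 fold change strictly below −0.5 are labelled downregulated.
Per cluster, a 2×2 membership × downregulation table is formed over the
universe of genes present in both the clustering and the expression table
(genes without expression data are excluded from the universe, not counted
as "not downregulated", and reported). The one-sided enrichment p-value is
the hypergeometric upper tail computed with exact integer binomial
coefficients; a two-sided option delegates to scipy. No multiple-testing
correction is applied across the k clusters by default (a Bonferroni column
is available), since the convention being matched reports raw thresholds.

## Synthetic data generator

The generator emulates exactly the contrast the pipeline measures. Per gene:
an NDR whose width is drawn from Normal(280, 20) bp truncated at 60 bp and
rounded to integers, flanked by a −1 and +1 nucleosome from which phased
arrays of `n_array` = 3 nucleosomes extend at a 165 bp repeat (154 bp is
offered as a fission-yeast-like alternative). NDR width is **dyad-to-dyad**:
the distance between the −1 and +1 nucleosome centers, which is what the
NDR-length statistic measures. 280 bp corresponds to ~130 bp of
nucleosome-free DNA plus one 147 bp footprint — a typical yeast promoter.
Substantially narrower defaults would let the 147 bp fragment footprints of
the flanking nucleosomes fill the NDR completely, making it undetectable by
construction rather than by biology.

The TSS is placed ceil(width/2) bp from the transcription-upstream boundary
nucleosome, i.e. mid-NDR. Real TSSs sit closer to the +1 nucleosome, but the
centered placement guarantees the TSS stays strictly inside the NDR in both
conditions for any shrink < 60 bp, which the NDR-length definition requires;
this changes no tested quantity since the length is boundary-to-boundary.
Genes alternate strand deterministically and are laid out on a lattice with
at least 2×(array extent + 750 bp) separation, so neighbouring genes never
share signal within the analysis window.

The mutant condition implements boundary encroachment, not insertion: each
boundary nucleosome moves toward the TSS by shrink/2 and its flanking array
translates rigidly with it, so the true NDR narrows by exactly
`mutant_shrink` (default 40 bp) per gene.

Noise-free occupancy renders a Gaussian bump (height 1, sd 25 bp, evaluated
within ±5 sd) at every nucleosome center. Noisy data draws Poisson(depth)
fragments per nucleosome (default depth 50), each 147 bp long with midpoint
= center + round(Normal(0, 25)); wild-type and mutant streams are
independent but both derive deterministically from the single run seed via
fixed stream tags.

What the generator does **not** model: MNase digestion bias, fragment-length
variability, sequence-dependent nucleosome affinity, fuzzy or delocalized
nucleosomes, replicates, or heterogeneous per-gene responses. Passing tests
on this generator therefore demonstrate that the measurement machinery is
correct and well-calibrated under a clean encroachment model — not that the
pipeline is robust to every artifact of real MNase-seq data.

## Numerical and degenerate-case choices

- Exact recovery: on noise-free renders at default geometry, nucleosome
  calling recovers every truth center exactly and NDR lengths match truth
  exactly. For NDRs narrower than ~120 bp at peak sd 25, the −1/+1 Gaussians
  overlap enough to attract each other's argmax by 1–2 bp — a property of
  Gaussian mixtures, negligible at realistic widths.
- All-zero tracks cannot be normalized (error), empty delta sets and
  all-zero delta vectors are errors, an empty enrichment universe is an
  error; parsers fail with the offending line number.
- bedGraph writing uses shortest-round-trip float formatting, so
  read(write(t)) == t exactly; overlapping bedGraph intervals are rejected.
- Seeds: one integer seed per run; simulation streams are derived from it
  with fixed tags, and the k-means seed is the analysis seed. Identical
  configs produce byte-identical reports.

## Problem sizes used in validation

The automated checks run at desk scale, chosen to finish in minutes on one
core while keeping estimates stable: 200 genes per simulated landscape,
depth 50 fragments per nucleosome, 20 seeds for effect recovery, 100 seeds
for the null-control rejection rate, 1,000 random tracks of length 2,000 for
caller-vs-scan agreement, 1,000 enumeration cases for the exact Wilcoxon,
and every 2×2 table with universe ≤ 50 for the Fisher tail.

## Reproducing the original full-scale analysis

The pipeline accepts real data directly: per-base occupancy (bedGraph or
fixedStep wiggle, e.g. exported from a DANPOS run), a BED6 TSS annotation,
a chrom-sizes file, and optionally a gene-level log2 fold-change TSV. The
datasets this design targets are deposited in GEO as GSE84912
(*S. pombe*: rsc1Δ and tetO-snf21 vs wild type) and GSE65593
(*S. cerevisiae*: sth1 degron vs control); download the occupancy profiles,
convert to bedGraph, and point an `inputs:` block of the run config at them.
No download automation is included.
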