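# Methods

## Overview

`stromascope` quantifies the stromal microenvironment of medulloblastoma
from transcriptomic data and traces it down to single cells. The pipeline
has five analytic stages, each an independently callable module:

1. **Signature scoring** — per-sample stromal/immune enrichment of bulk
   log2 expression (ssGSEA-style running sum), plus a scaled-average
   signature score and a PC1 module meta-gene.
2. **Screening** — one-vs-pooled-rest differential expression for a target
   molecular subgroup together with per-gene Pearson correlation against
   the stromal score.
3. **Associate classification** — rule-based labelling of receptor/ligand
   genes as stroma *drivers* or *suppressors*.
4. **Network centrality** — thresholded Pearson co-expression graph over
   the associates, ranked by closeness centrality.
5. **Cell states** — per-cell associate counts, stroma-active/inactive
   classes, marker detection, a metastasis contrast, and a simplified
   developmental-potential score.

Because the cohorts this kind of analysis runs on are large external
repositories, the package ships a first-class synthetic-data generator
that plants every structure the pipeline is meant to recover; all
recovery claims below are made, and tested, on that generator.

## Signature scoring

For a sample with expression vector `x` over `N` genes and a signature
`S`, genes are walked in descending expression order. Ranks are the
average ranks of `x` (ties share a rank; the walking order breaks ties by
gene position, which is irrelevant to the score precisely because tied
genes carry identical rank weights). With weight `w_g = rank(x_g)^alpha`,

    ES = sum_{i=1..N} [ P_in(i) - P_out(i) ],
    P_in(i)  = (sum of w over in-set genes at positions <= i) / (sum of w over all in-set genes),
    P_out(i) = (# out-of-set genes at positions <= i) / (N - |S|).

`alpha = 0.25` by default, the convention of the established
tumour-purity scorers whose core this reimplements. The score is a raw
per-sample running sum — no between-sample normalisation — so
cross-cohort comparison is the caller's responsibility. The score is
invariant under any within-sample rank-preserving transform and under
gene reordering (both property-tested). The platform-calibrated purity
transform applied by some tools downstream of these scores is out of
scope; the stromal/immune scores themselves are the deliverable.

The scaled-average score z-scores each gene across samples (population
SD; zero-variance genes contribute z = 0) and reports
`mean(z, g in S) - mean(z, g not in S)`. The module meta-gene is the
first principal component of the module submatrix (genes centred), with
the sign fixed so the meta-gene correlates non-negatively with mean
module expression.

## Screening

Differential expression contrasts the target subgroup against the pooled
remaining subgroups with Welch's two-sample t-test on the log2 matrix;
`log2fc` is the difference of group means. Welch was chosen because the
data model is array-scale log2 intensities with no replicate-level
variance moderation; the test applied is recorded in the output metadata.
Genes with zero variance in both groups get `p = 1` by convention.
P-values are unadjusted by default — the screen's thresholds are
deliberately the literal published-style cutoffs (`|FC| > 2`, `p < 0.05`)
— with an optional Benjamini-Hochberg mode. Correlation p-values use the
exact t-distribution transform of Pearson r. The stromal score used for
the cohort-wide screen is computed on the full cohort; per-subgroup
correlation profiles are available through a subgroup filter.

## Associate classification

A receptor/ligand gene is a **driver** iff `r_stroma > r_min` with
`p_corr < alpha` and it is either up in the stroma-enriched subgroup or
down in the stroma-suppressed one (`|log2fc| > log2(fc_min)`,
`p_dge < alpha`); a **suppressor** is the mirror image. All comparisons
are strict, matching the "greater than" wording of the cutoffs
(`fc_min = 2`, `r_min = 0.2`, `alpha = 0.05`). Genes in any exclusion
signature (the stromal/immune panels themselves) are removed first;
genes with undefined correlation (constant expression) are never
classified; a gene qualifying for both classes — impossible under exact
sign logic but conceivable with pathological inputs — is dropped with a
warning. For single-cell use, associates are additionally required to be
detected in at least 1% of cells (inclusive boundary).

## Network centrality

Edges are all-pairs Pearson correlations among associate genes, kept when
`|r| >= r_min` (0.6 bulk, 0.2 single cell) and `p < 0.05`; the sign is an
attribute, not a filter, so anticorrelated genes participate in the
topology. Closeness is computed on the unweighted thresholded graph with
Wasserman–Faust component scaling
`C(v) = (|R(v)|/(n-1)) * (|R(v)| / sum d(v,u))`, which keeps values in
[0, 1] and comparable across disconnected components; isolates score 0.
A weighted variant (distance `1 - |r|`) is available behind a flag for
sensitivity analysis. Graph machinery is networkx; the test suite checks
the centrality against an independent hand-written breadth-first-search
oracle.

## Cell states and developmental potential

A gene is "expressed" in a cell when its normalised value is positive
(the log-normalisation preserves zeros). Counts are tallied per role
(ligand / receptor / both; "both" contributes to each role tally but once
to the total). The state call uses the total associate count by default —
the role-specific counts are exposed and selectable, since published
figures plot ligands and receptors separately while the stated class
definition counts drivers — with strict cutoffs: active iff count > 5,
inactive iff count < 2, otherwise intermediate.

Markers of active vs inactive cells use a two-sided Wilcoxon rank-sum per
gene with BH adjustment; genes detected in < 1% of cells in both states
are not tested. The metastasis contrast is a rank-sum on per-cell counts
grouped by the tumour's metastasis flag; per-tumour mean counts are also
reported so the reader can see the pseudoreplication inherent in
cell-level inference (cells within a tumour are not independent).

The developmental-potential score counts detected genes per cell,
correlates every gene with that count, averages the `top_k = 200` most
count-correlated genes (a standard gene-counts-signature size;
configurable) into a signature, and rank-rescales that signature to
[0, 1] with 1 = least differentiated. This is a deliberately simplified
core of the gene-counts family of stemness scores: the
expression-similarity smoothing step of the full published method is
omitted, the score is validated only against synthetic activity
gradients, and it is never claimed to equal the original tool's output.

## Synthetic data

**Bulk.** Each sample gets a subgroup by categorical draw (default shares
0.29 SHH / 0.19 Group3 / 0.43 Group4 / 0.09 WNT, mirroring a large
published cohort's composition) and a latent stromal fraction
`s ~ Beta(a, b)` with subgroup-specific shapes — SHH-like Beta(5, 2)
(stroma-rich), Group3-like Beta(2, 5) (stroma-poor), Beta(3, 3)
otherwise. A Beta latent is the simplest bounded choice. Expression is
`baseline + effects + N(0, noise_sd)` on the log2 scale (Gaussian noise
matches array-like data): stromal-signature genes add
`signature_coupling * s` (default 2.0), immune genes track an independent
Beta(2, 5) immune latent, and the 30 planted driver genes add
`driver_log2fc * 1[subgroup = SHH] + driver_stroma_coupling * s`
(defaults 1.5 and 1.2; with `noise_sd = 0.5` the implied population
gene-score correlation is near 0.5 at n = 200, the regime the recovery
guarantees are calibrated in). 150 decoy receptor/ligand genes carry no
signal, making false-discovery proportions measurable; drivers and
decoys are paired into a ligand/receptor table.

**Single cell.** Per tumour, cell activity `a ~ Beta`, with metastatic
tumours drawn from Beta(4, 2) and non-metastatic from Beta(2, 4) —
planting the direction the metastasis contrast must detect. Associate
genes are detected with probability
`logistic(detection_coupling * (a - 0.5))` (default slope 6, spanning
detection probabilities ~0.05–0.95); every other gene's
negative-binomial mean (fixed dispersion 2) is scaled by
`exp(potential_coupling * (a - 0.5))` (default 1.5) so the detected-gene
count rises with activity. Counts are normalised per cell to a 1e4 total
and natural-log1p transformed, the standard droplet-pipeline
normalisation. All draws flow from one seeded generator, so identical
configs are bit-reproducible.

**What the generator does not emulate:** batch effects, doublets, ambient
RNA, gene-length/GC bias, tumour-level expression covariance beyond the
planted latents, or realistic signature co-expression structure. Passing
recovery tests therefore demonstrates that the pipeline's logic recovers
the structures it targets under its stated statistical model — not that
it would do so at the same rates on real cohorts.

## Numerical and design choices

- Percentages in cohort summaries are rounded half-up to one decimal
  (`decimal.Decimal`, not banker's rounding), the convention of the
  cohort reports this mirrors.
- ssGSEA walking order breaks expression ties by gene label (not storage
  position), so the score is invariant to gene reordering even with tied
  values; tied genes additionally share average-rank weights.
- Pearson r is clipped to [-1, 1] before the t-transform; `|r| = 1` maps
  to `p = 0`.
- Constant genes: excluded from correlation screens (flagged
  `defined = False`), isolated nodes in networks, never potential
  signature members.
- PC1 sign ambiguity is resolved by non-negative correlation with mean
  module expression, making the meta-gene deterministic.
- The pipeline's per-stage problem sizes used in the test and acceptance
  runs — 200 samples x 2000 genes bulk, 10 tumours x 300 cells x 1500
  genes single-cell, 20 Monte-Carlo seeds — were chosen as the smallest
  sizes at which the planted effects are comfortably identifiable.

## Known limitations

- The DGE screen has no variance moderation or covariate adjustment; at
  small group sizes the literal `p < 0.05` screen is anti-conservative.
- The cell-level metastasis contrast treats cells as exchangeable; the
  per-tumour summary is reported precisely because that assumption is
  wrong in general.
- The potential score's omission of similarity smoothing means noisy
  cells are not shrunk toward neighbours; on real data the full published
  estimator should be preferred.
- Gene identifiers are opaque strings: no alias or ortholog resolution.
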