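# stromascope

Stromal-microenvironment analysis of medulloblastoma transcriptomes.

Medulloblastoma, the most common malignant paediatric brain tumour,
comprises four molecular subgroups (WNT, SHH, Group 3, Group 4) whose
microenvironments differ sharply: the SHH subgroup is stroma-enriched
while Group 3 is stroma-suppressed. `stromascope` implements the analysis
chain that characterises this difference and traces it to single cells:

- **Signature scoring** — per-sample stromal/immune enrichment by an
  ssGSEA-style rank statistic: for sample expression `x` over `N` genes
  and signature `S`, walking genes in descending expression order,
  `ES = Σ_i [P_in(i) − P_out(i)]` with rank weights `rank(x_g)^α`
  (α = 0.25). Also a scaled-average signature score
  `mean_{g∈S} z_g − mean_{g∉S} z_g` and a PC1 module meta-gene.
- **Stroma-associate screening** — Welch differential expression of a
  subgroup against the pooled rest plus per-gene Pearson correlation with
  the stromal score; receptor/ligand genes passing `|FC| > 2`,
  `|r| > 0.2`, `p < 0.05` (both tests) are classified as stroma
  *drivers* (positive correlation) or *suppressors* (negative).
- **Network centrality** — thresholded Pearson co-expression networks
  over the associates (|r| ≥ 0.6 bulk, ≥ 0.2 single cell, p < 0.05),
  ranked by Wasserman–Faust closeness centrality.
- **Cell states** — per-cell associate counts; stroma-active (> 5
  associates) vs stroma-inactive (< 2) classes; Wilcoxon/BH marker
  detection; a metastasis contrast; and a simplified gene-counts
  developmental-potential score in [0, 1].
- **Synthetic cohorts** — a generator that plants subgroup structure,
  latent stromal fractions, driver genes and per-cell activity gradients,
  so the whole pipeline is testable end-to-end without external data.

The statistical core is exposed as scikit-learn-style estimators
(`SignatureScorer`, `DifferentialExpressionScreen`, `AssociateClassifier`,
`CorrelationNetwork`, `CellActivityProfiler`, `DevelopmentalPotential`, …)
with plain functions as thin wrappers, so the pieces compose with sklearn
pipelines and model selection.

## Worked example

```python
import stromascope as ss
from scipy.stats import spearmanr

bulk = ss.generate_bulk(ss.BulkSimConfig(seed=1))          # 2000 genes x 200 samples
scores = ss.score_table(bulk.matrix, [bulk.stromal_signature,
                                      bulk.immune_signature])
print(scores["stromal"].groupby(bulk.annotation["subgroup"]).mean().round(1))
```

```
subgroup
Group3    372.2
Group4    511.5
SHH       655.7
WNT       541.4
```

The stromal score separates the subgroups exactly as planted: the
SHH-like subgroup is the most stroma-enriched and the Group3-like
subgroup the most suppressed, and the score tracks each sample's latent
stromal fraction (`spearmanr(...) = 0.986`). Screening both subgroups
against the pooled rest and classifying receptor/ligand genes:

```python
enr = ss.screen(bulk.matrix, bulk.annotation, scores["stromal"], "SHH")
sup = ss.screen(bulk.matrix, bulk.annotation, scores["stromal"], "Group3")
assoc = ss.classify_associates(enr, sup, bulk.rl_table,
                               exclude=[bulk.stromal_signature,
                                        bulk.immune_signature])
# -> 30 associates, 30 drivers  (all 30 planted drivers, no false positives)

G = ss.build_network(bulk.matrix, assoc, r_min=0.6)
ss.closeness(G).sort_values(ascending=False).head(3)
# G00101    1.0
# G00102    1.0
# G00103    1.0   (drivers are mutually stroma-coupled, so the graph is dense)
```

On paired synthetic single cells the per-cell driver counts classify
cells into stroma states, and the developmental-potential score rises
with stroma activity, mirroring the gradient planted by the generator:

```python
sc = ss.generate_sc(ss.ScSimConfig(seed=2), bulk.truth["drivers"])
counts = ss.count_associates(sc.matrix, assoc)
counts["state"] = ss.classify_state(counts["n_total"])   # 2397 active / 496 intermediate / 107 inactive
pot = ss.dev_potential(sc.matrix)
ss.potential_vs_activity(pot, counts)                    # r = 0.93, p < 1e-300
```

## Command line

Every stage is a subcommand (`simulate`, `summarize`, `score`, `screen`,
`associates`, `network`, `cellstate`, `potential`), and `stromascope run
--config examples/run.yaml` executes the whole pipeline from one YAML
config, writing stage outputs plus a `manifest.json` with SHA-256 hashes
of every input and output (identical config + seed ⇒ identical hashes).

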