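# grangersift

Minimal gene-predictor panels from multi-omics screens, for systems
biologists who need a handful of marker genes that separate tumor from
normal samples without losing classification accuracy.

Large differential screens routinely return thousands of candidate
genes. `grangersift` reduces them in five stages, each with an explicit
statistical contract:

1. **Differential screening** — per-gene Welch t-tests on expression
   (|log2FC| ≥ 1, BH-FDR ≤ 0.01), methylation beta values (p ≤ 0.01,
   |Δβ| ≥ 0.35) and miRNA expression; targets of > 2 differential miRNAs
   also qualify. Any hit in any channel is a *diff-gene*.
2. **Multi-interaction network** — co-location, physical and
   shared-protein-domain interactions induce a multigraph on the
   diff-genes; high-degree nodes (degree counted with channel
   multiplicity) are the *feature genes*.
3. **Granger directing** — every *interacting* feature-gene pair is run
   through a gated cascade on time-series expression: Pearson
   correlation (α = 0.01), ADF unit-root and Engle–Granger
   cointegration checks, then Granger F-tests in both directions
   (α = 0.05). An edge `a → b` is kept only when the past of `a` helps
   predict `b` and the reverse does not hold.
4. **Independence screen** — on the directed network, genes with
   in-degree 0 (sources, isolated nodes) and members of feedback
   subnetworks (nontrivial strongly connected components) are the
   *globally independent genes*: the dominant regulators.
5. **Stepwise character selection** — a forward-add /
   conditional-backward-remove wrapper around stratified 5-fold
   Random-Forest CV accuracy (ntree = 500, mtry = √p), with tolerance ε:
   while the panel's accuracy has not fallen by more than ε, adopt the
   best addition, then drop any member whose removal strictly improves
   accuracy. Panels are scored by ACC, SN, SP, MCC and AUC.

A synthetic-data module generates statistically controlled inputs for
every stage (planted differential genes, planted VAR(1) causal
couplings, random typed interaction graphs), so the whole pipeline can
be exercised and calibrated without any external data.

## Worked example

Generate the standard synthetic study (40 genes, 60/60 samples, 150
time points, three planted discriminative genes G000–G002 that double as
causal sources) and run the pipeline end-to-end:

```sh
grangersift simulate --seed 1 --outdir study/
grangersift run \
    --expression study/expression.tsv --labels study/labels.tsv \
    --timeseries study/timeseries.tsv --interactions study/interactions.tsv \
    --methylation study/methylation.tsv --mirna study/mirna.tsv \
    --mirna-targets study/mirna_targets.tsv \
    --config study_config.yaml --outdir study/out/
```

with `study_config.yaml` holding the study-scale settings
(`feature_degree_cut: 0`, `n_trees: 100`, `n_repeats: 2`,
`epsilon: 0.0`, `max_iterations: 40`, `seed: 1`). The run prints

```
predictors: G000, G001, G002, G009 (ACC 0.983, AUC 0.997)
```

i.e. from 40 genes the pipeline kept 12 diff-genes, directed their
interaction network, screened 7 globally independent candidates, and
selected a 4-gene panel containing all three planted markers (G009 is a
moderate planted DEG) with 98.3 % cross-validated accuracy. Every
intermediate — differential tables, degrees, the directed network with
per-edge test diagnostics, the selection trace, ROC points and a
provenance log — is written under `study/out/`.

The same pipeline is available as a library:

```python
import grangersift as gs

spec = gs.default_spec(seed=1)
expr, labels, truth = gs.simulate_expression(spec)
ts, _ = gs.simulate_var_timeseries(spec)
res = gs.run_pipeline(
    gs.PipelineConfig(feature_degree_cut=0, n_trees=100, n_repeats=2,
                      epsilon=0.0, seed=1),
    expression=expr, labels=labels, timeseries=ts,
    interactions=gs.simulate_interactions(spec),
)
print(res.predictors, round(res.metrics.acc, 3))
```

For real studies, point the same commands at your own TSV matrices
(genes × samples, tab-separated; see `docs/methods.md` for formats and
for every tunable threshold).

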