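# scsurv

Gene prioritization from single-cell RNA-seq and miRNA-targeting data for
penalized Cox survival modeling.

## The problem

Prognostic gene signatures for colorectal cancer are usually built from bulk
RNA-seq alone, which averages away tumor-cell heterogeneity and ignores
post-transcriptional regulation. `scsurv` ranks candidate genes by combining
three complementary signals before any survival model sees them:

* **miRNA** — how many distinct miRNAs are predicted to target the gene
  (row sums of a binary genes × miRNAs interaction matrix built from a
  TargetScan-style export);
* **MAD** — the median absolute deviation of the gene's processed
  single-cell expression, a robust measure of expression variability;
* **SDE** — switch-like differential expression: the steepness |κ| of a
  sigmoid fit of expression against a pseudotime that orders cells by the
  expression of a mesenchymal marker (VIM) as a proxy for progression
  through the epithelial–mesenchymal transition,

  f(t) = 2·μ₀ / (1 + exp(−κ·(t − t₀))).

Each metric is normalized to sum to 1 over its gene universe and combined as

    w = a₁·w_SDE + a₂·w_MAD + a₃·w_miRNA,   a₁ + a₂ + a₃ = 1,

with a gene lacking miRNA-targeting information contributing 0 for that
metric. The weights are chosen by an exhaustive simplex grid search (default
spacing 0.1) scored by the mean cross-validated concordance index of a
LASSO-penalized Cox proportional-hazards model fitted to the top-ranked
genes in a bulk cohort with survival follow-up. The fitted model is
evaluated by the concordance index

    C = #(concordant comparable pairs) / #(comparable pairs),

where a pair is comparable when the patient with the shorter observed time
had an observed event, and by Kaplan–Meier curves of median-risk-split
patient groups compared with a log-rank test, χ² = Σ_groups (O − E)²/E.
Genes with hazard ratio exp(β) > 2 are reported as risk-increasing and
< 0.5 as risk-decreasing.

Everything is testable without external downloads: the `simulate` module
generates all three input kinds (single-cell counts with planted switch
genes, miRNA-target pairs with planted hubs, and a proportional-hazards
survival cohort) with known ground truth.

## Worked example

```python
import numpy as np
import scsurv as s

# synthetic inputs with 12 planted switch genes that also drive the hazard
mat, truth, _ = s.simulate_sc_matrix(
    s.ScSimSpec(n_genes=60, n_cells=200, frac_switch=0.2, noise_sd=0.05, seed=101))
planted = truth.index[truth.cls == "switch"].tolist()
pre = s.preprocess(mat, min_cells=10, knn=5, steps=3, pca_dims=10)
ordering = s.order_by_marker(pre, "VIM")

sde = s.normalize_scores(s.sde_metric(pre, ordering))
mad = s.normalize_scores(s.mad_metric(pre))
pairs = s.simulate_interactions(n_mirnas=60, n_genes=60, density=0.08,
                                hub_genes=planted, hub_boost=6.0, seed=102,
                                gene_ids=mat.gene_ids)
mirna = s.normalize_scores(s.mirna_metric(s.build_interaction_matrix(pairs)))

cohort, _ = s.simulate_survival_cohort(
    s.SurvSimSpec(n_patients=250, signature_betas={g: 0.8 for g in planted},
                  censor_rate=0.2, seed=103),
    expression_source=mat)

best, table = s.grid_search_weights(
    s.enumerate_weight_grid(0.25), sde, mad, mirna, cohort,
    n_top=15, cv_folds=5, seed=104, lambda_strategy="fixed", lam=0.01)
top = s.select_top(s.combine_scores(sde, mad, mirna, best), 15)
print("planted recovered in top 15:", len(set(top) & set(planted)), "/", len(planted))
print("mean CV C-index at best weights:", round(table["mean_cindex"].max(), 4))
```

prints

```
planted recovered in top 15: 12 / 12
mean CV C-index at best weights: 0.8755
```

meaning all planted genes were re-identified by the combined ranking and
the LASSO Cox model on them discriminates survival well above the chance
level of 0.5. Fitting the model on the top genes and splitting patients at
the median risk score separates the groups decisively (log-rank statistic
165.1, p ≈ 9e-38), and five genes exceed the hazard-ratio threshold of 2
(per standard deviation of expression).

The same pipeline is available from the shell via the `scsurv` command with
subcommands `simulate`, `preprocess`, `pseudotime`, `metrics`, `prioritize`,
`grid-search` and `fit-survival` (see `scsurv --help`). Single-cell CSVs
have genes as rows; bulk expression CSVs have patients as rows.

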