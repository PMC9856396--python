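# Methods

## Pipeline overview

`scsurv` turns three inputs — a genes × cells single-cell count matrix, a
miRNA–gene interaction table, and a bulk cohort with right-censored survival
follow-up — into a ranked gene list and a penalized Cox survival model. The
stages are: single-cell preprocessing → marker-based pseudotime → three
per-gene metrics → normalized weighted combination with grid-searched
weights → LASSO Cox fitting and evaluation.

## Single-cell preprocessing

The order is fixed: filter → library-size normalize → square-root transform
→ diffusion denoise. Each stage is recorded on the matrix and enforced, so
a metric cannot accidentally be computed on raw counts.

* **Filtering** keeps genes with strictly positive raw counts in at least
  `min_cells_per_gene` cells (default 10). "Expressed" is evaluated on raw
  counts, the simplest defensible reading.
* **Normalization** is two-step: each cell is scaled to proportions
  (column sum 1), then all cells are multiplied by the median of the
  original per-cell totals, so every cell ends at the median library size.
  Within-cell expression ratios are preserved exactly.
* **Square root** stabilizes variance without the pseudocounts a log
  transform would need on zeros.
* **Denoising** diffuses each gene's profile over a cell–cell Markov
  graph. Distances are Euclidean in a PCA projection (default 20
  components, capped by the data); an adaptive Gaussian kernel with
  per-cell bandwidth equal to the distance to the `denoise_knn`-th
  neighbor (default 5) and exponent `denoise_decay` (default 2) gives an
  affinity matrix, which is symmetrized and row-normalized into a
  transition matrix P. The output is the matrix right-multiplied by
  (P^steps)ᵀ over the cell axis; `denoise_steps` is an integer diffusion
  time (default 3), not a matrix exponential, and steps = 0 is the
  identity. Tiny negative values from floating-point round-off are clipped
  to 0 to preserve nonnegativity. No rescaling back to the original data
  range and no adaptive selection of the diffusion time is attempted.

## Pseudotime

Cells are ordered by the expression of one mesenchymal marker gene
(default VIM) as a proxy for progression through the epithelial–
mesenchymal transition: t = (rank − 1)/(n − 1) in [0, 1], with ties broken
lexicographically by cell id so the ordering is deterministic and invariant
to any strictly monotone transform of the marker. This is deliberately not
trajectory inference — no graph, no branching, no attractor analysis; the
ordering only provides a common axis for the switch fits. Whether to use
raw marker expression or its rank as t is genuinely open; the rank-rescaled
form was chosen because it is invariant to the upstream transform choices.
A diagnostic reports the Spearman correlation of listed epithelial and
mesenchymal genes with t (epithelial genes should trend negative,
mesenchymal positive); rank correlation is used because the square-root
transform makes product–moment correlations scale-dependent. A small
editable E/M marker list ships with the package.

## Metrics

* **miRNA**: from deduplicated (miRNA, gene) pairs, each miRNA keeps its
  first `top_k_targets_per_mirna` genes (input order is the provider's
  ranking; default 50, a realistic prediction-export depth — no
  authoritative value exists). The score is the row sum of the resulting
  0/1 matrix: integers in [0, m]. Genes absent from the table are handled
  at combination time (score 0), not here.
* **MAD**: median of |eᵢ − median(e)| per gene, computed on the denoised
  matrix by default. No 1.4826 consistency factor is applied — the score
  is used for ranking, not as a variance estimate. MAD is shift-invariant
  and positively homogeneous.
* **SDE**: maximum-likelihood fit of the sigmoid mean with iid Gaussian
  noise (equivalently nonlinear least squares; σ is the RMS residual).
  Zero-inflation is deliberately not modeled. The fit is multimodal in
  (κ, t₀), so a multi-start is used: κ₀ ∈ {−10, −1, 1, 10},
  t₀ ∈ {0.25, 0.5, 0.75}, μ₀ = half the maximum expression; best
  log-likelihood wins and near-ties (within 1e-6) resolve to the smallest
  |κ|, which makes flat genes land at κ ≈ 0 rather than an arbitrary sign.
  μ₀ is bounded below by 0. The score is |κ| so up- and down-switching
  genes both rank high and raw scores stay nonnegative as the
  normalization step requires; genes whose fit does not converge (e.g.
  all-zero profiles) score 0. No significance testing of the fits is done.

## Combination and weight search

Each metric is normalized by dividing by its own total, so normalized
scores are in [0, 1] and sum to 1 over that metric's gene universe. The
combined score is the convex combination over the union universe with
missing entries treated as 0; consequently w ∈ [0, 1] and the total
combined mass is at most 1. Ranking ties break by gene id.

The weight triples live on a simplex lattice with spacing `grid_step`
(default 0.1, giving 66 triples; in general (k+1)(k+2)/2 with k = 1/step),
enumerated in lexicographic order. Each triple is scored by the mean
cross-validated concordance of a LASSO Cox model on the top
`n_top_genes` genes (default 500; desk-scale analyses use smaller values
matched to their simulated gene universes). The CV folds are fixed by the
seed across all triples so that C-index differences reflect the weights,
not fold noise; ties go to the first triple in grid order and the full
audit table is returned. The search uses CV on the full cohort, which can
be optimistic relative to a held-out split; this is a known limitation.

## Survival modeling

Covariates are standardized (mean 0, sd 1) before fitting, so hazard
ratios are per standard deviation of expression — output headers say so.
L1-penalized fitting is delegated to scikit-survival's coordinate-descent
elastic net (l1_ratio = 1) with Breslow tie handling; the penalty `lam` is
on that solver's scale (mean partial log-likelihood minus lam·Σ|β|; a
sample-size factor only rescales the λ axis, not the solution path).
`lam = 0` routes to the unpenalized Breslow fitter. Zero-variance genes
are dropped with a warning. Two λ strategies exist: `fixed`, and
`cv_within_train`, which picks λ from the coordinate-descent path by
5-fold held-out partial likelihood inside each training split so no test
information leaks into the choice.

* **Concordance index**: a pair is comparable when the patient with the
  shorter observed time had an observed event; tied risk scores count 1/2,
  which keeps C(r) + C(−r) = 1 exact in the absence of ties. Implemented
  by explicit pair counting (O(n²), fine at cohort scale).
* **Cross-validated concordance**: event-stratified folds dealt
  round-robin from a seeded shuffle; per fold the model is fitted on the
  training split and the C-index evaluated on the held-out split. Folds
  with fewer than 2 training events or no comparable test pairs are
  skipped with a warning.
* **Kaplan–Meier**: the standard product-limit estimator — at each
  distinct event time a factor (1 − d/n) with d deaths and n at risk;
  censored subjects remain at risk through their follow-up time. A plain
  single-interval fraction cannot accommodate censoring, which is why the
  product-limit form is used. With no censoring the curve equals
  1 − ECDF.
* **Log-rank**: the chi-squared form Σ_groups (O − E)²/E with expected
  deaths allocated by at-risk shares at each event time, referred to χ²
  with 1 df and the conventional 0.05 significance threshold. This is the
  simple (unweighted-variance) form, which is slightly conservative
  relative to the variance-weighted statistic.
* **Stratification**: patients split at the median linear predictor, ties
  to low risk. Genes are classed risk-increasing when exp(β) > 2 and
  risk-decreasing when exp(β) < 0.5 (strict inequalities), configurable.

## Synthetic data

The generators are pure functions of their spec (seed included) and
emulate the three input kinds:

* **Single-cell matrix**: latent pseudotime uniform per cell; a
  `frac_switch` fraction of genes follows the sigmoid mean with |κ| drawn
  from `kappa_range` (default 8–15, random sign), μ₀ from 1–3 and t₀ from
  0.2–0.8; remaining genes are flat. One designated marker gene switches
  upward with steepness `marker_kappa` (default 12) so the marker-rank
  pseudotime recovers the latent ordering. Gaussian noise (default sd 0.1)
  is added, truncated at 0, and values are scaled (default ×25) and
  rounded to counts. This emulates switch-like structure only — there is
  no negative-binomial sampling, dropout or batch structure, so passing
  tests demonstrate correctness of the machinery, not robustness to real
  scRNA-seq noise.
* **Interactions**: independent Bernoulli(density) per (miRNA, gene) pair,
  with hub genes boosted to min(1, density·hub_boost).
* **Survival cohort**: covariates iid standard normal; event times
  exponential with rate baseline_hazard·exp(Σβx) (the simplest model in
  which proportional hazards holds exactly, so Cox recovery is
  well-posed); independent exponential censoring whose rate is calibrated
  by root-finding so the expected censored fraction matches `censor_rate`.

## Problem sizes

Default analyses in the test suite and examples run at desk scale: tens of
genes, a few hundred cells, cohorts of 100–300 patients, 4–5 CV folds, and
simplex grids at spacing 0.25–0.5 (the 0.1 grid is exercised where only
enumeration is needed). These sizes are the package's chosen study
conditions for synthetic validation; all algorithms scale to full-size
inputs unchanged.

## Known limitations

* Pseudotime is a single-marker rank; multimodal or non-monotone EMT
  progression is out of scope.
* The weight search evaluates CV on the same cohort used for the final
  model, a potential optimism source.
* The log-rank statistic is the simple chi-squared form; no stratified or
  weighted variants.
* No elastic-net mixing, time-dependent covariates, competing risks, or
  confidence bands beyond the point estimates.
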