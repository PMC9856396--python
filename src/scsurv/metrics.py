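"""Per-gene prioritization metrics.

Three raw scores feed the weighted combination downstream:

* **miRNA** — the number of distinct miRNAs predicted to target the gene,
  read off as row sums of a binary genes x miRNAs interaction matrix.
* **MAD** — the median absolute deviation from the median of the gene's
  (processed) expression across cells; a robust dispersion score.  No
  consistency scaling factor is applied.
* **SDE** — switch-like differential expression: the absolute steepness
  |kappa| of a sigmoid fit of expression against pseudotime,

      f(t) = 2*mu0 / (1 + exp(-kappa * (t - t0)))

  where mu0 is the average peak expression, kappa the activation
  nonlinearity and t0 the activation offset.  Genes that switch on or off
  sharply along the ordering score high; flat genes score ~0.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import (
    ExpressionMatrix,
    InteractionMatrix,
    MetricScores,
    PseudotimeOrdering,
    SigmoidFit,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# miRNA interaction metric
# ---------------------------------------------------------------------------

def build_interaction_matrix(
    pairs: list[tuple[str, str]], top_k_targets: int = 50
) -> InteractionMatrix:
    """Build the binary genes x miRNAs matrix from ranked (miRNA, gene) pairs.

    Input order encodes the provider's target ranking: for each miRNA only
    its first `top_k_targets` genes are retained.  Duplicate pairs are
    idempotent.  Axis labels are the union over retained pairs, in first
    appearance order.
    """
    if not pairs:
        raise ValueError("no interaction pairs provided")
    if top_k_targets < 1:
        raise ValueError("top_k_targets must be >= 1")
    per_mirna: dict[str, list[str]] = {}
    for m, g in pairs:
        targets = per_mirna.setdefault(m, [])
        if g not in targets and len(targets) < top_k_targets:
            targets.append(g)
    genes: list[str] = []
    for targets in per_mirna.values():
        for g in targets:
            if g not in genes:
                genes.append(g)
    mirnas = list(per_mirna)
    if not genes:
        warnings.warn("no interactions retained; interaction matrix is empty")
    entries = pd.DataFrame(0, index=genes, columns=mirnas, dtype=int)
    for m, targets in per_mirna.items():
        entries.loc[targets, m] = 1
    return InteractionMatrix(entries=entries)


def mirna_metric(interactions: InteractionMatrix) -> MetricScores:
    """Raw miRNA score per gene: its total number of interacting miRNAs."""
    scores = interactions.entries.sum(axis=1).astype(float)
    return MetricScores(metric="miRNA", scores=scores, normalized=False)


# ---------------------------------------------------------------------------
# MAD metric
# ---------------------------------------------------------------------------

def mad_metric(matrix: ExpressionMatrix) -> MetricScores:
    """Raw MAD score per gene: median |e_i - median(e)| across cells."""
    X = matrix.values.to_numpy(dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1)
    return MetricScores(
        metric="MAD",
        scores=pd.Series(mad, index=matrix.values.index),
        normalized=False,
    )


# ---------------------------------------------------------------------------
# SDE metric (sigmoid switch fit)
# ---------------------------------------------------------------------------

def sigmoid(t: np.ndarray, mu0: float, kappa: float, t0: float) -> np.ndarray:
    """Switch-like mean function: 2*mu0 / (1 + exp(-kappa*(t - t0)))."""
    z = np.clip(kappa * (np.asarray(t, dtype=float) - t0), -500, 500)
    return 2.0 * mu0 / (1.0 + np.exp(-z))


def _gaussian_loglik(resid: np.ndarray) -> tuple[float, float]:
    n = resid.size
    sse = float(resid @ resid)
    sigma2 = max(sse / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return ll, float(np.sqrt(sigma2))

#: Multi-start grid for the sigmoid fit; the surface is multimodal in
#: (kappa, t0) so several steepness signs/magnitudes and offsets are tried.
_KAPPA_STARTS = (-10.0, -1.0, 1.0, 10.0)
_T0_STARTS = (0.25, 0.5, 0.75)


def fit_sigmoid(expression: np.ndarray, t: np.ndarray) -> SigmoidFit:
    """Maximum-likelihood sigmoid fit under iid Gaussian noise.

    Runs a small multi-start of bounded least squares (Gaussian MLE for the
    mean parameters); the best log-likelihood wins, with near-ties resolved
    toward the smallest |kappa|.
    """
    y = np.asarray(expression, dtype=float)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise ValueError("non-finite expression or pseudotime values")
    if y.size < 8:
        raise ValueError("sigmoid fit requires at least 8 cells")
    if not y.any():
        return SigmoidFit(mu0=0.0, kappa=0.0, t0=0.5, sigma=0.0, converged=False)

    mu0_start = max(float(y.max()) / 2.0, 1e-8)
    best: SigmoidFit | None = None
    for k0 in _KAPPA_STARTS:
        for t00 in _T0_STARTS:
            try:
                res = least_squares(
                    lambda p: sigmoid(t, *p) - y,
                    x0=[mu0_start, k0, t00],
                    bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                    method="trf",
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            ll, sigma = _gaussian_loglik(res.fun)
            fit = SigmoidFit(
                mu0=float(res.x[0]),
                kappa=float(res.x[1]),
                t0=float(res.x[2]),
                sigma=sigma,
                converged=bool(res.success),
                loglik=ll,
            )
            if best is None:
                best = fit
            elif ll > best.loglik + 1e-6:
                best = fit
            elif abs(ll - best.loglik) <= 1e-6 and abs(fit.kappa) < abs(best.kappa):
                best = fit
    if best is None:
        return SigmoidFit(mu0=0.0, kappa=0.0, t0=0.5, sigma=0.0, converged=False)
    return best


def sde_metric(matrix: ExpressionMatrix, ordering: PseudotimeOrdering) -> MetricScores:
    """Raw SDE score per gene: |kappa| of the sigmoid fit against pseudotime.

    Non-converged fits (e.g. all-zero genes) score 0 so that raw scores
    remain nonnegative and finite for every gene.
    """
    t = ordering.as_series().reindex(matrix.cell_ids)
    if t.isna().any():
        raise ValueError("pseudotime ordering does not cover all cells of the matrix")
    tv = t.to_numpy()
    scores = {}
    for gene in matrix.values.index:
        fit = fit_sigmoid(matrix.values.loc[gene].to_numpy(), tv)
        scores[gene] = abs(fit.kappa) if fit.converged else 0.0
    return MetricScores(
        metric="SDE", scores=pd.Series(scores, dtype=float), normalized=False
    )
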