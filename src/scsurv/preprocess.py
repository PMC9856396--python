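"""Single-cell expression preprocessing.

The fixed pipeline order is: gene filtering on raw counts, library-size
normalization, square-root transform, then graph-diffusion denoising.  Each
step advances the :class:`~scsurv.containers.ExpressionMatrix` stage tag and
refuses out-of-order application.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_genes(matrix: ExpressionMatrix, min_cells: int = 10) -> ExpressionMatrix:
    """Keep genes with nonzero raw expression in at least `min_cells` cells.

    "Expressed" means strictly positive raw counts; the cell axis is never
    touched.
    """
    if matrix.stage != "raw":
        raise ValueError(f"filter_genes expects stage 'raw', got {matrix.stage!r}")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    breadth = (matrix.values.to_numpy() > 0).sum(axis=1)
    keep = breadth >= min_cells
    if not keep.any():
        raise ValueError(
            f"no gene is expressed in >= {min_cells} cells; lower the threshold"
        )
    kept = matrix.values.loc[keep]
    logger.info("filter_genes: retained %d/%d genes", keep.sum(), matrix.n_genes)
    return matrix.advance(kept, "filtered")


def normalize_library_size(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalize: scale each cell to sum 1, then rescale all
    cells by the median of the original per-cell totals.

    Within-cell proportions are preserved exactly; after the rescale every
    cell has the same total (the median library size).
    """
    if matrix.stage != "filtered":
        raise ValueError(
            f"normalize_library_size expects stage 'filtered', got {matrix.stage!r}"
        )
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals.to_numpy() == 0].tolist()
    if zero:
        raise ValueError(f"cells with zero total expression: {zero}")
    median_total = float(np.median(totals.to_numpy()))
    normed = matrix.values.div(totals, axis=1) * median_total
    return matrix.advance(normed, "normalized")


def sqrt_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise square root; variance-stabilizing without pseudocounts."""
    if matrix.stage != "normalized":
        raise ValueError(
            f"sqrt_transform expects stage 'normalized', got {matrix.stage!r}"
        )
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative entries upstream of sqrt_transform")
    return matrix.advance(np.sqrt(matrix.values), "transformed")


def markov_transition_matrix(
    matrix: ExpressionMatrix,
    knn: int,
    decay: float = 2.0,
    pca_dims: int = 20,
    random_state: int = 0,
) -> np.ndarray:
    """Cell-cell Markov transition matrix from an adaptive Gaussian kernel.

    Distances are Euclidean in a PCA projection (at most `pca_dims`
    components).  The kernel bandwidth adapts per cell to the distance of its
    knn-th neighbor, with kernel exp(-(d/sigma)^decay); the affinity is
    symmetrized and row-normalized so each row sums to 1.
    """
    n_cells = matrix.n_cells
    if knn >= n_cells:
        raise ValueError(f"knn ({knn}) must be < number of cells ({n_cells})")
    if decay <= 0:
        raise ValueError("decay must be positive")
    X = matrix.values.to_numpy().T  # cells x genes
    n_comp = min(pca_dims, n_cells - 1, X.shape[1])
    if n_comp >= 1:
        X = PCA(n_components=n_comp, random_state=random_state).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=min(knn + 1, n_cells)).fit(X)
    knn_dist, _ = nn.kneighbors(X)
    sigma = knn_dist[:, -1]  # distance to knn-th neighbor (excluding self)
    sigma = np.where(sigma <= 0, np.finfo(float).eps, sigma)
    from scipy.spatial.distance import cdist

    D = cdist(X, X)
    A = np.exp(-((D / sigma[:, None]) ** decay))
    A = (A + A.T) / 2.0
    P = A / A.sum(axis=1, keepdims=True)
    return P


def diffusion_denoise(
    matrix: ExpressionMatrix,
    knn: int = 5,
    decay: float = 2.0,
    steps: int = 3,
    pca_dims: int = 20,
) -> ExpressionMatrix:
    """Denoise by diffusing expression over the cell-cell Markov graph.

    Each gene's profile is replaced by its t-step diffusion: for output cell
    c, the new value is the P^steps-weighted average of that gene over all
    cells.  steps = 0 is the identity.
    """
    if matrix.stage != "transformed":
        raise ValueError(
            f"diffusion_denoise expects stage 'transformed', got {matrix.stage!r}"
        )
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return matrix.advance(matrix.values.copy(), "denoised")
    P = markov_transition_matrix(matrix, knn=knn, decay=decay, pca_dims=pca_dims)
    Pt = np.linalg.matrix_power(P, steps)
    denoised = matrix.values.to_numpy() @ Pt.T
    denoised = np.clip(denoised, 0.0, None)  # guard tiny negative round-off
    out = pd.DataFrame(denoised, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.advance(out, "denoised")


def preprocess(
    matrix: ExpressionMatrix,
    min_cells: int = 10,
    knn: int = 5,
    decay: float = 2.0,
    steps: int = 3,
    pca_dims: int = 20,
) -> ExpressionMatrix:
    """Run the full preprocessing chain: filter, normalize, sqrt, denoise."""
    m = filter_genes(matrix, min_cells=min_cells)
    m = normalize_library_size(m)
    m = sqrt_transform(m)
    return diffusion_denoise(m, knn=knn, decay=decay, steps=steps, pca_dims=pca_dims)
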