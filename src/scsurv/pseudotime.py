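"""Marker-based pseudotime.

Cells are ordered by the expression of a single mesenchymal marker gene
(default VIM) as a proxy for progression through the epithelial-mesenchymal
transition.  This is a deterministic rank transform, not trajectory
inference: the ordering only provides a common axis against which per-gene
switch-like behavior is fitted.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import ExpressionMatrix, PseudotimeOrdering


def _closest_matches(target: str, candidates: list[str], k: int = 5) -> list[str]:
    import difflib

    return difflib.get_close_matches(target, candidates, n=k, cutoff=0.0)


def order_by_marker(matrix: ExpressionMatrix, marker: str = "VIM") -> PseudotimeOrdering:
    """Rank cells by marker expression, rescaled to [0, 1].

    t = (rank - 1) / (n - 1) with ascending ranks; ties are broken by
    cell-id lexicographic order so the result is fully deterministic.
    """
    if marker not in matrix.values.index:
        hints = _closest_matches(marker, matrix.gene_ids)
        raise KeyError(f"marker gene {marker!r} not in matrix; closest: {hints}")
    expr = matrix.values.loc[marker]
    n = len(expr)
    order = sorted(range(n), key=lambda i: (expr.iloc[i], str(expr.index[i])))
    rank = np.empty(n, dtype=float)
    for r, i in enumerate(order):
        rank[i] = r
    t = rank / (n - 1) if n > 1 else np.zeros(n)
    return PseudotimeOrdering(cell_ids=[str(c) for c in expr.index], t=t)


def default_em_genes() -> pd.DataFrame:
    """Load the bundled epithelial/mesenchymal marker list (editable TSV)."""
    with resources.files("scsurv.data").joinpath("em_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def em_correlation_diagnostic(
    matrix: ExpressionMatrix,
    ordering: PseudotimeOrdering,
    e_genes: list[str],
    m_genes: list[str],
) -> pd.DataFrame:
    """Spearman correlation of each listed E/M gene's expression with pseudotime.

    A sensible EMT ordering shows epithelial genes anti-correlated and
    mesenchymal genes positively correlated with t.  Returns a table with
    columns gene, cls ("E"/"M"), correlation, plus summary fractions in
    ``DataFrame.attrs``: frac_e_negative, frac_m_positive.
    """
    present_e = [g for g in e_genes if g in matrix.values.index]
    present_m = [g for g in m_genes if g in matrix.values.index]
    if not present_e and not present_m:
        raise ValueError("none of the listed E/M genes are present in the matrix")
    t = ordering.as_series().reindex(matrix.cell_ids).to_numpy()
    rows = []
    for cls, genes in (("E", present_e), ("M", present_m)):
        for g in genes:
            rho = spearmanr(matrix.values.loc[g].to_numpy(), t).statistic
            rows.append({"gene": g, "cls": cls, "correlation": float(rho)})
    table = pd.DataFrame(rows)
    e_corr = table.loc[table.cls == "E", "correlation"]
    m_corr = table.loc[table.cls == "M", "correlation"]
    table.attrs["frac_e_negative"] = float((e_corr < 0).mean()) if len(e_corr) else np.nan
    table.attrs["frac_m_positive"] = float((m_corr > 0).mean()) if len(m_corr) else np.nan
    return table
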