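"""Readers and writers for the pipeline's tabular formats.

Conventions
-----------
* Single-cell expression: genes are rows, cells are columns (dense CSV), or a
  matrix-market triplet file with sidecar ``<stem>.genes.txt`` /
  ``<stem>.cells.txt`` label files (one identifier per line).
* Bulk expression: patients are rows, genes are columns (dense CSV).
* miRNA-target interactions: TSV with a header and at least the columns
  ``mirna`` and ``gene`` (extra provider columns are ignored).
* Clinical data: TSV with columns ``patient``, ``time`` (days) and
  ``status`` (1 = death observed, 0 = censored).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, SurvivalCohort

INTERACTION_COLUMNS = ("mirna", "gene")
CLINICAL_COLUMNS = ("patient", "time", "status")


def _label_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cells.txt")


def read_expression_matrix(path: str | Path, format: str = "csv") -> ExpressionMatrix:
    """Read a genes x cells expression matrix from CSV or matrix-market.

    CSV: first column gene ids, header row cell ids.  MTX: triplet file plus
    ``<stem>.genes.txt`` and ``<stem>.cells.txt`` label sidecars.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        genes_path, cells_path = _label_paths(path)
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'mtx'")
    return ExpressionMatrix(values=df.astype(float), stage="raw")


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, format: str = "csv"
) -> None:
    path = Path(path)
    if format == "csv":
        matrix.values.to_csv(path)
    elif format == "mtx":
        genes_path, cells_path = _label_paths(path)
        spio.mmwrite(path, sparse.coo_matrix(matrix.values.to_numpy()))
        genes_path.write_text("\n".join(matrix.gene_ids) + "\n")
        cells_path.write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_interaction_table(path: str | Path) -> list[tuple[str, str]]:
    """Read (miRNA, gene) pairs from a TSV, deduplicated in first-appearance order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in INTERACTION_COLUMNS if c not in cols]
    if missing:
        raise ValueError(
            f"interaction table missing column(s) {missing}; "
            f"expected header with {list(INTERACTION_COLUMNS)}"
        )
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for m, g in zip(df[cols["mirna"]], df[cols["gene"]]):
        pair = (str(m), str(g))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


def write_interaction_table(pairs: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=list(INTERACTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_clinical(path: str | Path) -> SurvivalCohort:
    """Read patient survival times and event indicators from a clinical TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in CLINICAL_COLUMNS if c not in cols]
    if missing:
        raise ValueError(
            f"clinical table missing column(s) {missing}; "
            f"expected header with {list(CLINICAL_COLUMNS)}"
        )
    time = pd.to_numeric(df[cols["time"]]).to_numpy(dtype=float)
    status = df[cols["status"]].to_numpy()
    for i, (t, s) in enumerate(zip(time, status)):
        if t < 0:
            raise ValueError(f"negative survival time at row {i + 1}")
        if s not in (0, 1):
            raise ValueError(f"event status must be 0 or 1, got {s!r} at row {i + 1}")
    return SurvivalCohort(
        patient_ids=[str(p) for p in df[cols["patient"]]],
        time=time,
        event=np.asarray(status, dtype=int),
    )


def write_clinical(cohort: SurvivalCohort, path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient": cohort.patient_ids,
            "time": cohort.time,
            "status": cohort.event,
        }
    ).to_csv(path, sep="\t", index=False)


def read_bulk_expression(path: str | Path) -> pd.DataFrame:
    """Read a patients x genes bulk expression CSV (patients are rows)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_ranked_genes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked-gene table as TSV: rank, gene, combined + per-metric scores."""
    out = table.copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
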