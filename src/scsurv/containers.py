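"""Core data containers shared across the pipeline.

All containers are thin, validated dataclasses around numpy/pandas objects.
Gene and cell identifiers are always strings and always unique per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Allowed processing stages, in pipeline order.
STAGES = ("raw", "filtered", "normalized", "transformed", "denoised")


def _check_unique(labels: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {axis} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionMatrix:
    """Genes x cells (or genes x patients) nonnegative expression matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are cells; entries finite and >= 0.
    stage : str
        One of :data:`STAGES`; transitions only move forward.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "cell")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite entry at gene {self.values.index[bad[0]]!r}, "
                f"cell {self.values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative entry at gene {self.values.index[bad[0]]!r}, "
                f"cell {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def cell_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix at `stage`, enforcing forward stage order."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(f"stage must advance: {self.stage!r} -> {stage!r}")
        return ExpressionMatrix(values=values, stage=stage)


@dataclass
class InteractionMatrix:
    """Binary genes x miRNAs targeting matrix (1 = predicted interaction)."""

    entries: pd.DataFrame  # genes x mirnas, values in {0, 1}

    def __post_init__(self) -> None:
        _check_unique(list(self.entries.index), "gene")
        _check_unique(list(self.entries.columns), "miRNA")
        arr = self.entries.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("interaction entries must be 0 or 1")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.entries.index]

    @property
    def mirnas(self) -> list[str]:
        return [str(m) for m in self.entries.columns]


@dataclass
class MetricScores:
    """Per-gene nonnegative scores for one prioritization metric."""

    metric: str  # "miRNA", "MAD" or "SDE"
    scores: pd.Series  # index = gene ids, values >= 0
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(list(self.scores.index), "gene")
        arr = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{self.metric} metric contains non-finite scores")
        if (arr < 0).any():
            raise ValueError(f"{self.metric} metric contains negative scores")
        if self.normalized:
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"normalized {self.metric} scores must sum to 1, got {arr.sum()}"
                )
            if (arr > 1 + 1e-12).any():
                raise ValueError("normalized scores must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.scores.index]


@dataclass
class PseudotimeOrdering:
    """Per-cell pseudotime in [0, 1], min 0 and max 1 when >= 2 cells."""

    cell_ids: list[str]
    t: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if len(self.cell_ids) != self.t.shape[0]:
            raise ValueError("cell_ids and t must have equal length")
        if self.t.size and ((self.t < -1e-12).any() or (self.t > 1 + 1e-12).any()):
            raise ValueError("pseudotime values must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.t, index=self.cell_ids, name="pseudotime")


@dataclass
class SigmoidFit:
    """Parameters of a sigmoid switch fit: f(t) = 2*mu0 / (1 + exp(-kappa*(t - t0)))."""

    mu0: float
    kappa: float
    t0: float
    sigma: float
    converged: bool
    loglik: float = float("-inf")


@dataclass
class MetricWeights:
    """Convex weights (a1, a2, a3) for the SDE, MAD and miRNA metrics."""

    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        for a in (self.a1, self.a2, self.a3):
            if a < -1e-12:
                raise ValueError("metric weights must be nonnegative")
        if abs(self.a1 + self.a2 + self.a3 - 1.0) > 1e-9:
            raise ValueError("metric weights must sum to 1")

    def astuple(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)


@dataclass
class RankedGeneList:
    """Genes sorted by descending combined score with per-metric provenance.

    `table` columns: combined, sde, mad, mirna; index = gene ids in rank order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.table["combined"].to_numpy()
        if w.size > 1 and (np.diff(w) > 1e-12).any():
            raise ValueError("combined scores must be non-increasing down the list")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.table.index]

    @property
    def combined(self) -> pd.Series:
        return self.table["combined"]


@dataclass
class SurvivalCohort:
    """Right-censored survival cohort with optional expression covariates.

    time[i] is the observed follow-up (min of event and censoring time),
    event[i] is 1 for an observed death and 0 for censoring.
    """

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None  # patients x genes

    def __post_init__(self) -> None:
        _check_unique(self.patient_ids, "patient")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patient_ids)
        if self.time.shape[0] != n or self.event.shape[0] != n:
            raise ValueError("time/event length must match patient_ids")
        if (self.time < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if self.covariates is not None and self.covariates.shape[0] != n:
            raise ValueError("covariate rows must match patients")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalCohort":
        idx = np.asarray(idx)
        return SurvivalCohort(
            patient_ids=[self.patient_ids[i] for i in idx],
            time=self.time[idx],
            event=self.event[idx],
            covariates=None if self.covariates is None else self.covariates.iloc[idx],
        )


@dataclass
class CoxModel:
    """Fitted (possibly L1-penalized) Cox proportional hazards model.

    Coefficients are on the standardized-covariate scale: each gene was
    centered and scaled to unit standard deviation before fitting, so
    exp(beta) is the hazard ratio per standard deviation of expression.
    """

    lam: float
    beta: pd.Series  # index = gene ids
    means: pd.Series
    sds: pd.Series
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = [str(g) for g in self.beta.index]

    @property
    def active_set(self) -> list[str]:
        return [str(g) for g in self.beta.index[self.beta.to_numpy() != 0]]

    def risk_scores(self, covariates: pd.DataFrame) -> np.ndarray:
        """Linear predictor r_i = sum_j beta_j * z_ij on standardized covariates."""
        X = covariates[self.genes].to_numpy(dtype=float)
        Z = (X - self.means.to_numpy()) / self.sds.to_numpy()
        return Z @ self.beta.to_numpy()


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve evaluated at distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if (np.diff(self.times) <= 0).any():
            raise ValueError("event times must be strictly increasing")
        if self.survival.size and (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")
        if self.survival.size and (
            (self.survival < -1e-12).any() or (self.survival > 1 + 1e-12).any()
        ):
            raise ValueError("survival probabilities must lie in [0, 1]")


@dataclass
class LogRankResult:
    """Two-group log-rank comparison: observed/expected event totals and chi2 test."""

    observed: np.ndarray  # per group
    expected: np.ndarray  # per group
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("log-rank statistic must be nonnegative")
        if abs(self.observed.sum() - self.expected.sum()) > 1e-9:
            raise ValueError("total observed and expected events must agree")
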