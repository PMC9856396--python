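"""Synthetic data generators with known ground truth.

Three generators mirror the pipeline's three input kinds: a single-cell
count matrix with planted switch-like genes along a latent pseudotime, a
miRNA-target pair list with planted hub genes, and a right-censored
survival cohort whose hazard is log-linear in chosen signature genes
(exponential event times, so proportional hazards holds exactly).  All
generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ExpressionMatrix, SurvivalCohort
from .metrics import sigmoid


@dataclass
class ScSimSpec:
    """Conditions for the synthetic single-cell matrix.

    A `frac_switch` fraction of genes follows the sigmoid switch model along
    a latent uniform pseudotime with steepness drawn from `kappa_range`
    (random sign) and peak expression from `mu0_range`; the rest are flat.
    One designated marker gene switches with steepness `marker_kappa` so the
    marker-rank pseudotime can recover the latent ordering.  Gaussian noise
    (sd `noise_sd`, truncated at 0) is added before scaling to counts.
    """

    n_genes: int = 100
    n_cells: int = 300
    frac_switch: float = 0.2
    kappa_range: tuple[float, float] = (8.0, 15.0)
    mu0_range: tuple[float, float] = (1.0, 3.0)
    noise_sd: float = 0.1
    marker_kappa: float = 12.0
    marker_gene: str = "VIM"
    count_scale: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_switch <= 1:
            raise ValueError("frac_switch must be in [0, 1]")
        for lo, hi in (self.kappa_range, self.mu0_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (low, high)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_sc_matrix(
    spec: ScSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, np.ndarray]:
    """Generate (raw count matrix, per-gene truth table, latent pseudotime).

    The truth table has one row per gene with columns cls
    ("switch"/"flat"/"marker"), mu0, kappa, t0.
    """
    rng = np.random.default_rng(spec.seed)
    t = rng.uniform(0.0, 1.0, size=spec.n_cells)
    n_switch = int(round(spec.frac_switch * spec.n_genes))
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    # marker replaces the last gene id
    gene_ids[-1] = spec.marker_gene
    switch_idx = set(range(n_switch))
    rows = []
    values = np.zeros((spec.n_genes, spec.n_cells))
    for i, gid in enumerate(gene_ids):
        if gid == spec.marker_gene:
            mu0 = rng.uniform(*spec.mu0_range)
            kappa, t0, cls = spec.marker_kappa, 0.5, "marker"
            mean = sigmoid(t, mu0, kappa, t0)
        elif i in switch_idx:
            mu0 = rng.uniform(*spec.mu0_range)
            kappa = rng.uniform(*spec.kappa_range) * rng.choice([-1.0, 1.0])
            t0 = rng.uniform(0.2, 0.8)
            cls = "switch"
            mean = sigmoid(t, mu0, kappa, t0)
        else:
            mu0 = rng.uniform(*spec.mu0_range)
            kappa, t0, cls = 0.0, 0.5, "flat"
            mean = np.full(spec.n_cells, mu0)
        noisy = np.clip(mean + rng.normal(0.0, spec.noise_sd, spec.n_cells), 0.0, None)
        values[i] = np.round(noisy * spec.count_scale)
        rows.append({"gene": gid, "cls": cls, "mu0": mu0, "kappa": kappa, "t0": t0})
    cell_ids = [f"c{i:04d}" for i in range(spec.n_cells)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=cell_ids), stage="raw"
    )
    truth = pd.DataFrame(rows).set_index("gene")
    return matrix, truth, t


def simulate_interactions(
    n_mirnas: int,
    n_genes: int,
    density: float,
    hub_genes: list[str] | None = None,
    hub_boost: float = 1.0,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Random bipartite miRNA-target pairs with optionally boosted hub genes.

    Each (miRNA, gene) pair is present independently with probability
    `density`, raised to min(1, density * hub_boost) for hub genes, so a
    hub's expected miRNA count is about n_mirnas * density * hub_boost.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    hubs = set(hub_genes or [])
    pairs: list[tuple[str, str]] = []
    for m in range(n_mirnas):
        mid = f"mir{m:03d}"
        for g in gene_ids:
            p = min(1.0, density * hub_boost) if g in hubs else density
            if rng.random() < p:
                pairs.append((mid, g))
    return pairs


@dataclass
class SurvSimSpec:
    """Conditions for the synthetic survival cohort.

    Event times are exponential with patient rate
    baseline_hazard * exp(sum beta_true * x); censoring is an independent
    exponential whose rate is calibrated so the expected censored fraction
    equals `censor_rate`.
    """

    n_patients: int = 200
    signature_betas: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.01
    censor_rate: float = 0.2
    n_noise_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


def _calibrate_censor_rate(rates: np.ndarray, target: float) -> float:
    """Censoring rate c with mean_i c/(rate_i + c) = target (exponential races)."""
    if target == 0:
        return 0.0

    def gap(c: float) -> float:
        return float(np.mean(c / (rates + c)) - target)

    hi = rates.max()
    while gap(hi) < 0:
        hi *= 10
    return brentq(gap, 1e-12, hi)


def simulate_survival_cohort(
    spec: SurvSimSpec, expression_source: ExpressionMatrix | None = None
) -> tuple[SurvivalCohort, pd.Series]:
    """Generate a proportional-hazards cohort; returns (cohort, true betas).

    Covariates are iid standard normal per patient.  The gene universe is
    the signature genes plus `n_noise_genes` null genes, or, when
    `expression_source` is given, that matrix's gene ids (signature betas
    apply to the genes they name; all others are null).
    """
    rng = np.random.default_rng(spec.seed)
    if expression_source is not None:
        genes = expression_source.gene_ids
    else:
        genes = list(spec.signature_betas) + [
            f"noise{i:03d}" for i in range(spec.n_noise_genes)
        ]
    beta_true = pd.Series(0.0, index=genes)
    for g, b in spec.signature_betas.items():
        if g in beta_true.index:
            beta_true[g] = b
    X = rng.standard_normal((spec.n_patients, len(genes)))
    eta = X @ beta_true.to_numpy()
    rates = spec.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / rates)
    if spec.censor_rate > 0:
        c_rate = _calibrate_censor_rate(rates, spec.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=spec.n_patients)
    else:
        censor_time = np.full(spec.n_patients, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    cohort = SurvivalCohort(
        patient_ids=[f"p{i:04d}" for i in range(spec.n_patients)],
        time=time,
        event=event,
        covariates=pd.DataFrame(
            X, index=[f"p{i:04d}" for i in range(spec.n_patients)], columns=genes
        ),
    )
    return cohort, beta_true
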