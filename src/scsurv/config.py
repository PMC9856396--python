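"""Pipeline configuration: one object, one seed, no global state."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    All randomness (CV folds, simulations) flows from `seed` via explicitly
    passed generators.  `grid_step` must divide 1 exactly.
    """

    min_cells_per_gene: int = 10
    denoise_knn: int = 5
    denoise_decay: float = 2.0
    denoise_steps: int = 3
    pca_dims: int = 20
    marker_gene: str = "VIM"
    top_k_targets_per_mirna: int = 50
    n_top_genes: int = 500
    grid_step: float = 0.1
    cv_folds: int = 10
    lambda_strategy: str = "cv_within_train"
    lambda_fixed: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_cells_per_gene", "denoise_knn", "pca_dims",
                     "top_k_targets_per_mirna", "n_top_genes", "cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.denoise_steps < 0:
            raise ValueError("denoise_steps must be >= 0")
        if self.denoise_decay <= 0:
            raise ValueError("denoise_decay must be positive")
        k = 1.0 / self.grid_step
        if abs(k - round(k)) > 1e-9:
            raise ValueError("grid_step must divide 1 exactly")
        if self.lambda_strategy not in ("cv_within_train", "fixed"):
            raise ValueError("lambda_strategy must be 'cv_within_train' or 'fixed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
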