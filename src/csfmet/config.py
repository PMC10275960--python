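"""Pipeline configuration: every threshold and seed used downstream.

A flat key-value document (YAML on disk); CLI flags override file values.
The defaults are the study's analysis settings: blank ratio 10, dilution
p < 0.05, LOESS span 0.2, QC CV < 0.20, ±2.5 ppm / ±5 s matching windows,
age filter p < 0.05, 90% presence, elastic-net mixing 0.5 with balanced
7-fold CV (five patients per phenotype per fold) and the 1-SE lambda rule,
and class-conditional transductive conformal prediction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # preprocessing
    blank_ratio_min: float = 10.0
    dilution_p_max: float = 0.05
    loess_span: float = 0.2
    cv_max: float = 0.20
    tic_mad_factor: float = 3.0
    # harmonization
    ppm_max: float = 2.5
    rt_max_s: float = 5.0
    age_p_max: float = 0.05
    presence_min: float = 0.90
    # signature selection
    alpha_mix: float = 0.5
    k_folds: int = 7
    per_class_fold_size: int = 5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    # conformal prediction
    epsilon_start: float = 0.001
    epsilon_stop: float = 0.50
    epsilon_step: float = 0.001
    smoothing: bool = False
    n_cost: int = 30
    n_gamma: int = 30
    cost_log2_min: float = -5.0
    cost_log2_max: float = 15.0
    gamma_log2_min: float = -15.0
    gamma_log2_max: float = 3.0
    # monitoring
    n_permutations: int = 999
    # randomness
    seed: int = 0

    def validate(self) -> None:
        checks = [
            self.blank_ratio_min > 0,
            0 < self.dilution_p_max < 1,
            0 < self.loess_span <= 1,
            self.cv_max > 0,
            self.ppm_max > 0,
            self.rt_max_s > 0,
            0 < self.age_p_max < 1,
            0 <= self.presence_min <= 1,
            0 <= self.alpha_mix <= 1,
            self.k_folds >= 2,
            self.per_class_fold_size >= 1,
            self.n_lambda >= 2,
            0 < self.lambda_min_ratio < 1,
            0 < self.epsilon_start < self.epsilon_stop < 1,
            self.n_permutations >= 1,
            self.seed is not None,
        ]
        if not all(checks):
            raise ValueError("PipelineConfig has a threshold outside its valid range")

    def epsilon_grid(self):
        import numpy as np

        n = int(round((self.epsilon_stop - self.epsilon_start) / self.epsilon_step)) + 1
        return np.round(self.epsilon_start + self.epsilon_step * np.arange(n), 10)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:10]

    def provenance(self) -> dict:
        return {"config": self.hash(), "seed": self.seed}

    # -- disk ------------------------------------------------------------
    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
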