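"""Run configuration: validated settings for the fitting pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

__all__ = ["RunConfig"]

_SELECTORS = ("map", "average", "aicc", "gcv", "bic", "cv-obs", "cv-well")


@dataclass
class RunConfig:
    """Everything a fit run needs; loadable from a flat YAML mapping."""

    n_basis: tuple[int, int, int] = (14, 8, 5)
    degree: int = 2
    penalty_order: int = 1
    transform_offset: float = 1.0
    prior_a: float = 1e-4
    prior_b: float = 1e-4
    lambda_min: float = 1e-6
    lambda_max: float = 1e8
    lambda_size: int = 81
    selector: str = "map"
    credible_level: float = 0.95
    prediction_shape: tuple[int, int, int] = (50, 50, 20)
    cv_folds: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_basis = tuple(int(v) for v in self.n_basis)
        self.prediction_shape = tuple(int(v) for v in self.prediction_shape)
        problems = []
        if len(self.n_basis) != 3 or any(v < self.degree + 1 for v in self.n_basis):
            problems.append(
                f"n_basis must be 3 counts, each >= degree+1={self.degree + 1}; "
                f"got {self.n_basis}"
            )
        if self.degree < 0:
            problems.append(f"degree must be >= 0, got {self.degree}")
        if self.penalty_order not in (1, 2):
            problems.append(f"penalty_order must be 1 or 2, got {self.penalty_order}")
        if self.transform_offset <= 0:
            problems.append("transform_offset must be > 0")
        if self.prior_a <= 0 or self.prior_b <= 0:
            problems.append("prior_a and prior_b must be > 0")
        if not (0 < self.lambda_min < self.lambda_max):
            problems.append("need 0 < lambda_min < lambda_max")
        if self.lambda_size < 1:
            problems.append("lambda_size must be >= 1")
        if self.selector not in _SELECTORS:
            problems.append(f"selector must be one of {_SELECTORS}, got {self.selector!r}")
        if not 0.0 <= self.credible_level < 1.0:
            problems.append("credible_level must be in [0, 1)")
        if len(self.prediction_shape) != 3 or any(v < 2 for v in self.prediction_shape):
            problems.append("prediction_shape must be 3 counts >= 2")
        if self.cv_folds < 2:
            problems.append("cv_folds must be >= 2")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def lambda_grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.lambda_min), np.log10(self.lambda_max), self.lambda_size
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable short hash of the configuration, for output headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
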