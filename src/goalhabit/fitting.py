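"""Functional fitting interface: thin wrappers over :class:`AdherenceModel`."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .actr import predict_matrix
from .estimator import DEFAULT_INIT_RANGES, AdherenceModel
from .params import DecayConfig, FreeParams, SystemParams
from .sequences import Cohort


@dataclass(frozen=True)
class FitConfig:
    """Multi-start BFGS settings."""

    n_starts: int = 20
    init_ranges: tuple = DEFAULT_INIT_RANGES
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Fitted coefficients plus optimiser metadata."""

    params: FreeParams
    objective_value: float
    converged: bool
    n_starts_used: int
    best_start_index: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "params": {
                "beta0": self.params.beta0,
                "beta": self.params.beta,
                "Tr": self.params.tr,
                "U0": self.params.u0,
                "R0": self.params.r0,
            },
            "objective_value": self.objective_value,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "best_start_index": self.best_start_index,
            "seed": self.seed,
        }

    def save(self, path: str | Path, **extra) -> None:
        payload = self.to_dict()
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "FitResult":
        p = payload["params"]
        return cls(
            params=FreeParams(
                beta0=float(p["beta0"]),
                beta=float(p["beta"]),
                tr=float(p.get("Tr", p.get("tr"))),
                u0=float(p.get("U0", p.get("u0"))),
                r0=float(p.get("R0", p.get("r0"))),
            ),
            objective_value=float(payload["objective_value"]),
            converged=bool(payload["converged"]),
            n_starts_used=int(payload["n_starts_used"]),
            best_start_index=int(payload["best_start_index"]),
            seed=int(payload["seed"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(cohort) -> np.ndarray:
    return cohort.matrix if isinstance(cohort, Cohort) else np.asarray(cohort)


def predicted_group_curve(
    cohort,
    fp: FreeParams,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    B: np.ndarray | None = None,
) -> np.ndarray:
    """Mean predicted success probability per day, conditioning each
    participant on their own observed history."""
    X = _as_matrix(cohort)
    return predict_matrix(X, fp, sys, decay, B=B)["P_SMDB"].mean(axis=0)


def objective(
    fp: FreeParams,
    cohort,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    B: np.ndarray | None = None,
) -> float:
    """Mean squared per-day discrepancy between observed and predicted curves."""
    X = _as_matrix(cohort)
    pred = predicted_group_curve(X, fp, sys, decay, B=B)
    value = float(np.mean((X.mean(axis=0) - pred) ** 2))
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite objective at parameters {fp!r}")
    return value


def fit_group(
    cohort,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one study arm's coefficients with multi-start BFGS."""
    cfg = config or FitConfig()
    model = AdherenceModel(
        system=sys,
        decay=decay,
        n_starts=cfg.n_starts,
        init_ranges=cfg.init_ranges,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    model.fit(_as_matrix(cohort))
    return FitResult(
        params=model.free_params_,
        objective_value=model.objective_value_,
        converged=model.converged_,
        n_starts_used=model.n_starts_used_,
        best_start_index=model.best_start_index_,
        seed=cfg.seed,
    )
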