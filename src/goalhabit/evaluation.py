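"""Fit-quality metrics, bootstrap confidence intervals and residual diagnostics.

The model is evaluated on the group curve: MSE, RMSE and R-squared of
the predicted versus observed daily adherence proportions.  Percentile
bootstrap intervals (default 1000 replicates, 90% coverage) come from
resampling participants with replacement while holding the fitted
coefficients fixed; both curves are recomputed per replicate.  Residual
autocorrelation is checked with the Ljung-Box portmanteau statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .actr import predict_matrix
from .fitting import FitResult, _as_matrix
from .params import DecayConfig, FreeParams, SystemParams


@dataclass(frozen=True)
class FitMetrics:
    mse: float
    rmse: float
    r2: float  # nan flags an undefined R^2 (constant observed series)
    residuals: np.ndarray


def fit_metrics(observed, predicted) -> FitMetrics:
    """MSE, RMSE and R-squared of two equal-length daily-proportion curves.

    R-squared is ``1 - SS_res / SS_tot`` about the observed mean; for a
    constant observed series it is undefined and reported as ``nan``
    (never coerced to 0).  Residuals are observed minus predicted.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1 or observed.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, length >= 2")
    residuals = observed - predicted
    mse = float(np.mean(residuals**2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    constant = bool(np.all(observed == observed[0]))
    r2 = float("nan") if constant or ss_tot == 0 else 1.0 - float(np.sum(residuals**2)) / ss_tot
    return FitMetrics(mse=mse, rmse=float(np.sqrt(mse)), r2=r2, residuals=residuals)


def ljung_box(residuals, lags: int = 20) -> tuple[float, float]:
    """Ljung-Box portmanteau test for residual autocorrelation.

    ``Q = n (n + 2) * sum_{k=1..lags} rho_k^2 / (n - k)`` with the
    p-value from a chi-square with ``lags`` degrees of freedom.  With a
    21-day residual series the default ``lags=20`` is close to the
    series length, which is statistically degenerate but mirrors how
    short adherence series are commonly tested; pass a smaller value
    for a better-behaved test.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if n < lags + 1:
        raise ValueError(f"need at least lags + 1 = {lags + 1} residuals, got {n}")
    xc = x - x.mean()
    denom = float(np.sum(xc**2))
    if denom == 0.0:
        raise ValueError("zero-variance residuals: autocorrelation undefined")
    q = 0.0
    for k in range(1, lags + 1):
        rho_k = float(np.sum(xc[k:] * xc[:-k])) / denom
        q += rho_k**2 / (n - k)
    q *= n * (n + 2.0)
    return q, float(stats.chi2.sf(q, df=lags))


@dataclass(frozen=True)
class BootstrapCI:
    ci_mse: tuple[float, float]
    ci_rmse: tuple[float, float]
    ci_r2: tuple[float, float]
    replicates: pd.DataFrame = field(repr=False)
    n_boot: int
    level: float
    seed: int


def bootstrap_ci(
    cohort,
    fp: FreeParams,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CIs for MSE, RMSE and R-squared.

    Each replicate resamples participants with replacement and
    recomputes both the observed and the predicted group curve under
    the *fixed* fitted coefficients.  Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    X = _as_matrix(cohort)
    n = X.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs at least 2 participants")
    # Per-participant predictions depend only on each participant's own
    # history, so they are computed once and row-resampled afterwards.
    P = predict_matrix(X, fp, sys, decay)["P_SMDB"]
    rng = np.random.default_rng(seed)
    records = []
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = fit_metrics(X[idx].mean(axis=0), P[idx].mean(axis=0))
        records.append({"replicate": b, "mse": m.mse, "rmse": m.rmse, "r2": m.r2})
    reps = pd.DataFrame(records)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 - (1 - level) / 2)

    def ci(col: str) -> tuple[float, float]:
        values = reps[col].to_numpy()
        if np.all(np.isnan(values)):  # e.g. R^2 when every resampled curve is constant
            return float("nan"), float("nan")
        lo, hi = np.nanpercentile(values, [lo_q, hi_q])
        return float(lo), float(hi)

    return BootstrapCI(
        ci_mse=ci("mse"),
        ci_rmse=ci("rmse"),
        ci_r2=ci("r2"),
        replicates=reps,
        n_boot=n_boot,
        level=level,
        seed=seed,
    )


@dataclass(frozen=True)
class EvalReport:
    """Point metrics, bootstrap CIs and residual diagnostics for one arm."""

    mse: float
    rmse: float
    r2: float
    ci_mse: tuple[float, float]
    ci_rmse: tuple[float, float]
    ci_r2: tuple[float, float]
    lb_stat: float
    lb_p: float
    residuals: np.ndarray
    n_boot: int
    level: float
    lags: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": None if np.isnan(self.r2) else self.r2,
            "ci_mse": list(self.ci_mse),
            "ci_rmse": list(self.ci_rmse),
            "ci_r2": list(self.ci_r2),
            "ljung_box": {"stat": self.lb_stat, "p": self.lb_p, "lags": self.lags},
            "residuals": [float(r) for r in self.residuals],
            "bootstrap": {"n_boot": self.n_boot, "level": self.level},
            "seed": self.seed,
        }

    def save(self, path: str | Path, **extra) -> None:
        payload = self.to_dict()
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def evaluation_report(
    cohort,
    fit: FitResult,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    n_boot: int = 1000,
    level: float = 0.90,
    lags: int = 20,
    seed: int = 0,
) -> tuple[EvalReport, pd.DataFrame, pd.DataFrame]:
    """Assemble the full evaluation for a fitted arm.

    Returns the report plus two exportable tables: fitted-versus-actual
    (day, observed, predicted) and residuals (day, residual).
    """
    X = _as_matrix(cohort)
    observed = X.mean(axis=0)
    predicted = predict_matrix(X, fit.params, sys, decay)["P_SMDB"].mean(axis=0)
    metrics = fit_metrics(observed, predicted)
    boot = bootstrap_ci(X, fit.params, sys, decay, n_boot=n_boot, level=level, seed=seed)
    lb_stat, lb_p = ljung_box(metrics.residuals, lags=lags)
    report = EvalReport(
        mse=metrics.mse,
        rmse=metrics.rmse,
        r2=metrics.r2,
        ci_mse=boot.ci_mse,
        ci_rmse=boot.ci_rmse,
        ci_r2=boot.ci_r2,
        lb_stat=lb_stat,
        lb_p=lb_p,
        residuals=metrics.residuals,
        n_boot=n_boot,
        level=level,
        lags=lags,
        seed=seed,
    )
    days = np.arange(1, observed.size + 1)
    fitted_vs_actual = pd.DataFrame({"day": days, "observed": observed, "predicted": predicted})
    residual_table = pd.DataFrame({"day": days, "residual": metrics.residuals})
    return report, fitted_vs_actual, residual_table
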