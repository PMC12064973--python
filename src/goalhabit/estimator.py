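"""Group-level model fitting as a scikit-learn estimator.

:class:`AdherenceModel` estimates the five free coefficients of one
study arm by minimising the mean squared discrepancy between the
observed group adherence curve (daily proportion adherent) and the mean
predicted success probability, where each participant's prediction is
conditioned on their own observed history.  The objective is smooth but
multimodal, so the default strategy is multi-start BFGS with
central-difference gradients; the lowest-objective start wins.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .actr import _validate_binary_matrix, baselevel_matrix, predict_matrix
from .params import DecayConfig, FreeParams, SystemParams

#: Uniform sampling box for the multi-start initialisations, in the
#: order (beta0, beta, tr, u0, r0).
DEFAULT_INIT_RANGES = ((-5.0, 5.0), (-5.0, 5.0), (0.0, 5.0), (-5.0, 5.0), (0.0, 5.0))


class FitConvergenceError(RuntimeError):
    """No optimiser start converged; carries per-start diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        super().__init__(
            "no BFGS start converged; per-start diagnostics: "
            + "; ".join(
                f"start {d['start']}: fun={d['fun']:.6g}, message={d['message']}"
                for d in diagnostics
            )
        )


def _curve_mse(theta, obs_curve, X, B, system):
    fp = FreeParams.from_array(theta)
    parts = predict_matrix(X, fp, system, B=B)
    pred_curve = parts["P_SMDB"].mean(axis=0)
    value = float(np.mean((obs_curve - pred_curve) ** 2))
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite objective at parameters {theta!r}")
    return value


def _central_grad(fun, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2.0 * h)
    return g


class AdherenceModel(BaseEstimator):
    """Two-mechanism adherence model fitted to a group curve.

    Parameters
    ----------
    system : SystemParams, optional
        Fixed architecture constants (defaults are conventional values).
    decay : DecayConfig, optional
        Base-level decay rule (spacing-sensitive by default).
    n_starts : int
        Number of random BFGS initialisations.
    init_ranges : sequence of (lo, hi), optional
        Per-parameter uniform sampling intervals for the starts, in the
        order (beta0, beta, tr, u0, r0).
    tol : float
        Gradient-norm convergence tolerance passed to BFGS.
    max_iter : int
        Iteration cap per start.
    fd_step : float
        Central finite-difference step for the numerical gradient.
    random_state : int
        Seed for the start sampler; fitting is deterministic given the
        data and this seed.

    Attributes
    ----------
    beta0_, beta_, tr_, u0_, r0_ : float
        Fitted coefficients of the best start.
    objective_value_ : float
        Mean squared curve discrepancy at the optimum.
    converged_ : bool
        Whether the winning start reported convergence.
    best_start_index_, n_starts_used_ : int
    start_objectives_ : list of float
        Final objective of every start, in sampling order.
    """

    def __init__(
        self,
        system: SystemParams | None = None,
        decay: DecayConfig | None = None,
        n_starts: int = 20,
        init_ranges=None,
        tol: float = 1e-6,
        max_iter: int = 200,
        fd_step: float = 1e-6,
        random_state: int = 0,
    ):
        self.system = system
        self.decay = decay
        self.n_starts = n_starts
        self.init_ranges = init_ranges
        self.tol = tol
        self.max_iter = max_iter
        self.fd_step = fd_step
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the five coefficients to the binary cohort matrix ``X``.

        ``X`` has one row per participant and one 0/1 column per day;
        at least two participants are required.  ``y`` is ignored (the
        target is the column mean of ``X`` itself).
        """
        X = _validate_binary_matrix(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 participants to fit a group curve")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        system = self.system if self.system is not None else SystemParams()
        decay = self.decay if self.decay is not None else DecayConfig()
        ranges = self.init_ranges if self.init_ranges is not None else DEFAULT_INIT_RANGES

        # Base-level activation depends only on histories and the decay
        # rule, so it is precomputed once and shared by every start.
        B = baselevel_matrix(X, decay, system)
        obs_curve = X.mean(axis=0)
        fun = lambda theta: _curve_mse(theta, obs_curve, X, B, system)
        jac = lambda theta: _central_grad(fun, theta, self.fd_step)

        rng = np.random.default_rng(self.random_state)
        diagnostics = []
        best = None
        for i in range(self.n_starts):
            # One draw per start, sequentially, so a longer run extends a
            # shorter run with the same seed instead of reshuffling it.
            x0 = np.array([rng.uniform(lo, hi) for lo, hi in ranges])
            res = minimize(
                fun,
                x0,
                jac=jac,
                method="BFGS",
                options={"gtol": self.tol, "maxiter": self.max_iter},
            )
            diagnostics.append(
                {
                    "start": i,
                    "x0": x0,
                    "fun": float(res.fun),
                    "success": bool(res.success),
                    "message": res.message,
                    "nit": int(res.nit),
                }
            )
            if best is None or res.fun < best[1].fun:
                best = (i, res)
        if not any(d["success"] for d in diagnostics):
            raise FitConvergenceError(diagnostics)

        best_index, best_res = best
        self.beta0_, self.beta_, self.tr_, self.u0_, self.r0_ = (
            float(v) for v in best_res.x
        )
        self.objective_value_ = float(best_res.fun)
        self.converged_ = bool(best_res.success)
        self.best_start_index_ = best_index
        self.n_starts_used_ = self.n_starts
        self.start_objectives_ = [d["fun"] for d in diagnostics]
        self.start_diagnostics_ = diagnostics
        self.system_ = system
        self.decay_ = decay
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def free_params_(self) -> FreeParams:
        self._check_fitted()
        return FreeParams(
            beta0=self.beta0_, beta=self.beta_, tr=self.tr_, u0=self.u0_, r0=self.r0_
        )

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Per-participant day-ahead success probabilities (rows align with ``X``)."""
        self._check_fitted()
        X = _validate_binary_matrix(X)
        return predict_matrix(X, self.free_params_, self.system_, self.decay_)["P_SMDB"]

    def predict_curve(self, X) -> np.ndarray:
        """Mean predicted success probability per day (the fitted group curve)."""
        return self.predict(X).mean(axis=0)

    def decompose(self, X):
        """Mean mechanism-contribution curves: goal, habit, and their sum."""
        import pandas as pd

        self._check_fitted()
        X = _validate_binary_matrix(X)
        parts = predict_matrix(X, self.free_params_, self.system_, self.decay_)
        return pd.DataFrame(
            {
                "day": np.arange(1, X.shape[1] + 1),
                "goal_contrib": parts["goal_contrib"].mean(axis=0),
                "habit_contrib": parts["habit_contrib"].mean(axis=0),
                "p_smdb": parts["P_SMDB"].mean(axis=0),
            }
        )

    def trace(self, X, ids=None):
        """Tidy per-participant-per-day trace table of all model internals."""
        import pandas as pd

        self._check_fitted()
        X = _validate_binary_matrix(X)
        parts = predict_matrix(X, self.free_params_, self.system_, self.decay_)
        n, T = X.shape
        if ids is None:
            ids = [f"p{i:04d}" for i in range(n)]
        frames = []
        for i in range(n):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": ids[i],
                        "day": np.arange(1, T + 1),
                        **{k: parts[k][i] for k in
                           ("B", "A", "P_G", "P_S", "U", "P_H", "P_SMDB",
                            "goal_contrib", "habit_contrib")},
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def score(self, X, y=None) -> float:
        """R-squared of the predicted group curve against the observed one."""
        from .evaluation import fit_metrics

        X = _validate_binary_matrix(X)
        return fit_metrics(X.mean(axis=0), self.predict_curve(X)).r2

    def _check_fitted(self) -> None:
        if not hasattr(self, "beta0_"):
            raise NotFittedError("this AdherenceModel instance is not fitted yet")
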