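"""Subsymbolic ACT-R computations for day-ahead adherence prediction.

Daily execution of dietary self-monitoring is modelled as the outcome of
two competing routes:

* **Goal pursuit** — the monitoring goal is retrieved from declarative
  memory with probability ``P_G`` (a logistic in the chunk's total
  activation ``A``) and, once retrieved, translated into action with
  probability ``P_S`` (the same logistic applied to the activation after
  intention-action translation).
* **Habit formation** — when the goal is not retrieved, the practiced
  "record diet" production rule may still fire automatically with
  probability ``P_H``, a Boltzmann choice against a do-nothing rule
  driven by the rule's learned utility ``U``.

The composite day-ahead success probability is the convex combination

    ``P_SMDB = P_G * P_S + (1 - P_G) * P_H``.

Both routes are driven by a single state variable: the participant's
practice history (which days the behaviour was actually executed).
Prediction is autoregressive — day ``n`` is always conditioned on the
*observed* history of days ``1 .. n-1``, never on the model's own
predictions.

Base-level activation follows the log power-law of practice,
``B = ln(sum_i t_i^(-d_i))`` with ``t_i`` the age of the *i*-th practice
at prediction time.  By default the per-practice decay is the
spacing-sensitive rule ``d_1 = a``, ``d_i = c * exp(m_{i-1}) + a`` where
``m_{i-1}`` is the activation of the earlier practices evaluated at the
moment practice *i* was encoded; a constant-decay variant is available
for reference computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .params import DecayConfig, FreeParams, SystemParams

__all__ = [
    "DayTrace",
    "practice_ages",
    "base_level_activation",
    "history_decays",
    "baselevel_series",
    "baselevel_matrix",
    "total_activation",
    "retrieval_probability",
    "goal_success_probability",
    "utility_trajectory",
    "habit_probability",
    "predict_sequence",
    "predict_matrix",
    "mechanism_contributions",
    "traces_to_frame",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class DayTrace:
    """Per-day model internals for one participant.

    ``B`` is ``nan`` on days with an empty practice history, where the
    activation falls back to the intercept (``A = beta0``).
    """

    day: int
    B: float
    A: float
    P_G: float
    P_S: float
    U: float
    P_H: float
    P_SMDB: float
    goal_contrib: float
    habit_contrib: float


def _validate_history(executed_days: Sequence[int]) -> list[int]:
    days = [int(d) for d in executed_days]
    prev = 0
    for d in days:
        if d < 1:
            raise ValueError(f"executed day indices must be >= 1, got {d}")
        if d <= prev:
            raise ValueError("executed days must be strictly increasing")
        prev = d
    return days


def practice_ages(executed_days: Sequence[int], day: int) -> list[int]:
    """Ages (in days) of all practices that precede ``day``, in execution order.

    The first practice is the oldest, so the returned list is strictly
    decreasing; it is empty when nothing was executed before ``day``.
    """
    if day < 1:
        raise ValueError(f"day index must be >= 1, got {day}")
    days = _validate_history(executed_days)
    return [day - k for k in days if k < day]


def history_decays(
    executed_days: Sequence[int],
    decay: DecayConfig | None = None,
    sys: SystemParams | None = None,
) -> list[float]:
    """Per-practice decay exponents for a full practice history.

    Each practice keeps the decay assigned at its encoding time, which
    under the spacing-sensitive rule depends only on *earlier*
    practices; the list is therefore a stable prefix as history grows.
    """
    decay = decay or DecayConfig()
    sys = sys or SystemParams()
    days = _validate_history(executed_days)
    if decay.mode == "constant":
        return [decay.d_const] * len(days)
    out: list[float] = []
    for i, day_i in enumerate(days):
        if i == 0:
            out.append(sys.a)
            continue
        # m_{i-1} = ln(S) evaluated at practice i's encoding time, so
        # exp(m_{i-1}) is just the power-law sum S itself.
        s_sum = 0.0
        for j in range(i):
            s_sum += float(day_i - days[j]) ** (-out[j])
        out.append(sys.c * s_sum + sys.a)
    return out


def base_level_activation(
    ages: Sequence[float],
    decay: DecayConfig | None = None,
    sys: SystemParams | None = None,
) -> float:
    """Base-level activation ``B = ln(sum_i ages_i^(-d_i))``.

    ``ages`` are the ages of past practices at prediction time, given in
    execution order (first practice first, hence largest age first).
    The empty-history case is a caller-side convention (the ``beta * B``
    term is dropped and ``A = beta0``), so an empty list is an error
    here.
    """
    decay = decay or DecayConfig()
    sys = sys or SystemParams()
    ages = [float(t) for t in ages]
    if not ages:
        raise ValueError("empty practice history: apply the empty-history convention upstream")
    if any(t < 1 for t in ages):
        raise ValueError("practice ages must be >= 1 day")
    if decay.mode == "constant":
        return math.log(sum(t ** (-decay.d_const) for t in ages))
    if any(ages[i] <= ages[i + 1] for i in range(len(ages) - 1)):
        raise ValueError(
            "spacing-sensitive decay requires strictly decreasing ages "
            "(one practice per day, execution order)"
        )
    decays: list[float] = []
    for i in range(len(ages)):
        if i == 0:
            decays.append(sys.a)
            continue
        # Age of practice j at the moment practice i was encoded is the
        # difference of their ages at prediction time; exp of the
        # log-sum activation is the power-law sum itself.
        s_sum = sum((ages[j] - ages[i]) ** (-decays[j]) for j in range(i))
        decays.append(sys.c * s_sum + sys.a)
    return math.log(sum(t ** (-d) for t, d in zip(ages, decays)))


def baselevel_series(
    executed_days: Sequence[int],
    horizon: int,
    decay: DecayConfig | None = None,
    sys: SystemParams | None = None,
) -> np.ndarray:
    """Base-level activation entering each day ``1 .. horizon`` (``nan`` while empty)."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    days = _validate_history(executed_days)
    decays = history_decays(days, decay, sys)
    out = np.full(horizon, np.nan)
    for n in range(1, horizon + 1):
        s_sum = 0.0
        seen = False
        for day_j, d_j in zip(days, decays):
            if day_j >= n:
                break
            seen = True
            s_sum += float(n - day_j) ** (-d_j)
        if seen:
            out[n - 1] = math.log(s_sum)
    return out


def baselevel_matrix(
    X: np.ndarray,
    decay: DecayConfig | None = None,
    sys: SystemParams | None = None,
) -> np.ndarray:
    """Per-participant, per-day base-level activation for a binary matrix.

    ``X`` has one row per participant and one 0/1 column per day.  The
    result depends only on the observed histories and the decay
    parameters, never on the free coefficients, so it can be computed
    once per cohort and reused across objective evaluations.
    """
    X = np.asarray(X)
    out = np.full(X.shape, np.nan)
    for i in range(X.shape[0]):
        executed = [n + 1 for n in np.flatnonzero(X[i])]
        out[i] = baselevel_series(executed, X.shape[1], decay, sys)
    return out


def total_activation(B: float, fp: FreeParams) -> float:
    """Total activation ``A = beta0 + beta * B``."""
    return fp.beta0 + fp.beta * B


def retrieval_probability(A, sys: SystemParams | None = None):
    """Probability of retrieving the monitoring goal: logistic in ``A``."""
    sys = sys or SystemParams()
    return expit((np.asarray(A, dtype=float) - sys.tau) / sys.s)


def goal_success_probability(A, fp: FreeParams, sys: SystemParams | None = None):
    """Probability of successful intention-action translation.

    The activation is transformed by the coefficient ``Tr``
    (multiplicatively by default, additively if configured) and passed
    through the same retrieval logistic.
    """
    sys = sys or SystemParams()
    A = np.asarray(A, dtype=float)
    A_prime = fp.tr * A if sys.translation == "multiplicative" else A + fp.tr
    return expit((A_prime - sys.tau) / sys.s)


def utility_trajectory(
    executed_days: Sequence[int],
    horizon: int,
    fp: FreeParams,
    sys: SystemParams | None = None,
) -> np.ndarray:
    """Utility of the habitual rule entering each day ``1 .. horizon``.

    The utility starts at ``u0`` and, after every executed day, moves a
    fraction ``alpha`` of the way towards the constant per-execution
    reward ``r0`` (delta rule); non-executed days leave it unchanged.
    """
    sys = sys or SystemParams()
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    executed = set(_validate_history(executed_days))
    out = np.empty(horizon)
    u = float(fp.u0)
    for n in range(1, horizon + 1):
        out[n - 1] = u
        if n in executed:
            u += sys.alpha * (fp.r0 - u)
    return out


def habit_probability(U, sys: SystemParams | None = None):
    """Probability the habitual rule wins a Boltzmann choice against doing nothing."""
    sys = sys or SystemParams()
    return expit(np.asarray(U, dtype=float) / (_SQRT2 * sys.s_u))


def predict_matrix(
    X: np.ndarray,
    fp: FreeParams,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    B: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised day-ahead prediction for a cohort matrix.

    Returns a dict of (n_participants, T) arrays: ``B``, ``A``, ``P_G``,
    ``P_S``, ``U``, ``P_H``, ``P_SMDB``, ``goal_contrib``,
    ``habit_contrib``.  Pass a precomputed ``B`` (from
    :func:`baselevel_matrix`) to skip the history-dependent part, which
    is invariant under changes of the free coefficients.
    """
    sys = sys or SystemParams()
    X = _validate_binary_matrix(X)
    if B is None:
        B = baselevel_matrix(X, decay, sys)
    n, T = X.shape
    with np.errstate(invalid="ignore"):
        A = np.where(np.isnan(B), fp.beta0, fp.beta0 + fp.beta * B)
    U = np.empty((n, T))
    U[:, 0] = fp.u0
    for t in range(1, T):
        U[:, t] = U[:, t - 1] + sys.alpha * (fp.r0 - U[:, t - 1]) * X[:, t - 1]
    P_G = retrieval_probability(A, sys)
    P_S = goal_success_probability(A, fp, sys)
    P_H = habit_probability(U, sys)
    goal = P_G * P_S
    habit = (1.0 - P_G) * P_H
    return {
        "B": B,
        "A": A,
        "P_G": P_G,
        "P_S": P_S,
        "U": U,
        "P_H": P_H,
        "P_SMDB": goal + habit,
        "goal_contrib": goal,
        "habit_contrib": habit,
    }


def predict_sequence(
    seq: Sequence[int],
    fp: FreeParams,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
) -> list[DayTrace]:
    """Day-by-day traces for a single observed binary adherence sequence."""
    seq = np.asarray(seq)
    if seq.ndim != 1 or seq.size < 1:
        raise ValueError("adherence sequence must be a non-empty 1-D vector")
    parts = predict_matrix(seq[np.newaxis, :], fp, sys, decay)
    traces = []
    for n in range(seq.size):
        traces.append(
            DayTrace(
                day=n + 1,
                B=float(parts["B"][0, n]),
                A=float(parts["A"][0, n]),
                P_G=float(parts["P_G"][0, n]),
                P_S=float(parts["P_S"][0, n]),
                U=float(parts["U"][0, n]),
                P_H=float(parts["P_H"][0, n]),
                P_SMDB=float(parts["P_SMDB"][0, n]),
                goal_contrib=float(parts["goal_contrib"][0, n]),
                habit_contrib=float(parts["habit_contrib"][0, n]),
            )
        )
    return traces


def mechanism_contributions(traces: Sequence[DayTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Goal-pursuit and habit-formation contribution curves; they sum to ``P_SMDB``."""
    if not traces:
        raise ValueError("traces must be non-empty")
    goal = np.array([t.goal_contrib for t in traces])
    habit = np.array([t.habit_contrib for t in traces])
    return goal, habit


def traces_to_frame(traces: Sequence[DayTrace], participant_id: str):
    """Tidy one-row-per-day export of a participant's traces."""
    import pandas as pd

    rows = [
        {
            "participant_id": participant_id,
            "day": t.day,
            "B": t.B,
            "A": t.A,
            "P_G": t.P_G,
            "P_S": t.P_S,
            "U": t.U,
            "P_H": t.P_H,
            "P_SMDB": t.P_SMDB,
            "goal_contrib": t.goal_contrib,
            "habit_contrib": t.habit_contrib,
        }
        for t in traces
    ]
    return pd.DataFrame(rows)


def _validate_binary_matrix(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (participants x days) matrix")
    if X.shape[1] < 1:
        raise ValueError("need at least one day")
    vals = np.unique(X)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("adherence values must be binary 0/1")
    return X.astype(float)
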