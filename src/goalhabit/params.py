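"""Parameter containers and JSON (de)serialisation.

Two kinds of parameters enter the model:

* :class:`SystemParams` — fixed constants of the cognitive architecture
  (decay control, noise scales, learning rate, retrieval threshold).
  These are held fixed during fitting.
* :class:`FreeParams` — the five coefficients estimated per study arm:
  the activation intercept and slope, the intention-action
  transformation coefficient, and the initial utility and reward of the
  habitual production rule.

:class:`DecayConfig` selects the base-level decay rule: the
spacing-sensitive two-parameter rule (per-practice decay
``d_i = c * exp(m_{i-1}) + a``) or a constant decay exponent, which is
mostly useful for testing against direct-summation references.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

DECAY_MODES = ("pavlik_anderson", "constant")
TRANSLATION_MODES = ("multiplicative", "additive")


@dataclass(frozen=True)
class SystemParams:
    """Fixed architecture constants.

    Parameters
    ----------
    c, a : float
        Control parameters of the activation decay coefficient.  ``a`` is
        the decay of the first practice; later practices decay faster the
        higher the chunk's activation was when they were encoded.
    s : float
        Activation noise scale of the retrieval logistic.
    s_u : float
        Utility noise scale of production-rule selection.
    alpha : float
        Delta-rule learning rate of the habitual rule's utility.
    tau : float
        Retrieval threshold (logistic midpoint on the activation scale).
    translation : str
        How the intention-action coefficient ``Tr`` enters the
        goal-success logistic: ``"multiplicative"`` (``A' = Tr * A``,
        default) or ``"additive"`` (``A' = A + Tr``).
    """

    c: float = 0.217
    a: float = 0.177
    s: float = 0.25
    s_u: float = 0.25
    alpha: float = 0.2
    tau: float = 0.0
    translation: str = "multiplicative"

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("activation noise s must be > 0")
        if not self.s_u > 0:
            raise ValueError("utility noise s_u must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("learning rate alpha must be in (0, 1]")
        if self.c < 0 or self.a < 0:
            raise ValueError("decay controls c and a must be >= 0")
        if self.translation not in TRANSLATION_MODES:
            raise ValueError(
                f"translation must be one of {TRANSLATION_MODES}, got {self.translation!r}"
            )


@dataclass(frozen=True)
class DecayConfig:
    """Base-level decay rule: spacing-sensitive (default) or constant."""

    mode: str = "pavlik_anderson"
    d_const: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in DECAY_MODES:
            raise ValueError(f"decay mode must be one of {DECAY_MODES}, got {self.mode!r}")
        if not self.d_const > 0:
            raise ValueError("d_const must be > 0")


@dataclass(frozen=True)
class FreeParams:
    """The five fitted coefficients of a study arm.

    ``beta0``/``beta`` are the intercept and slope mapping base-level
    activation to total activation; ``tr`` is the intention-action
    transformation coefficient; ``u0`` and ``r0`` are the initial
    utility and the per-execution reward of the habitual rule.  None of
    them is sign-constrained: fitted slopes are typically negative.
    """

    beta0: float
    beta: float
    tr: float
    u0: float
    r0: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise ValueError(f"free parameter {name} must be finite, got {value!r}")

    def as_array(self):
        import numpy as np

        return np.array([self.beta0, self.beta, self.tr, self.u0, self.r0], dtype=float)

    @classmethod
    def from_array(cls, values) -> "FreeParams":
        beta0, beta, tr, u0, r0 = (float(v) for v in values)
        return cls(beta0=beta0, beta=beta, tr=tr, u0=u0, r0=r0)


def save_params(
    path: str | Path,
    system: SystemParams,
    decay: DecayConfig,
    free: FreeParams | None = None,
) -> None:
    """Write a parameter file with a ``system`` block and optional ``free`` block."""
    payload: dict = {
        "system": {
            "c": system.c,
            "a": system.a,
            "s": system.s,
            "s_u": system.s_u,
            "alpha": system.alpha,
            "tau": system.tau,
            "translation": system.translation,
            "decay_mode": decay.mode,
            "d_const": decay.d_const,
        }
    }
    if free is not None:
        payload["free"] = {
            "beta0": free.beta0,
            "beta": free.beta,
            "Tr": free.tr,
            "U0": free.u0,
            "R0": free.r0,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_params(path: str | Path) -> tuple[SystemParams, DecayConfig, FreeParams | None]:
    """Read a parameter file written by :func:`save_params`."""
    payload = json.loads(Path(path).read_text())
    sysd = dict(payload.get("system", {}))
    decay = DecayConfig(
        mode=sysd.pop("decay_mode", "pavlik_anderson"),
        d_const=float(sysd.pop("d_const", 0.5)),
    )
    system = SystemParams(**{k: (v if k == "translation" else float(v)) for k, v in sysd.items()})
    free = None
    if "free" in payload:
        f = payload["free"]
        free = FreeParams(
            beta0=float(f["beta0"]),
            beta=float(f["beta"]),
            tr=float(f.get("Tr", f.get("tr"))),
            u0=float(f.get("U0", f.get("u0"))),
            r0=float(f.get("R0", f.get("r0"))),
        )
    return system, decay, free
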