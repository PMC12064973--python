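"""Self-consistent synthetic cohorts.

The generator runs the adherence model *generatively*: each day the
composite success probability is computed from the participant's
simulated history so far, a Bernoulli outcome is drawn, and the history
grows accordingly.  The generative model therefore equals the
inferential model, which makes parameter-recovery experiments
meaningful.  On adherent days the participant uploads 2-4 entries at
random times of day; non-adherent days still carry a single entry with
probability ``p_single_entry``, exercising the at-least-two-entries
binarisation rule downstream.

Three built-in presets carry the coefficient sets estimated for the
three arms of a 21-day digital weight-loss intervention
(self-management, tailored feedback, intensive support) together with
the arms' modelled sample sizes, so every downstream stage can be run
without access to the original system logs.  An optional
misspecification hook mixes in outcome noise (with probability
``noise_eps`` the day's outcome is drawn from a fixed Bernoulli rate
``noise_p`` instead of the model), for robustness experiments with
lower, externally forced adherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import DecayConfig, FreeParams, SystemParams
from .sequences import AdherenceSequence, Cohort, EventLog, build_sequence

_SQRT2 = float(np.sqrt(2.0))
_DEFAULT_START = pd.Timestamp("2022-01-01")


@dataclass(frozen=True)
class GroupPreset:
    """Everything needed to simulate one study arm."""

    label: str
    n_participants: int
    free_params: FreeParams
    p_all_zero: float = 0.0
    p_single_entry: float = 0.2
    T: int = 21
    noise_eps: float = 0.0
    noise_p: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0 <= self.p_all_zero < 1:
            raise ValueError("p_all_zero must lie in [0, 1)")
        if not 0 <= self.p_single_entry <= 1:
            raise ValueError("p_single_entry must lie in [0, 1]")
        if not 0 <= self.noise_eps <= 1 or not 0 <= self.noise_p <= 1:
            raise ValueError("noise_eps and noise_p must lie in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def group_presets() -> dict[str, GroupPreset]:
    """Built-in presets for the three intervention arms (keys sm/tf/is)."""
    return {
        "sm": GroupPreset(
            label="self_management",
            n_participants=49,
            free_params=FreeParams(beta0=1.3245, beta=-0.6909, tr=1.8575, u0=0.1959, r0=0.7983),
        ),
        "tf": GroupPreset(
            label="tailored_feedback",
            n_participants=23,
            free_params=FreeParams(beta0=3.2422, beta=-1.6991, tr=3.6615, u0=1.9833, r0=1.9909),
        ),
        "is": GroupPreset(
            label="intensive_support",
            n_participants=25,
            free_params=FreeParams(beta0=3.6510, beta=-2.2174, tr=3.1929, u0=-0.3126, r0=4.7796),
        ),
    }


def participant_rng(seed: int, index: int) -> np.random.Generator:
    """Per-participant stream derived from the master seed by participant index.

    Streams are keyed by index, so adding participants to a cohort never
    changes the draws of existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_participant(
    fp: FreeParams,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    T: int = 21,
    seed: int = 0,
    index: int = 0,
    participant_id: str | None = None,
    p_single_entry: float = 0.2,
    start_date=_DEFAULT_START,
    force_zero: bool = False,
    noise_eps: float = 0.0,
    noise_p: float = 0.0,
) -> tuple[AdherenceSequence, EventLog]:
    """Forward-simulate one participant; the log re-binarises to the sequence.

    The per-day success probability is computed from the *simulated*
    history accumulated so far, exactly as the autoregressive predictor
    would condition on an observed history.
    """
    sys = sys or SystemParams()
    decay = decay or DecayConfig()
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = participant_rng(seed, index)
    pid = participant_id if participant_id is not None else f"p{index:04d}"
    start = pd.Timestamp(start_date).normalize()

    executed: list[int] = []
    decays: list[float] = []
    x = np.zeros(T, dtype=np.int8)
    entries: list[pd.Timestamp] = []
    u = float(fp.u0)
    for n in range(1, T + 1):
        if executed:
            s_sum = sum(float(n - e) ** (-d) for e, d in zip(executed, decays))
            A = fp.beta0 + fp.beta * np.log(s_sum)
        else:
            s_sum = 0.0
            A = fp.beta0
        p_g = float(expit((A - sys.tau) / sys.s))
        A_prime = fp.tr * A if sys.translation == "multiplicative" else A + fp.tr
        p_s = float(expit((A_prime - sys.tau) / sys.s))
        p_h = float(expit(u / (_SQRT2 * sys.s_u)))
        p = p_g * p_s + (1.0 - p_g) * p_h

        if noise_eps > 0 and rng.random() < noise_eps:
            adherent = rng.random() < noise_p
        else:
            adherent = rng.random() < p
        if force_zero:
            adherent = False

        day_start = start + pd.Timedelta(days=n - 1)
        if adherent:
            x[n - 1] = 1
            if decay.mode == "constant":
                d_new = decay.d_const
            else:
                # s_sum is the chunk's power-law trace at encoding time.
                d_new = sys.a if not executed else sys.c * s_sum + sys.a
            executed.append(n)
            decays.append(d_new)
            u += sys.alpha * (fp.r0 - u)
            n_entries = int(rng.integers(2, 5))
        else:
            n_entries = 1 if rng.random() < p_single_entry else 0
        for sec in sorted(rng.integers(0, 86400, size=n_entries).tolist()):
            entries.append(day_start + pd.Timedelta(seconds=int(sec)))

    log = EventLog(participant_id=pid, entries=entries)
    seq = build_sequence(log, start, T=T, min_entries=2)
    assert np.array_equal(seq.days, x), "simulated sequence must round-trip its log"
    return seq, log


def simulate_group(
    preset: GroupPreset,
    sys: SystemParams | None = None,
    decay: DecayConfig | None = None,
    seed: int = 0,
    start_date=_DEFAULT_START,
) -> tuple[Cohort, list[EventLog]]:
    """Simulate a whole arm; the trailing ``p_all_zero`` share is forced all-zero."""
    n = preset.n_participants
    n_zero = int(round(preset.p_all_zero * n))
    sequences, logs = [], []
    for i in range(n):
        seq, log = simulate_participant(
            preset.free_params,
            sys,
            decay,
            T=preset.T,
            seed=seed,
            index=i,
            participant_id=f"{preset.label}_{i:04d}",
            p_single_entry=preset.p_single_entry,
            start_date=start_date,
            force_zero=i >= n - n_zero,
            noise_eps=preset.noise_eps,
            noise_p=preset.noise_p,
        )
        sequences.append(seq)
        logs.append(log)
    return Cohort(group_label=preset.label, sequences=sequences), logs
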