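import numpy as np
import pytest

from goalhabit import Cohort, AdherenceSequence, DecayConfig, FreeParams, SystemParams
from goalhabit.simulate import group_presets


@pytest.fixture(scope="session")
def system():
    return SystemParams()


@pytest.fixture(scope="session")
def pavlik():
    return DecayConfig(mode="pavlik_anderson")


@pytest.fixture(scope="session")
def const_decay():
    return DecayConfig(mode="constant", d_const=0.5)


@pytest.fixture(scope="session")
def presets():
    return group_presets()


@pytest.fixture(scope="session")
def sm_params(presets):
    return presets["sm"].free_params


def make_cohort(X, label="self_management", prefix="p"):
    X = np.asarray(X)
    return Cohort(
        group_label=label,
        sequences=[
            AdherenceSequence(participant_id=f"{prefix}{i:03d}", days=row)
            for i, row in enumerate(X)
        ],
    )


@pytest.fixture()
def random_binary_cohort():
    rng = np.random.default_rng(42)
    return make_cohort((rng.random((12, 21)) < 0.6).astype(int))


def random_history(rng, horizon=21, max_len=10):
    """Random strictly-increasing practice history within a horizon."""
    k = int(rng.integers(1, max_len + 1))
    days = rng.choice(np.arange(1, horizon + 1), size=min(k, horizon), replace=False)
    return sorted(int(d) for d in days)
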