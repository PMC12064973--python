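"""Unit and property tests for the subsymbolic model computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from goalhabit import (
    DecayConfig,
    FreeParams,
    SystemParams,
    base_level_activation,
    baselevel_matrix,
    baselevel_series,
    goal_success_probability,
    habit_probability,
    mechanism_contributions,
    practice_ages,
    predict_matrix,
    predict_sequence,
    retrieval_probability,
    total_activation,
    utility_trajectory,
)
from conftest import random_history


@pytest.mark.parametrize(
    "history, day, expected",
    [
        ([1, 3], 4, [3, 1]),
        ([], 1, []),
        ([1, 2, 5], 6, [5, 4, 1]),
        ([3], 2, []),  # future practices are invisible
    ],
)
def test_practice_ages(history, day, expected):
    assert practice_ages(history, day) == expected


def test_practice_ages_rejects_nonpositive_day():
    with pytest.raises(ValueError):
        practice_ages([1], 0)


class TestBaseLevelActivation:
    def test_single_fresh_practice_is_zero(self, const_decay):
        assert base_level_activation([1], const_decay) == pytest.approx(0.0, abs=1e-15)

    def test_two_practices_direct_sum(self, const_decay):
        expected = math.log(1.0 + 2.0 ** -0.5)
        assert base_level_activation([2, 1], const_decay) == pytest.approx(expected, rel=1e-15)

    def test_constant_mode_matches_bruteforce(self, const_decay):
        rng = np.random.default_rng(7)
        for _ in range(150):
            history = random_history(rng)
            day = int(rng.integers(max(history) + 1, 23))
            ages = practice_ages(history, day)
            got = base_level_activation(ages, const_decay)
            want = math.log(sum(t ** -const_decay.d_const for t in ages))
            assert got == pytest.approx(want, abs=1e-12)

    def test_spacing_mode_with_c0_degenerates_to_constant(self, system):
        rng = np.random.default_rng(8)
        sys0 = SystemParams(c=0.0, a=system.a)
        const = DecayConfig(mode="constant", d_const=system.a)
        pav = DecayConfig(mode="pavlik_anderson")
        for _ in range(50):
            history = random_history(rng)
            ages = practice_ages(history, 22)
            assert base_level_activation(ages, pav, sys0) == base_level_activation(ages, const)

    def test_empty_and_invalid_ages_rejected(self, const_decay):
        with pytest.raises(ValueError):
            base_level_activation([], const_decay)
        with pytest.raises(ValueError):
            base_level_activation([2, 0.5], const_decay)

    def test_more_practices_never_decrease_activation(self, const_decay):
        # adding a practice adds a positive power-law term
        rng = np.random.default_rng(9)
        for _ in range(50):
            history = random_history(rng, horizon=15, max_len=8)
            extra = next(d for d in range(16, 21))
            ages = practice_ages(history + [extra], 22)
            sub = practice_ages(history, 22)
            assert base_level_activation(ages, const_decay) >= base_level_activation(
                sub, const_decay
            )

    def test_spacing_decays_start_at_a_and_grow_with_activation(self, system, pavlik):
        # massed daily practice drives activation up, hence decay above a
        dense = practice_ages(list(range(1, 11)), 11)
        sparse = practice_ages([1, 10], 11)
        b_dense = base_level_activation(dense, pavlik, system)
        b_sparse = base_level_activation(sparse, pavlik, system)
        assert b_dense > b_sparse

    def test_series_agrees_with_per_day_calls(self, system, pavlik, const_decay):
        rng = np.random.default_rng(10)
        for decay in (pavlik, const_decay):
            for _ in range(20):
                history = random_history(rng)
                series = baselevel_series(history, 21, decay, system)
                for day in range(1, 22):
                    ages = practice_ages(history, day)
                    if not ages:
                        assert np.isnan(series[day - 1])
                    else:
                        assert series[day - 1] == pytest.approx(
                            base_level_activation(ages, decay, system), abs=1e-12
                        )


class TestPointwiseMaps:
    def test_total_activation_intercept_only(self):
        fp = FreeParams(beta0=1.3245, beta=-0.6909, tr=1.0, u0=0.0, r0=0.0)
        assert total_activation(0.0, fp) == pytest.approx(1.3245)
        fp0 = FreeParams(beta0=2.5, beta=0.0, tr=1.0, u0=0.0, r0=0.0)
        assert total_activation(123.0, fp0) == pytest.approx(2.5)
        fp1 = FreeParams(beta0=0.0, beta=2.0, tr=1.0, u0=0.0, r0=0.0)
        assert total_activation(1.0, fp1) == pytest.approx(2.0)

    def test_retrieval_logistic_midpoint_and_closed_form(self, system):
        assert retrieval_probability(system.tau, system) == pytest.approx(0.5)
        assert retrieval_probability(system.tau + system.s * math.log(9), system) == pytest.approx(
            0.9
        )
        assert retrieval_probability(1e6, system) == pytest.approx(1.0)

    def test_retrieval_strictly_increasing(self, system):
        grid = np.linspace(-5, 5, 201)
        p = retrieval_probability(grid, system)
        assert np.all(np.diff(p) > 0)

    def test_goal_success_identity_translation(self, system):
        fp = FreeParams(beta0=0, beta=0, tr=1.0, u0=0, r0=0)
        for A in (-2.0, 0.0, 1.7):
            assert goal_success_probability(A, fp, system) == pytest.approx(
                float(retrieval_probability(A, system))
            )

    def test_goal_success_midpoint_and_closed_form(self, system):
        fp = FreeParams(beta0=0, beta=0, tr=2.0, u0=0, r0=0)
        assert goal_success_probability(system.tau / 2.0, fp, system) == pytest.approx(0.5)
        fp_tf = FreeParams(beta0=0, beta=0, tr=3.6615, u0=0, r0=0)
        want = 1.0 / (1.0 + math.exp(-3.6615 / 0.25))
        assert goal_success_probability(1.0, fp_tf, system) == pytest.approx(want, rel=1e-12)

    def test_additive_translation_mode(self):
        sys_add = SystemParams(translation="additive")
        fp = FreeParams(beta0=0, beta=0, tr=0.7, u0=0, r0=0)
        want = float(expit((1.0 + 0.7) / sys_add.s))
        assert goal_success_probability(1.0, fp, sys_add) == pytest.approx(want)

    def test_habit_probability_symmetry(self, system):
        assert habit_probability(0.0, system) == pytest.approx(0.5)
        for u in (0.3, 1.5, 4.0):
            assert habit_probability(u, system) + habit_probability(-u, system) == pytest.approx(
                1.0
            )
        assert habit_probability(1e6, system) == pytest.approx(1.0)


class TestUtilityTrajectory:
    def test_no_executions_constant(self, system):
        fp = FreeParams(beta0=0, beta=0, tr=1, u0=0.37, r0=5.0)
        assert np.allclose(utility_trajectory([], 10, fp, system), 0.37)

    def test_full_step_update(self):
        sys1 = SystemParams(alpha=1.0)
        fp = FreeParams(beta0=0, beta=0, tr=1, u0=0.0, r0=2.5)
        u = utility_trajectory([1], 2, fp, sys1)
        assert u[1] == pytest.approx(2.5)

    def test_three_updates_hand_recursion(self):
        sys02 = SystemParams(alpha=0.2)
        fp = FreeParams(beta0=0, beta=0, tr=1, u0=0.0, r0=1.0)
        u = utility_trajectory([1, 2, 3], 4, fp, sys02)
        assert u[3] == pytest.approx(1.0 - 0.8**3, abs=1e-12)

    def test_fixed_point_u0_equals_r0(self, system):
        fp = FreeParams(beta0=0, beta=0, tr=1, u0=0.9, r0=0.9)
        assert np.allclose(utility_trajectory(list(range(1, 15)), 15, fp, system), 0.9)

    def test_converges_to_r0(self, system):
        fp = FreeParams(beta0=0, beta=0, tr=1, u0=-3.0, r0=2.0)
        horizon = 1001
        u = utility_trajectory(list(range(1, horizon)), horizon, fp, system)
        assert abs(u[-1] - 2.0) < 1e-6


def _assert_traces_equal(a, b):
    """Field-wise identity, treating the empty-history nan B as equal to itself."""
    assert a.day == b.day
    for name in ("B", "A", "P_G", "P_S", "U", "P_H", "P_SMDB", "goal_contrib", "habit_contrib"):
        x, y = getattr(a, name), getattr(b, name)
        assert (np.isnan(x) and np.isnan(y)) or x == y


class TestPredictSequence:
    def test_hand_stepped_toy_sequence(self, system, const_decay, sm_params):
        """Independent scalar re-derivation of a 3-day trace, [1, 0, 1]."""
        fp = sm_params
        seq = [1, 0, 1]
        traces = predict_sequence(seq, fp, system, const_decay)

        def logistic(z):
            return 1.0 / (1.0 + math.exp(-z))

        d = const_decay.d_const
        u = fp.u0
        expected = []
        for day, hist in ((1, []), (2, [1]), (3, [1])):
            ages = [day - k for k in hist]
            A = fp.beta0 if not ages else fp.beta0 + fp.beta * math.log(
                sum(t**-d for t in ages)
            )
            p_g = logistic((A - system.tau) / system.s)
            p_s = logistic((fp.tr * A - system.tau) / system.s)
            p_h = logistic(u / (math.sqrt(2) * system.s_u))
            expected.append((A, p_g, p_s, p_h, p_g * p_s + (1 - p_g) * p_h))
            if seq[day - 1]:
                u = u + system.alpha * (fp.r0 - u)

        for t, (A, p_g, p_s, p_h, p) in zip(traces, expected):
            assert t.A == pytest.approx(A, abs=1e-12)
            assert t.P_G == pytest.approx(p_g, abs=1e-12)
            assert t.P_S == pytest.approx(p_s, abs=1e-12)
            assert t.P_H == pytest.approx(p_h, abs=1e-12)
            assert t.P_SMDB == pytest.approx(p, abs=1e-12)

    def test_conditioning_is_on_observed_history_only(self, system, const_decay, sm_params):
        # changing a FUTURE day never changes an earlier day's trace
        t1 = predict_sequence([1, 0, 0, 0], sm_params, system, const_decay)
        t2 = predict_sequence([1, 0, 0, 1], sm_params, system, const_decay)
        for a, b in zip(t1[:3], t2[:3]):
            _assert_traces_equal(a, b)

    def test_saturated_retrieval_reduces_to_goal_route(self, system, const_decay):
        fp = FreeParams(beta0=50.0, beta=0.0, tr=0.02, u0=-1.0, r0=-1.0)
        for t in predict_sequence([1, 1, 0, 1, 0], fp, system, const_decay):
            assert t.P_SMDB == pytest.approx(t.P_S, abs=1e-9)

    def test_suppressed_retrieval_reduces_to_habit_route(self, system, const_decay):
        fp = FreeParams(beta0=-50.0, beta=0.0, tr=1.0, u0=0.4, r0=0.9)
        for t in predict_sequence([1, 1, 0, 1, 0], fp, system, const_decay):
            assert t.P_SMDB == pytest.approx(t.P_H, abs=1e-9)

    def test_rejects_non_binary(self, system, const_decay, sm_params):
        with pytest.raises(ValueError):
            predict_sequence([0, 2, 1], sm_params, system, const_decay)

    def test_deterministic(self, system, pavlik, sm_params):
        a = predict_sequence([1, 0, 1, 1, 0, 1], sm_params, system, pavlik)
        b = predict_sequence([1, 0, 1, 1, 0, 1], sm_params, system, pavlik)
        for ta, tb in zip(a, b):
            _assert_traces_equal(ta, tb)

    def test_matrix_path_matches_sequence_path(self, system, pavlik, const_decay, sm_params):
        rng = np.random.default_rng(11)
        X = (rng.random((8, 21)) < 0.55).astype(int)
        for decay in (pavlik, const_decay):
            parts = predict_matrix(X, sm_params, system, decay)
            for i in range(X.shape[0]):
                traces = predict_sequence(X[i], sm_params, system, decay)
                np.testing.assert_allclose(
                    parts["P_SMDB"][i], [t.P_SMDB for t in traces], atol=1e-12
                )
                np.testing.assert_allclose(parts["U"][i], [t.U for t in traces], atol=1e-12)


class TestMechanismContributions:
    def test_sum_identity_and_direct_arithmetic(self, system, pavlik, sm_params):
        traces = predict_sequence([1, 1, 0, 1, 0, 0, 1], sm_params, system, pavlik)
        goal, habit = mechanism_contributions(traces)
        total = np.array([t.P_SMDB for t in traces])
        np.testing.assert_allclose(goal + habit, total, atol=1e-12)
        # direct arithmetic: P_G=0.5, P_S=0.8, P_H=0.4 -> (0.4, 0.2)
        assert 0.5 * 0.8 == pytest.approx(0.4)
        assert (1 - 0.5) * 0.4 == pytest.approx(0.2)

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            mechanism_contributions([])


@settings(max_examples=60, derandomize=True)
@given(
    beta0=st.floats(-10, 10),
    beta=st.floats(-5, 5),
    tr=st.floats(-5, 5),
    u0=st.floats(-10, 10),
    r0=st.floats(-10, 10),
)
def test_all_probabilities_bounded(beta0, beta, tr, u0, r0):
    fp = FreeParams(beta0=beta0, beta=beta, tr=tr, u0=u0, r0=r0)
    for t in predict_sequence([1, 0, 1, 1, 0], fp):
        for p in (t.P_G, t.P_S, t.P_H, t.P_SMDB):
            assert 0.0 <= p <= 1.0
        assert abs(t.P_SMDB - (t.goal_contrib + t.habit_contrib)) < 1e-12


def test_baselevel_matrix_matches_series(system, pavlik):
    rng = np.random.default_rng(12)
    X = (rng.random((6, 14)) < 0.5).astype(int)
    B = baselevel_matrix(X, pavlik, system)
    for i in range(6):
        executed = [n + 1 for n in np.flatnonzero(X[i])]
        np.testing.assert_array_equal(
            np.isnan(B[i]), np.isnan(baselevel_series(executed, 14, pavlik, system))
        )
        np.testing.assert_allclose(
            B[i], baselevel_series(executed, 14, pavlik, system), atol=1e-15, equal_nan=True
        )
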