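"""Weighted importance sampling, bootstrap bounds, constrained baselines."""

import numpy as np
import pytest

from sepsisrl.discretize import action_components
from sepsisrl.ope import (
    LoggedTrajectory,
    SoftenedPolicy,
    bootstrap_bounds,
    calibration_curve,
    importance_ratios,
    make_constrained_policies,
    soften,
    wis_estimate,
)
from sepsisrl.solvers import Policy, policy_evaluation
from sepsisrl.toy import random_mdp


def _traj(states, actions, reward):
    return LoggedTrajectory(
        states=np.array(states), actions=np.array(actions), terminal_reward=reward
    )


def uniform_policy(k, A):
    return Policy(kind="stochastic", probs=np.full((k, A), 1.0 / A))


class TestImportanceRatios:
    def test_identical_policies_give_unit_ratios(self):
        pi = uniform_policy(3, 4)
        t = _traj([0, 1, 2], [0, 1, 2], 100.0)
        assert np.allclose(importance_ratios(t, pi, pi), 1.0)

    def test_running_product(self):
        pi_t = Policy(kind="stochastic", probs=np.array([[0.8, 0.2], [0.2, 0.8]]))
        pi_b = Policy(kind="stochastic", probs=np.array([[0.4, 0.6], [0.6, 0.4]]))
        t = _traj([0, 1], [0, 0], 100.0)
        # ratios 0.8/0.4 = 2 and 0.2/0.6 = 1/3 -> cumulative [2, 2/3]
        assert np.allclose(importance_ratios(t, pi_t, pi_b), [2.0, 2.0 / 3.0])

    def test_softened_policy_arithmetic(self):
        # greedy action 1 of 3 available: probs (0.005, 0.99, 0.005)
        base = Policy(kind="deterministic", actions=np.array([1]))
        sp = SoftenedPolicy(base=base, available=np.ones((1, 3), bool), p_greedy=0.99)
        pi_b = Policy(kind="stochastic", probs=np.array([[0.5, 0.3, 0.2]]))
        t = _traj([0], [0], 100.0)
        assert importance_ratios(t, sp, pi_b)[0] == pytest.approx(0.005 / 0.5)

    def test_zero_behavior_probability_is_an_error(self):
        pi_t = uniform_policy(1, 2)
        pi_b = Policy(kind="stochastic", probs=np.array([[1.0, 0.0]]))
        t = _traj([0], [1], 100.0)
        with pytest.raises(ValueError, match="zero probability"):
            importance_ratios(t, pi_t, pi_b)

    def test_unsoftened_deterministic_target_rejected(self):
        det = Policy(kind="deterministic", actions=np.array([0]))
        with pytest.raises(ValueError, match="softened"):
            wis_estimate([_traj([0], [0], 100.0)], det, uniform_policy(1, 2))


class TestWISEstimate:
    def test_self_evaluation_equals_mean_discounted_return(self):
        rng = np.random.default_rng(0)
        pi = Policy(kind="stochastic", probs=rng.dirichlet(np.ones(4), size=5))
        trajs = [
            _traj(
                rng.integers(0, 5, size=T),
                rng.integers(0, 4, size=T),
                100.0 if rng.random() < 0.6 else -100.0,
            )
            for T in rng.integers(1, 8, size=30)
        ]
        gamma = 0.97
        expected = np.mean([t.discounted_return(gamma) for t in trajs])
        got = wis_estimate(trajs, pi, pi, gamma).estimate
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_trajectory_self_normalizes(self):
        pi_t = Policy(kind="stochastic", probs=np.array([[0.9, 0.1]]))
        pi_b = Policy(kind="stochastic", probs=np.array([[0.2, 0.8]]))
        t = _traj([0, 0, 0], [0, 0, 1], -100.0)
        got = wis_estimate([t], pi_t, pi_b, gamma=0.9).estimate
        assert got == pytest.approx(0.9**2 * -100.0, abs=1e-12)

    def test_three_trajectory_hand_oracle(self):
        # gamma=1; behavior uniform over 2 actions (p=0.5 each step), target
        # puts 0.8 on action 0 and 0.2 on action 1 in every state:
        #   traj A: actions [0,0], survived : rho = (1.6)^2 = 2.56, G=+100
        #   traj B: actions [0,1], died     : rho = 1.6*0.4 = 0.64, G=-100
        #   traj C: actions [1],  survived  : rho = 0.4,           G=+100
        # weights sum = 3.60; WIS = (2.56*100 - 0.64*100 + 0.4*100)/3.60
        pi_t = Policy(kind="stochastic", probs=np.array([[0.8, 0.2]]))
        pi_b = Policy(kind="stochastic", probs=np.array([[0.5, 0.5]]))
        trajs = [
            _traj([0, 0], [0, 0], 100.0),
            _traj([0, 0], [0, 1], -100.0),
            _traj([0], [1], 100.0),
        ]
        expected = (2.56 * 100 - 0.64 * 100 + 0.4 * 100) / 3.60
        got = wis_estimate(trajs, pi_t, pi_b, gamma=1.0).estimate
        assert got == pytest.approx(expected, abs=1e-10)

    def test_scaling_all_ratios_leaves_wis_unchanged(self):
        # common horizon T: scaling per-step probabilities by c scales every
        # cumulative ratio by the same constant c^T, which self-normalizes away
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(3), size=4)
        pi_b = Policy(kind="stochastic", probs=rng.dirichlet(np.ones(3), size=4))
        trajs = [
            _traj(rng.integers(0, 4, size=4), rng.integers(0, 3, size=4),
                  100.0 if rng.random() < 0.5 else -100.0)
            for _ in range(20)
        ]
        base = wis_estimate(trajs, probs, pi_b, 0.99).estimate
        scaled = wis_estimate(trajs, probs * 7.3, pi_b, 0.99).estimate
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_no_trajectories_rejected(self):
        with pytest.raises(ValueError):
            wis_estimate([], uniform_policy(1, 2), uniform_policy(1, 2))

    def test_estimate_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            probs = rng.dirichlet(np.ones(3) * 0.3, size=4)
            pi_t = Policy(kind="stochastic", probs=probs)
            pi_b = uniform_policy(4, 3)
            trajs = [
                _traj(rng.integers(0, 4, size=T), rng.integers(0, 3, size=T),
                      100.0 if rng.random() < 0.5 else -100.0)
                for T in rng.integers(1, 9, size=40)
            ]
            est = wis_estimate(trajs, pi_t, pi_b, 1.0).estimate
            assert -100.0 - 1e-9 <= est <= 100.0 + 1e-9


class TestBootstrap:
    def test_degenerate_identical_survivors(self):
        pi = uniform_policy(1, 2)
        trajs = [_traj([0], [0], 100.0) for _ in range(10)]
        res = bootstrap_bounds(trajs, pi, pi, gamma=1.0, B=100, seed=0)
        assert res.lb95 == res.lb99 == res.bootstrap_mean == 100.0

    def test_single_resample(self):
        pi = uniform_policy(1, 2)
        trajs = [_traj([0], [0], 100.0), _traj([0], [1], -100.0)]
        res = bootstrap_bounds(trajs, pi, pi, gamma=1.0, B=1, seed=3)
        assert res.lb95 == res.lb99 == res.bootstrap[0]

    def test_matches_independent_reference_implementation(self):
        rng = np.random.default_rng(5)
        pi_t = Policy(kind="stochastic", probs=rng.dirichlet(np.ones(3), size=4))
        pi_b = Policy(kind="stochastic", probs=rng.dirichlet(np.ones(3), size=4))
        trajs = [
            _traj(rng.integers(0, 4, size=T), rng.integers(0, 3, size=T),
                  100.0 if rng.random() < 0.5 else -100.0)
            for T in rng.integers(1, 6, size=20)
        ]
        gamma, B, seed = 0.98, 400, 11
        res = bootstrap_bounds(trajs, pi_t, pi_b, gamma, B=B, seed=seed)

        # naive reference: per-trajectory loops, same resample index stream
        def naive_wis(subset):
            rhos, returns = [], []
            for t in subset:
                rho = 1.0
                for s, a in zip(t.states, t.actions):
                    rho *= pi_t.probs[s, a] / pi_b.probs[s, a]
                rhos.append(rho)
                returns.append(gamma ** (t.horizon - 1) * t.terminal_reward)
            w = np.mean(rhos)
            return np.mean([r / w * g for r, g in zip(rhos, returns)])

        ref_rng = np.random.default_rng(seed)
        ref = np.array(
            [
                naive_wis([trajs[i] for i in ref_rng.integers(0, len(trajs), len(trajs))])
                for _ in range(B)
            ]
        )
        assert res.lb95 == pytest.approx(np.percentile(ref, 5), abs=1e-9)
        assert res.lb99 == pytest.approx(np.percentile(ref, 1), abs=1e-9)

    def test_bound_ordering_and_range(self):
        rng = np.random.default_rng(9)
        pi_t = Policy(kind="stochastic", probs=rng.dirichlet(np.ones(3), size=4))
        pi_b = uniform_policy(4, 3)
        trajs = [
            _traj(rng.integers(0, 4, size=T), rng.integers(0, 3, size=T),
                  100.0 if rng.random() < 0.5 else -100.0)
            for T in rng.integers(1, 6, size=25)
        ]
        res = bootstrap_bounds(trajs, pi_t, pi_b, 0.99, B=300, seed=2)
        assert res.lb99 <= res.lb95 <= res.bootstrap.max()
        assert res.lb95 <= res.bootstrap_mean + 1e-12
        assert np.all(np.abs(res.bootstrap) <= 100 + 1e-9)


class TestConstrainedPolicies:
    def test_no_vasopressor_policy_is_structurally_vaso_free(self):
        mdp = random_mdp(6, 25, seed=4)
        policies = make_constrained_policies(mdp)
        vb, _ = action_components(policies["NO_VASOPRESSORS"].actions)
        assert np.all(vb == 0)
        _, fb = action_components(policies["NO_FLUID"].actions)
        assert np.all(fb == 0)
        assert np.all(policies["NO_DRUGS"].actions == 0)

    def test_rand_uniform_over_available(self):
        mdp = random_mdp(3, 4, seed=1)
        mdp.counts[0, 1:] = 0  # state 0: only action 0 available
        pi = make_constrained_policies(mdp)["RAND"]
        assert pi.probs[0, 0] == 1.0
        assert np.allclose(pi.probs[1], 0.25)

    def test_rand_with_single_action_equals_that_action(self):
        k = 2
        mdp = random_mdp(k, 3, seed=2, gamma=1.0)
        mdp.counts[:, 1:] = 0
        pi_rand = make_constrained_policies(mdp)["RAND"]
        V_rand = policy_evaluation(mdp, pi_rand)
        det = Policy(kind="deterministic", actions=np.zeros(k, dtype=int))
        V_det = policy_evaluation(mdp, det)
        assert np.allclose(V_rand, V_det)


class TestCalibration:
    def test_all_survivors_at_top_value(self):
        out = calibration_curve(np.full(10, 100.0), np.zeros(10, bool))
        assert len(out) == 1
        assert out.iloc[0].value_mid == 90.0
        assert out.iloc[0].mortality == 0.0

    def test_split_extremes(self):
        values = np.array([-100.0] * 5 + [100.0] * 5)
        died = np.array([True] * 5 + [False] * 5)
        out = calibration_curve(values, died)
        assert out.mortality.tolist() == [1.0, 0.0]

    def test_mortality_decreases_with_value_on_synthetic_log(self, small_table):
        # behavior-policy state values should rank patients by survival
        from scipy.stats import spearmanr

        from sepsisrl.experiments import _prepare_log
        from sepsisrl.solvers import estimate_clinician_policy

        sm, ag, mdp, pi_c, trajs, _ = _prepare_log(
            small_table, "CARDIO", 15, 3, 5, 0.99
        )
        probs = np.where(
            mdp.available, pi_c.probs * mdp.available, 0.0
        )
        rows = probs.sum(1, keepdims=True)
        ok = rows[:, 0] > 0
        probs[ok] = probs[ok] / rows[ok]
        probs[~ok] = mdp.available[~ok] / np.maximum(
            mdp.available[~ok].sum(1, keepdims=True), 1
        )
        from sepsisrl.solvers import Policy as P

        V = policy_evaluation(mdp, P(kind="stochastic", probs=probs))
        values = np.array([V[t.states[0]] for t in trajs])
        died = np.array([t.terminal_reward < 0 for t in trajs])
        curve = calibration_curve(values, died, n_bins=6)
        if len(curve) >= 2:
            rho, _ = spearmanr(curve.value_mid, curve.mortality)
            assert rho <= 0
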