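"""Study-level validation experiments.

Each function runs one self-contained experiment of the pipeline's validation
protocol — dynamic-programming oracle agreement, weighted-importance-sampling
identities, off-policy-evaluation consistency, latent-policy recovery, and the
feature-informativeness comparison — and returns the measured quantities.
They are consumed by the acceptance test suite and by ``scripts/acceptance.py``.

Problem sizes (chosen as the study conditions, documented in the methods
note): 50 random MDPs of up to 20 states / 5 actions for the solver oracle;
a 10-state MDP with 500/5000 simulated trajectories for OPE consistency;
5000-patient cohorts with 50 clusters for policy recovery and the CARDIO
versus BASELINE comparison (20 re-clustered trials per model).
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, LatentGroundTruth, generate_cohort
from .discretize import ActionDiscretizer, StateDiscretizer
from .experiments import ExperimentConfig, _prepare_log, run_trial
from .features import CARDIO_FEATURES
from .mdp import (
    build_mdp,
    count_transitions,
    filter_rare_transitions,
    simulate_trajectories,
)
from .ope import soften, trajectories_from_sequences, wis_estimate
from .preprocessing import preprocess
from .solvers import (
    Policy,
    estimate_clinician_policy,
    policy_evaluation,
    policy_iteration,
)
from .toy import random_mdp, value_iteration_oracle


def solver_oracle_experiment(
    seed: int, n_mdps: int = 50, n_random_policies: int = 100
) -> dict:
    """Policy iteration vs long-horizon value iteration on random MDPs.

    Returns the worst absolute state-value discrepancy over all MDPs and the
    number of (state, policy) dominance violations against random
    deterministic policies (tolerance 1e-9).
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    violations = 0
    for i in range(n_mdps):
        k = int(rng.integers(2, 21))
        A = int(rng.integers(2, 6))
        gamma = float(rng.choice([0.9, 0.95, 0.99, 1.0]))
        mdp = random_mdp(k, A, seed=int(rng.integers(2**31)), gamma=gamma)
        pi, V, _ = policy_iteration(mdp)
        V_star = value_iteration_oracle(mdp, n_iter=10_000, tol=1e-13)
        max_err = max(max_err, float(np.max(np.abs(V[:k] - V_star))))
        for _ in range(n_random_policies):
            actions = rng.integers(0, A, size=k)
            V_rand = policy_evaluation(
                mdp, Policy(kind="deterministic", actions=actions)
            )
            violations += int(np.sum(V[:k] < V_rand[:k] - 1e-9))
    return {
        "max_abs_error": max_err,
        "dominance_violations": violations,
        "n_mdps": n_mdps,
    }


def wis_identity_experiment(seed: int, n_traj: int = 200) -> dict:
    """Exactness of the WIS estimator's three structural identities."""
    rng = np.random.default_rng(seed)
    k, A = 6, 4
    pi_b = Policy(kind="stochastic", probs=rng.dirichlet(np.ones(A), size=k))
    pi_t = Policy(kind="stochastic", probs=rng.dirichlet(np.ones(A), size=k))
    from .ope import LoggedTrajectory

    trajs = [
        LoggedTrajectory(
            states=rng.integers(0, k, size=T),
            actions=rng.integers(0, A, size=T),
            terminal_reward=100.0 if rng.random() < 0.6 else -100.0,
        )
        for T in rng.integers(1, 9, size=n_traj)
    ]
    gamma = 0.99
    # identity 1: self-evaluation returns the empirical mean discounted return
    mean_return = float(np.mean([t.discounted_return(gamma) for t in trajs]))
    self_err = abs(wis_estimate(trajs, pi_b, pi_b, gamma).estimate - mean_return)
    # identity 2: a single trajectory self-normalizes to its own return
    t0 = trajs[0]
    single_err = abs(
        wis_estimate([t0], pi_t, pi_b, gamma).estimate - t0.discounted_return(gamma)
    )
    # identity 3: scaling all cumulative ratios by a constant changes nothing
    T_common = 5
    common = [
        LoggedTrajectory(
            states=rng.integers(0, k, size=T_common),
            actions=rng.integers(0, A, size=T_common),
            terminal_reward=100.0 if rng.random() < 0.5 else -100.0,
        )
        for _ in range(50)
    ]
    base = wis_estimate(common, pi_t.probs, pi_b, gamma).estimate
    scaled = wis_estimate(common, pi_t.probs * 4.2, pi_b, gamma).estimate
    scale_err = abs(scaled - base)
    return {
        "self_evaluation_abs_err": self_err,
        "single_trajectory_abs_err": single_err,
        "scale_invariance_abs_err": scale_err,
        "n_trajectories": n_traj,
    }


def ope_consistency_experiment(
    seed: int, sizes: tuple[int, ...] = (500, 5000), n_reps: int = 5
) -> dict:
    """WIS of a softened greedy policy vs its model-based value.

    Trajectories are simulated from a known 10-state MDP under a stochastic
    behavior policy (70% greedy / 30% uniform); the error at each sample size
    is the RMSE over ``n_reps`` independent simulations.  The MDP absorbs at
    least 15% of mass per step so episode lengths — and hence the importance-
    ratio products — stay bounded.
    """
    gamma = 0.99
    mdp = random_mdp(
        10, 4, seed=seed, gamma=gamma, p_terminal=0.4, p_terminal_floor=0.15
    )
    pi_star, _, _ = policy_iteration(mdp)
    target = soften(mdp, pi_star, p_greedy=0.99)
    tp = target.prob_matrix()
    V_soft = policy_evaluation(mdp, Policy(kind="stochastic", probs=tp))
    v_model = float(mdp.d0[:10] @ V_soft[:10] / mdp.d0[:10].sum())
    behavior = 0.7 * tp + 0.3 * np.ones_like(tp) / tp.shape[1]
    out = {"model_based_value": v_model}
    for N in sizes:
        sq = []
        for rep in range(n_reps):
            seqs, acts = simulate_trajectories(
                mdp, behavior, N, seed=(seed * 7919 + 31 * N + rep) % 2**31
            )
            trajs = trajectories_from_sequences(seqs, acts, 10)
            counts, _ = count_transitions(seqs, acts, 10, 4)
            pi_c = estimate_clinician_policy(counts)
            est = wis_estimate(trajs, target, pi_c, gamma).estimate
            sq.append((est - v_model) ** 2)
        out[f"rmse_n{N}"] = float(np.sqrt(np.mean(sq)))
    return out


def policy_recovery_experiment(
    seed: int, n_patients: int = 5000, k: int = 50, treatment_effect: float = 2.0
) -> dict:
    """Fraction of training state-visits where the learned policy equals the
    latent-optimal action.

    Evaluated at gamma = 1 (pure survival-probability objective).
    """
    config = CohortConfig(
        n_patients=n_patients, seed=seed % 2**31, treatment_effect=treatment_effect
    )
    truth = LatentGroundTruth.default(config.feature_names)
    raw = generate_cohort(config, truth)
    table = preprocess(raw)
    sm, ag, mdp, pi_c, trajs, _ = _prepare_log(
        table, "CARDIO", k, (seed + 1) % 2**31, threshold=5, gamma=1.0
    )
    pi_ai, _, _ = policy_iteration(mdp)
    train = table[table.split == "train"]
    ids = sm.transform(train[list(CARDIO_FEATURES)].to_numpy(float))
    latents = raw.latents.set_index(["patient_id", "bin_index"]).latent
    z = latents.loc[list(zip(train.patient_id, train.bin_index))].to_numpy()
    optimal = np.asarray(truth.optimal_action_by_latent)[z]
    agreement = float(np.mean(pi_ai.actions[ids] == optimal))
    return {
        "agreement": agreement,
        "n_visits": int(len(z)),
        "mortality": float(
            table.drop_duplicates("patient_id").outcome.eq("died").mean()
        ),
    }


def feature_separation_experiment(
    seed: int, n_patients: int = 5000, k: int = 50, n_trials: int = 20
) -> dict:
    """CARDIO vs BASELINE mean policy values when the outcome depends only on
    cardiorespiratory features."""
    config = CohortConfig(
        n_patients=n_patients, seed=seed % 2**31, treatment_effect=2.0
    )
    truth = LatentGroundTruth.default(config.feature_names, informative="cardio_only")
    table = preprocess(generate_cohort(config, truth))
    ec = ExperimentConfig(n_trials=1, k_values=(k,), bootstrap_B=500)
    out = {}
    for name in ("CARDIO", "BASELINE"):
        vals = [
            run_trial(table, name, k, seed=(seed + 100 + t) % 2**31, config=ec)
            for t in range(n_trials)
        ]
        out[name] = {
            "median_mean_policy_value": float(
                np.median([v.mean_policy_value for v in vals])
            ),
            "best_mean_policy_value": float(
                max(v.mean_policy_value for v in vals)
            ),
        }
    out["clinician_value"] = vals[-1].clinician_value
    out["n_trials"] = n_trials
    return out


def structural_checks(seed: int) -> dict:
    """Grid cardinality, state count, terminal rewards, filter behavior —
    computed from fitted objects, not constants."""
    rng = np.random.default_rng(seed)
    doses_v = np.concatenate([np.zeros(50), rng.lognormal(-2.3, 0.9, 450)])
    doses_f = np.concatenate([np.zeros(50), rng.lognormal(5.5, 0.8, 450)])
    ag = ActionDiscretizer().fit(doses_v, doses_f)
    mesh_v = np.concatenate([[0.0], np.geomspace(1e-4, 10, 400)])
    mesh_f = np.concatenate([[0.0], np.geomspace(1e-2, 1e5, 400)])
    ids = ag.transform(
        np.repeat(mesh_v, len(mesh_f)), np.tile(mesh_f, len(mesh_v))
    )
    n_actions = int(len(np.unique(ids)))
    X = rng.normal(size=(3000, 6))
    sm = StateDiscretizer(k=750, seed=seed % 2**31).fit(X)
    n_states_total = int(sm.n_states_)
    # estimated MDP carries the terminal rewards
    seqs = {0: np.array([0, 1, 2]), 1: np.array([1, 0, 3])}
    acts = {0: np.array([0, 1]), 1: np.array([1, 0])}
    toy = build_mdp(seqs, acts, k=2, threshold=1, n_actions=2)
    R = toy.reward_vector()
    # filter behavior on a tensor holding counts 1..10
    counts = np.zeros((2, 5, 4), dtype=np.int64)
    counts.flat[:10] = np.arange(1, 11)
    kept = int((filter_rare_transitions(counts, 5) > 0).sum())
    boundary = filter_rare_transitions(counts, 5)
    kept_at_5 = int((boundary.flat[:10] > 0).sum())
    return {
        "n_actions": n_actions,
        "n_states_total": n_states_total,
        "reward_survive": float(R[toy.survived_state]),
        "reward_death": float(R[toy.dead_state]),
        "filter_toy_cells_kept": kept,
        "filter_kept_from_counts_5_to_10": kept_at_5,
    }
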