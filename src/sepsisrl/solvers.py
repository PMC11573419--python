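"""MDP solvers: exact policy evaluation, policy iteration, TD (SARSA), and
the empirical clinician policy.

Policy evaluation solves the linear Bellman system

    V(s) = sum_a pi(a|s) sum_s' T[s, a, s'] (R(s') + gamma * V(s'))

directly (the clinical state space is at most 750, so a dense solve is cheap
and exact).  Terminal states have V = 0 after reward receipt, so the system is
restricted to clinical states with the terminal reward folded into the
constant term.  Policy iteration alternates this evaluation with greedy
improvement over available actions, ties broken toward the lowest action id,
and terminates when the policy is a fixed point — guaranteed within
``n_states * n_actions`` improvement steps for a finite MDP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdp import MDPModel

#: Sentinel Q-value for unavailable state-action pairs.
UNAVAILABLE = -np.inf


@dataclass
class Policy:
    """Deterministic (``actions``) or stochastic (``probs``) state→action map.

    Only clinical states are covered; terminal states take no action.
    ``valid`` flags states with at least one available action — deterministic
    policies are undefined elsewhere and such states are skipped by the
    solvers (they fall back to a zero-reward self-loop).
    """

    kind: str
    actions: np.ndarray | None = None  # (k,) int
    probs: np.ndarray | None = None  # (k, A)
    valid: np.ndarray | None = None  # (k,) bool

    def __post_init__(self):
        if self.kind not in {"deterministic", "stochastic"}:
            raise ValueError("kind must be deterministic or stochastic")
        if self.kind == "deterministic" and self.actions is None:
            raise ValueError("deterministic policy needs actions")
        if self.kind == "stochastic":
            if self.probs is None:
                raise ValueError("stochastic policy needs probs")
            rows = self.probs.sum(axis=1)
            ok = self.valid if self.valid is not None else np.ones(len(rows), bool)
            if not np.allclose(rows[ok], 1.0, atol=1e-12):
                raise ValueError("stochastic policy rows must sum to 1")
        if self.valid is None:
            k = len(self.actions) if self.actions is not None else len(self.probs)
            self.valid = np.ones(k, dtype=bool)

    @property
    def k(self) -> int:
        return len(self.actions) if self.actions is not None else len(self.probs)

    def prob_matrix(self, n_actions: int) -> np.ndarray:
        """(k, A) action-probability rows (one-hot for deterministic)."""
        if self.kind == "stochastic":
            return self.probs
        P = np.zeros((self.k, n_actions))
        P[np.arange(self.k)[self.valid], self.actions[self.valid]] = 1.0
        return P


def policy_evaluation(mdp: MDPModel, pi: Policy) -> np.ndarray:
    """Exact V^pi over all states (terminals are 0) via direct linear solve."""
    k, A = mdp.k, mdp.n_actions
    avail = mdp.available
    P = pi.prob_matrix(A)
    if np.any(P[avail.any(axis=1) & pi.valid] @ np.ones(A) == 0):
        raise ValueError("policy undefined on a state with available actions")
    if np.any((P > 0) & ~avail):
        raise ValueError("policy places mass on an unavailable action")
    R = mdp.reward_vector()
    # T_pi[s, s'] = sum_a pi(a|s) T[s, a, s']
    T_pi = np.einsum("sa,sat->st", P, mdp.T)
    b = T_pi @ R  # expected terminal reward one step ahead
    M = mdp.gamma * T_pi[:, :k]  # clinical-to-clinical part
    V = np.zeros(mdp.n_states)
    solve_mask = pi.valid & avail.any(axis=1)
    if solve_mask.any():
        idx = np.where(solve_mask)[0]
        A_mat = np.eye(len(idx)) - M[np.ix_(idx, idx)]
        try:
            # transitions into invalid clinical states contribute via V=0
            V[idx] = np.linalg.solve(A_mat, b[idx])
        except np.linalg.LinAlgError:
            # gamma = 1 with a filtering-induced recurrent class: minimum-norm
            # solution keeps the absorbing part exact
            V[idx] = np.linalg.lstsq(A_mat, b[idx], rcond=None)[0]
    return np.clip(V, -100.0, 100.0)


def q_from_v(mdp: MDPModel, V: np.ndarray) -> np.ndarray:
    """Q(s, a) for available pairs; unavailable cells hold ``-inf``."""
    R = mdp.reward_vector()
    # terminal V is 0 post-reward; clinical V enters discounted
    target = R + mdp.gamma * np.concatenate([V[: mdp.k], [0.0, 0.0]])
    Q = np.einsum("sat,t->sa", mdp.T, target)
    Q[~mdp.available] = UNAVAILABLE
    return Q


#: Absolute tolerance for treating Q-values as tied (values live on ±100).
TIE_TOL = 1e-9


def greedy_policy(mdp: MDPModel, Q: np.ndarray) -> Policy:
    """Greedy improvement with a safety-minded tie rule.

    Among actions whose Q lies within ``TIE_TOL`` of the state's maximum, the
    one clinicians used most often (largest retained transition count) is
    chosen, with the lowest action id as the final tie-break.  Value ties are
    common near absorption — many actions lead to certain survival — and
    preferring the commonly-taken action follows the same rationale as the
    rare-transition filter.
    """
    valid = mdp.available.any(axis=1)
    counts_sa = mdp.counts.sum(axis=2)
    actions = np.zeros(mdp.k, dtype=np.int64)
    qv = Q[valid]
    qmax = qv.max(axis=1, keepdims=True)
    tied = qv >= qmax - TIE_TOL
    # argmax returns the first (lowest-id) maximum among tied counts
    actions[valid] = np.argmax(np.where(tied, counts_sa[valid], -1), axis=1)
    return Policy(kind="deterministic", actions=actions, valid=valid)


def initial_policy(mdp: MDPModel) -> Policy:
    """Deterministic start: lowest-index available action per state."""
    valid = mdp.available.any(axis=1)
    actions = np.zeros(mdp.k, dtype=np.int64)
    actions[valid] = np.argmax(mdp.available[valid], axis=1)
    return Policy(kind="deterministic", actions=actions, valid=valid)


def policy_iteration(
    mdp: MDPModel,
) -> tuple[Policy, np.ndarray, np.ndarray]:
    """Alternate exact evaluation and greedy improvement to the optimum.

    Returns ``(policy, V, Q)``; the policy is restricted to available actions
    and states with none are flagged invalid.
    """
    pi = initial_policy(mdp)
    max_steps = mdp.n_states * mdp.n_actions
    V_prev = None
    for _ in range(max_steps):
        V = policy_evaluation(mdp, pi)
        Q = q_from_v(mdp, V)
        new = greedy_policy(mdp, Q)
        unchanged = np.array_equal(new.actions[pi.valid], pi.actions[pi.valid])
        # value convergence catches cycling among value-tied policies (gamma=1)
        settled = V_prev is not None and np.max(np.abs(V - V_prev)) < 1e-10
        if unchanged or settled:
            return new, V, Q
        V_prev = V
        pi = new
    raise RuntimeError("policy iteration failed to converge (finite-MDP bound hit)")


def estimate_clinician_policy(
    raw_counts: np.ndarray, delta: float = 0.01
) -> Policy:
    """Empirical behavior policy with add-delta smoothing.

    pi_C(a|s) is the visit-frequency of action ``a`` in state ``s`` among the
    *unfiltered* counts, smoothed by ``delta`` over the actions observed at
    least once in ``s`` (never-observed actions keep probability zero, which
    downstream importance sampling treats as a hard error if the AI policy
    needs them — softening the AI policy over observed actions avoids this).
    States never visited get a uniform row over all actions and are flagged
    invalid.
    """
    visits = raw_counts.sum(axis=2).astype(float)  # (k, A)
    k, A = visits.shape
    observed = visits > 0
    n_s = visits.sum(axis=1)
    m_s = observed.sum(axis=1)
    probs = np.zeros_like(visits)
    vis_states = n_s > 0
    num = visits + delta * observed
    den = n_s + delta * m_s
    probs[vis_states] = num[vis_states] / den[vis_states, None]
    probs[~vis_states] = 1.0 / A
    return Policy(kind="stochastic", probs=probs, valid=vis_states)


@dataclass
class TDConfig:
    """SARSA hyperparameters (initialization Q=0; multiplicative step decay)."""

    alpha: float = 0.1
    n_sweeps: int = 200
    alpha_decay: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def td_evaluate_clinician(
    sequences: dict,
    actions: dict,
    k: int,
    n_actions: int,
    gamma: float = 0.99,
    config: TDConfig | None = None,
) -> np.ndarray:
    """SARSA evaluation of the logged behavior policy.

    Sweeps over every logged (s, a, r, s', a') tuple in randomized order
    (seeded), bootstrapping with Q(terminal, ·) = 0 and the terminal-only
    reward attached to the transition entering the absorbing state.
    Returns the final (k, A) Q-table.
    """
    config = config or TDConfig()
    tuples = []
    for pid, seq in sequences.items():
        seq = np.asarray(seq)
        acts = np.asarray(actions[pid])
        for t in range(len(seq) - 1):
            s, s2 = int(seq[t]), int(seq[t + 1])
            a = int(acts[t])
            terminal = s2 >= k
            r = 0.0
            if terminal:
                r = 100.0 if s2 == k else -100.0
                a2 = -1
            else:
                a2 = int(acts[t + 1])
            tuples.append((s, a, r, s2, a2, terminal))
    rng = np.random.default_rng(config.seed)
    Q = np.zeros((k, n_actions))
    alpha = config.alpha
    order = np.arange(len(tuples))
    for _ in range(config.n_sweeps):
        rng.shuffle(order)
        for i in order:
            s, a, r, s2, a2, terminal = tuples[i]
            target = r if terminal else r + gamma * Q[s2, a2]
            Q[s, a] += alpha * (target - Q[s, a])
        alpha *= config.alpha_decay
    return Q
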