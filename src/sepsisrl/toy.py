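"""Small synthetic MDPs with known structure, for validation and examples.

These factories build :class:`~sepsisrl.mdp.MDPModel` instances directly
(bypassing count estimation) so solver and off-policy-evaluation behavior can
be checked against closed forms and brute-force oracles.
"""

from __future__ import annotations

import numpy as np

from .mdp import MDPModel


def mdp_from_T(
    T: np.ndarray, d0: np.ndarray | None = None, gamma: float = 0.99
) -> MDPModel:
    """Wrap an explicit transition tensor ``T[s, a, s']`` (k, A, k+2)."""
    k, A, _ = T.shape
    counts = (T > 0).astype(np.int64) * 1000  # every used cell is "common"
    if d0 is None:
        d0 = np.zeros(k + 2)
        d0[:k] = 1.0 / k
    return MDPModel(
        k=k, counts=counts, raw_counts=counts, T=T, d0=d0, gamma=gamma, threshold=1
    )


def random_mdp(
    k: int,
    n_actions: int,
    seed: int,
    gamma: float = 0.99,
    p_terminal: float = 0.15,
    p_terminal_floor: float = 0.02,
) -> MDPModel:
    """Random absorbing MDP: every action available, Dirichlet rows.

    Each (s, a) row places between ``p_terminal_floor`` and
    ``p_terminal_floor + p_terminal`` mass on the two terminals (split at
    random) and the rest over clinical states, guaranteeing absorption with
    probability one; a larger floor bounds episode lengths more tightly.
    """
    rng = np.random.default_rng(seed)
    T = np.zeros((k, n_actions, k + 2))
    for s in range(k):
        for a in range(n_actions):
            clin = rng.dirichlet(np.ones(k))
            pt = p_terminal * rng.random() + p_terminal_floor
            surv = rng.random()
            T[s, a, :k] = (1 - pt) * clin
            T[s, a, k] = pt * surv
            T[s, a, k + 1] = pt * (1 - surv)
    d0 = np.zeros(k + 2)
    d0[:k] = rng.dirichlet(np.ones(k))
    return mdp_from_T(T, d0, gamma)


def chain_mdp(gamma: float = 1.0) -> MDPModel:
    """Fixed 4-state, 2-action chain used as a worked fixture.

    Action 0 drifts toward death, action 1 toward survival; state 3 is the
    sickest.  Values have no closed form but a long value-iteration run
    converges tightly, making this a good oracle target.
    """
    k, A = 4, 2
    T = np.zeros((k, A, k + 2))
    # action 0: stay / worsen
    T[0, 0] = [0.6, 0.2, 0.0, 0.0, 0.2, 0.0]
    T[1, 0] = [0.1, 0.5, 0.3, 0.0, 0.0, 0.1]
    T[2, 0] = [0.0, 0.1, 0.5, 0.3, 0.0, 0.1]
    T[3, 0] = [0.0, 0.0, 0.1, 0.5, 0.0, 0.4]
    # action 1: improve
    T[0, 1] = [0.3, 0.1, 0.0, 0.0, 0.6, 0.0]
    T[1, 1] = [0.5, 0.3, 0.1, 0.0, 0.1, 0.0]
    T[2, 1] = [0.1, 0.5, 0.3, 0.0, 0.0, 0.1]
    T[3, 1] = [0.0, 0.1, 0.5, 0.2, 0.0, 0.2]
    d0 = np.array([0.1, 0.3, 0.4, 0.2, 0.0, 0.0])
    return mdp_from_T(T, d0, gamma)


def value_iteration_oracle(
    mdp: MDPModel, n_iter: int = 10_000, tol: float = 0.0
) -> np.ndarray:
    """Brute-force optimal state values by long-horizon value iteration.

    Independent of the policy-iteration path: plain Bellman-optimality sweeps
    on dense arrays.
    """
    k = mdp.k
    R = mdp.reward_vector()
    V = np.zeros(k)
    avail = mdp.available
    for _ in range(n_iter):
        target = np.concatenate([mdp.gamma * V, [0.0, 0.0]]) + np.concatenate(
            [np.zeros(k), R[k:]]
        )
        Q = mdp.T @ target
        Q[~avail] = -np.inf
        V_new = np.where(avail.any(axis=1), Q.max(axis=1), 0.0)
        if tol and np.max(np.abs(V_new - V)) < tol:
            return V_new
        V = V_new
    return V
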