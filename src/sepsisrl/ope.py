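"""Off-policy evaluation by weighted importance sampling (WIS).

For each logged trajectory the cumulative importance ratio is

    rho_{1:t} = prod_{t'<=t} pi_target(a_t' | s_t') / pi_behavior(a_t' | s_t')

and the per-trajectory estimate is ``V_WIS = rho_{1:T} / w_T * G`` where
``G = sum_t gamma^(t-1) r_t`` is the discounted return and ``w_t`` is the
cohort average of ``rho_{1:t}`` (with each trajectory's ratio frozen at its
own horizon for later t, so the average stays defined across variable-length
stays).  The overall estimate is the mean of the per-trajectory values; it is
self-normalizing (invariant to scaling all ratios) and equals the empirical
mean return when target and behavior coincide.

Deterministic target policies are softened before evaluation: the greedy
action keeps mass ``p_greedy`` (default 0.99) and the remainder is spread
uniformly over the other available actions.  Without softening, any logged
step that deviates from the deterministic recommendation zeroes the whole
trajectory's ratio and most of the data is discarded.

Confidence lower bounds come from a percentile bootstrap over trajectories:
lb95/lb99 are the 5th/1st percentiles of the WIS estimate across resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import action_components
from .mdp import MDPModel, REWARD_DEATH, REWARD_SURVIVE
from .solvers import Policy, policy_iteration



@dataclass
class LoggedTrajectory:
    """One patient's logged (state, action) path and terminal reward."""

    states: np.ndarray  # (T,) clinical state ids
    actions: np.ndarray  # (T,)
    terminal_reward: float  # +100 or -100

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.actions = np.asarray(self.actions, dtype=np.int64)
        if len(self.states) != len(self.actions) or len(self.states) < 1:
            raise ValueError("states/actions must be equal length >= 1")
        if self.terminal_reward not in (REWARD_SURVIVE, REWARD_DEATH):
            raise ValueError("terminal reward must be +100 or -100")

    @property
    def horizon(self) -> int:
        return len(self.states)

    def discounted_return(self, gamma: float) -> float:
        # rewards are zero except on entering the absorbing state at step T
        return float(gamma ** (self.horizon - 1) * self.terminal_reward)


def trajectories_from_sequences(
    sequences: dict, actions: dict, k: int
) -> list[LoggedTrajectory]:
    """Convert terminal-capped state sequences into logged trajectories."""
    out = []
    for pid in sorted(sequences):
        seq = np.asarray(sequences[pid])
        reward = REWARD_SURVIVE if seq[-1] == k else REWARD_DEATH
        out.append(
            LoggedTrajectory(
                states=seq[:-1], actions=np.asarray(actions[pid]), terminal_reward=reward
            )
        )
    return out


@dataclass
class SoftenedPolicy:
    """Deterministic policy with greedy mass ``p_greedy`` spread for overlap.

    In states where the base policy is undefined (never visited or no
    available action in training) the fallback action — by convention the
    clinician-majority action — receives the greedy mass.
    """

    base: Policy
    available: np.ndarray  # (k, A) bool
    p_greedy: float = 0.99
    fallback_actions: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 < self.p_greedy <= 1.0:
            raise ValueError("p_greedy must lie in (0, 1]")

    def prob_matrix(self) -> np.ndarray:
        k, A = self.available.shape
        actions = self.base.actions.copy()
        if self.fallback_actions is not None:
            actions[~self.base.valid] = self.fallback_actions[~self.base.valid]
        P = np.zeros((k, A))
        for s in range(k):
            a = actions[s]
            others = np.where(self.available[s])[0]
            others = others[others != a]
            if len(others) == 0 or self.p_greedy == 1.0:
                P[s, a] = 1.0
            else:
                P[s, a] = self.p_greedy
                P[s, others] = (1.0 - self.p_greedy) / len(others)
        return P


@dataclass
class WISResult:
    """Point estimate, per-trajectory values and bootstrap lower bounds."""

    estimate: float
    per_trajectory: np.ndarray
    bootstrap: np.ndarray | None = None
    bootstrap_mean: float | None = None
    lb95: float | None = None
    lb99: float | None = None
    B: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "bootstrap_mean": self.bootstrap_mean,
            "lb95": self.lb95,
            "lb99": self.lb99,
            "B": self.B,
            "seed": self.seed,
        }


def _target_probs(pi_target) -> np.ndarray:
    if isinstance(pi_target, SoftenedPolicy):
        return pi_target.prob_matrix()
    if isinstance(pi_target, Policy):
        if pi_target.kind == "deterministic":
            raise ValueError(
                "deterministic policies must be softened before WIS "
                "(wrap in SoftenedPolicy)"
            )
        return pi_target.probs
    return np.asarray(pi_target, dtype=float)


def importance_ratios(
    traj: LoggedTrajectory, pi_target, pi_behavior: Policy
) -> np.ndarray:
    """Cumulative importance ratios rho_{1:t}, t = 1..T."""
    P_t = _target_probs(pi_target)
    P_b = pi_behavior.probs
    num = P_t[traj.states, traj.actions]
    den = P_b[traj.states, traj.actions]
    if np.any(den <= 0):
        raise ValueError(
            "behavior policy assigns zero probability to a logged action "
            "(smoothing violated)"
        )
    return np.cumprod(num / den)


def _rho_matrix(
    trajs: list[LoggedTrajectory], pi_target, pi_behavior: Policy
) -> tuple[np.ndarray, np.ndarray]:
    """(N, Tmax) cumulative ratios frozen at each horizon, plus horizons."""
    horizons = np.array([t.horizon for t in trajs])
    Tmax = horizons.max()
    M = np.empty((len(trajs), Tmax))
    for i, traj in enumerate(trajs):
        rho = importance_ratios(traj, pi_target, pi_behavior)
        M[i, : traj.horizon] = rho
        M[i, traj.horizon :] = rho[-1]
    return M, horizons


def _wis_from_parts(
    rho: np.ndarray, horizons: np.ndarray, returns: np.ndarray
) -> tuple[float, np.ndarray]:
    # with each trajectory's ratio frozen at its own horizon, the running
    # average at the final step is w = mean_i rho_i(T_i); normalizing every
    # trajectory by it makes the weights sum to one, so the estimate is a
    # weighted average of returns and stays within [-100, 100]
    rho_T = rho[np.arange(len(horizons)), horizons - 1]
    w = rho_T.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(rho_T > 0, rho_T / w * returns, 0.0)
    return float(v.mean()), v


def wis_estimate(
    trajs: list[LoggedTrajectory],
    pi_target,
    pi_behavior: Policy,
    gamma: float = 0.99,
) -> WISResult:
    """Point WIS estimate of the target policy's value."""
    if len(trajs) < 1:
        raise ValueError("need at least one trajectory")
    rho, horizons = _rho_matrix(trajs, pi_target, pi_behavior)
    if not np.any(rho[np.arange(len(trajs)), horizons - 1] > 0):
        raise ValueError("no overlap: all trajectory weights are zero")
    returns = np.array([t.discounted_return(gamma) for t in trajs])
    est, per = _wis_from_parts(rho, horizons, returns)
    return WISResult(estimate=est, per_trajectory=per)


def bootstrap_bounds(
    trajs: list[LoggedTrajectory],
    pi_target,
    pi_behavior: Policy,
    gamma: float = 0.99,
    B: int = 2000,
    seed: int = 0,
) -> WISResult:
    """WIS with percentile-bootstrap confidence lower bounds.

    Trajectories are resampled with replacement; the self-normalizing weights
    ``w_t`` are recomputed within each resample.  lb95/lb99 are the 5th/1st
    percentiles of the bootstrap distribution; its mean is reported as the
    mean policy value.
    """
    if len(trajs) < 2:
        raise ValueError("bootstrap needs at least two trajectories")
    rho, horizons = _rho_matrix(trajs, pi_target, pi_behavior)
    returns = np.array([t.discounted_return(gamma) for t in trajs])
    est, per = _wis_from_parts(rho, horizons, returns)
    rng = np.random.default_rng(seed)
    N = len(trajs)
    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, N, size=N)
        boot[b], _ = _wis_from_parts(rho[idx], horizons[idx], returns[idx])
    return WISResult(
        estimate=est,
        per_trajectory=per,
        bootstrap=boot,
        bootstrap_mean=float(boot.mean()),
        lb95=float(np.percentile(boot, 5.0)),
        lb99=float(np.percentile(boot, 1.0)),
        B=B,
        seed=seed,
    )


# --- constrained baseline policies ---------------------------------------


def _restricted_optimal(mdp: MDPModel, allowed: np.ndarray) -> Policy:
    """Policy iteration on the MDP restricted to ``allowed`` actions."""
    restricted = MDPModel(
        k=mdp.k,
        counts=np.where(allowed[None, :, None], mdp.counts, 0),
        raw_counts=mdp.raw_counts,
        T=np.where(allowed[None, :, None], mdp.T, 0.0),
        d0=mdp.d0,
        gamma=mdp.gamma,
        threshold=mdp.threshold,
    )
    pi, _, _ = policy_iteration(restricted)
    return pi


def make_constrained_policies(mdp: MDPModel) -> dict[str, object]:
    """The four fixed benchmark policies.

    - ``RAND``: uniform over the available actions of each state.
    - ``NO_DRUGS``: always action 0 (no treatment at all).
    - ``NO_VASOPRESSORS``: vasopressor bin forced to 0; the fluid bin follows
      the optimal policy of the fluid-only restricted MDP.
    - ``NO_FLUID``: symmetric (fluid bin 0, optimal vasopressor).
    """
    k, A = mdp.k, mdp.n_actions
    avail = mdp.available
    valid = avail.any(axis=1)
    probs = np.where(valid[:, None], avail / np.maximum(avail.sum(axis=1), 1)[:, None], 1.0 / A)
    rand = Policy(kind="stochastic", probs=probs, valid=valid)
    no_drugs = Policy(
        kind="deterministic", actions=np.zeros(k, dtype=np.int64), valid=valid
    )
    vaso_bin, fluid_bin = action_components(np.arange(A))
    no_vaso = _restricted_optimal(mdp, vaso_bin == 0)
    no_fluid = _restricted_optimal(mdp, fluid_bin == 0)
    return {
        "RAND": rand,
        "NO_DRUGS": no_drugs,
        "NO_VASOPRESSORS": no_vaso,
        "NO_FLUID": no_fluid,
    }


def evaluate_constrained_policies(
    mdp: MDPModel,
    trajs: list[LoggedTrajectory],
    pi_behavior: Policy,
    gamma: float = 0.99,
    B: int = 2000,
    seed: int = 0,
    p_greedy: float = 0.99,
    fallback_actions: np.ndarray | None = None,
) -> dict[str, WISResult]:
    """Bootstrap-evaluate the four benchmark policies against the log."""
    policies = make_constrained_policies(mdp)
    out = {}
    for name, pi in policies.items():
        target = (
            pi
            if pi.kind == "stochastic"
            else SoftenedPolicy(
                base=pi,
                available=_softening_support(mdp, pi),
                p_greedy=p_greedy,
                fallback_actions=fallback_actions,
            )
        )
        out[name] = bootstrap_bounds(trajs, target, pi_behavior, gamma, B, seed)
    return out


def _softening_support(mdp: MDPModel, pi: Policy) -> np.ndarray:
    """Actions eligible for softening mass: available, or the greedy action."""
    support = mdp.available.copy()
    support[np.arange(mdp.k), pi.actions] = True
    return support


def soften(
    mdp: MDPModel,
    pi: Policy,
    p_greedy: float = 0.99,
    fallback_actions: np.ndarray | None = None,
) -> SoftenedPolicy:
    """Convenience wrapper producing the evaluation form of a learned policy."""
    return SoftenedPolicy(
        base=pi,
        available=_softening_support(mdp, pi),
        p_greedy=p_greedy,
        fallback_actions=fallback_actions,
    )


def calibration_curve(
    values: np.ndarray, died: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Observed mortality per policy-value bin.

    Equal-width bins over [−100, 100]; empty bins are omitted.  Higher policy
    values should map to lower observed mortality when the value scale is
    meaningful.
    """
    values = np.asarray(values, dtype=float)
    died = np.asarray(died, dtype=bool)
    edges = np.linspace(-100.0, 100.0, n_bins + 1)
    idx = np.clip(np.digitize(values, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            rows.append(
                {
                    "value_mid": 0.5 * (edges[b] + edges[b + 1]),
                    "mortality": float(died[mask].mean()),
                    "n": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)
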