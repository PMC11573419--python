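"""Tabular MDP estimation from assigned state/action sequences.

The MDP has ``k`` clinical states plus two absorbing states (survived = ``k``,
dead = ``k+1``).  Transition counts are tallied over observed one-step
transitions; cells observed fewer than ``threshold`` times (default 5) are
removed so the learned agent can only choose state-action pairs clinicians
used with some regularity, and the remainder is row-normalized into
``T[s, a, s']``.  The reward is terminal-only: +100 on entering the survived
state, −100 on entering the dead state, granted on the transition into the
absorbing state; absorbing states self-loop without further reward.

Count and probability tensors are stored for clinical source states only,
shape ``(k, 25, k + 2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .discretize import N_ACTIONS

REWARD_SURVIVE = 100.0
REWARD_DEATH = -100.0


@dataclass
class MDPModel:
    """Estimated finite MDP.

    ``counts`` are the post-filter transition counts; ``raw_counts`` keep the
    unfiltered tally (needed to estimate the empirical clinician policy).
    ``available`` flags (s, a) pairs with at least one retained transition;
    states with no available action fall back to a zero-reward self-loop and
    are excluded from policy improvement.
    """

    k: int
    counts: np.ndarray  # (k, A, k+2) post-filter
    raw_counts: np.ndarray  # (k, A, k+2) pre-filter
    T: np.ndarray  # (k, A, k+2); rows of unavailable pairs are 0
    d0: np.ndarray  # (k+2,)
    gamma: float = 0.99
    threshold: int = 5

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def n_states(self) -> int:
        return self.k + 2

    @property
    def n_actions(self) -> int:
        return self.counts.shape[1]

    @property
    def survived_state(self) -> int:
        return self.k

    @property
    def dead_state(self) -> int:
        return self.k + 1

    @property
    def available(self) -> np.ndarray:
        """(k, A) boolean mask of usable state-action pairs."""
        return self.counts.sum(axis=2) > 0

    def reward_vector(self) -> np.ndarray:
        """Reward on *entering* each state: ±100 at the terminals, else 0."""
        r = np.zeros(self.n_states)
        r[self.survived_state] = REWARD_SURVIVE
        r[self.dead_state] = REWARD_DEATH
        return r

    # --- serialization ----------------------------------------------------

    def write(self, prefix) -> None:
        """Sparse triplet text dump + JSON header."""
        prefix = Path(prefix)
        s, a, s2 = np.nonzero(self.counts)
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            fh.write("s\ta\ts_next\tcount\tprob\n")
            for i, j, l in zip(s, a, s2):
                fh.write(
                    f"{i}\t{j}\t{l}\t{int(self.counts[i, j, l])}\t"
                    f"{self.T[i, j, l]:.12g}\n"
                )
        header = {
            "k": self.k,
            "n_actions": int(self.n_actions),
            "gamma": self.gamma,
            "threshold": self.threshold,
            "d0": self.d0.tolist(),
        }
        prefix.with_suffix(".json").write_text(json.dumps(header))


def count_transitions(
    sequences: dict, actions: dict, k: int, n_actions: int = N_ACTIONS
) -> tuple[np.ndarray, np.ndarray]:
    """Tally one-step transition counts and the initial-state distribution.

    ``sequences[pid]`` is a state-id array ending in an absorbing id (``k`` or
    ``k+1``); ``actions[pid]`` holds one action per non-terminal step (length
    one less).  Raises if a sequence does not terminate or actions are
    misaligned.
    """
    counts = np.zeros((k, n_actions, k + 2), dtype=np.int64)
    d0 = np.zeros(k + 2)
    for pid, seq in sequences.items():
        seq = np.asarray(seq)
        acts = np.asarray(actions[pid])
        if len(seq) < 2 or seq[-1] < k:
            raise ValueError(f"sequence for {pid!r} does not end in a terminal state")
        if np.any(seq[:-1] >= k):
            raise ValueError(f"action taken on a terminal state for {pid!r}")
        if len(acts) != len(seq) - 1:
            raise ValueError(f"actions misaligned with states for {pid!r}")
        d0[seq[0]] += 1
        np.add.at(counts, (seq[:-1], acts, seq[1:]), 1)
    if d0.sum() > 0:
        d0 = d0 / d0.sum()
    return counts, d0


def filter_rare_transitions(counts: np.ndarray, threshold: int = 5) -> np.ndarray:
    """Zero out transition cells observed fewer than ``threshold`` times."""
    if threshold < 1:
        raise ValueError("threshold must be at least 1")
    out = counts.copy()
    out[out < threshold] = 0
    return out


def normalize(counts: np.ndarray) -> np.ndarray:
    """Row-normalize counts into transition probabilities.

    Rows of unavailable (s, a) pairs are left all-zero; at least one pair must
    survive filtering.
    """
    rowsum = counts.sum(axis=2, keepdims=True)
    if not np.any(rowsum):
        raise ValueError("no state-action pair survived filtering")
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(rowsum > 0, counts / np.maximum(rowsum, 1), 0.0)
    return T


def build_mdp(
    sequences: dict,
    actions: dict,
    k: int,
    gamma: float = 0.99,
    threshold: int = 5,
    n_actions: int = N_ACTIONS,
) -> MDPModel:
    """Counts → rare-transition filter → normalization, in one call."""
    raw, d0 = count_transitions(sequences, actions, k, n_actions)
    counts = filter_rare_transitions(raw, threshold)
    T = normalize(counts)
    return MDPModel(
        k=k,
        counts=counts,
        raw_counts=raw,
        T=T,
        d0=d0,
        gamma=gamma,
        threshold=threshold,
    )


def simulate_trajectories(
    mdp: MDPModel,
    policy_probs: np.ndarray,
    n: int,
    seed: int = 0,
    max_steps: int = 200,
) -> tuple[dict, dict]:
    """Roll out trajectories from the MDP under a stochastic policy.

    Starts are drawn from ``d0``; each episode follows ``policy_probs``
    (k × A rows over available actions) until absorption or ``max_steps``
    (episodes hitting the cap are truncated into the survived state so every
    sequence terminates).  Returns ``(sequences, actions)`` in the same form
    :func:`count_transitions` consumes.
    """
    rng = np.random.default_rng(seed)
    k = mdp.k
    cum_d0 = np.cumsum(mdp.d0[:k] / mdp.d0[:k].sum())
    cum_pi = np.cumsum(policy_probs, axis=1)
    cum_T = np.cumsum(mdp.T, axis=2)
    sequences, actions = {}, {}
    for i in range(n):
        s = int(np.searchsorted(cum_d0, rng.random()))
        seq, acts = [s], []
        for _ in range(max_steps):
            a = int(np.searchsorted(cum_pi[s], rng.random()))
            row_total = cum_T[s, a, -1]
            if row_total <= 0:  # unavailable pair: zero-reward self-loop
                s2 = s
            else:
                s2 = int(np.searchsorted(cum_T[s, a], rng.random() * row_total))
            seq.append(s2)
            acts.append(a)
            if s2 >= k:
                break
            s = s2
        else:
            seq.append(mdp.survived_state)
            acts.append(int(np.searchsorted(cum_pi[s], rng.random())))
        if len(seq) - 1 != len(acts):
            acts = acts[: len(seq) - 1]
        sequences[i] = np.asarray(seq)
        actions[i] = np.asarray(acts)
    return sequences, actions
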