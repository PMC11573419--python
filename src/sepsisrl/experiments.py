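"""Comparison protocol: repeated re-clustered trials across state
representations and benchmark policies.

One *trial* is a complete pass for a given feature set and cluster count:
feature reduction → k-means state model (the trial's seed drives only this
clustering) → action grid → MDP estimation on the training split → policy
iteration → weighted-importance-sampling evaluation on the held-out split.
Repeating trials with fresh clustering seeds produces the distribution of
mean policy values and 95%/99% lower bounds that the study design compares
across models; per-model "best" is the maximum over trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import (
    ActionDiscretizer,
    N_ACTIONS,
    StateDiscretizer,
    action_components,
    assign_states,
)
from .features import FeatureSetSpec, FeatureSetTransformer
from .mdp import build_mdp
from .ope import (
    SoftenedPolicy,
    bootstrap_bounds,
    evaluate_constrained_policies,
    soften,
    trajectories_from_sequences,
    wis_estimate,
)
from .solvers import Policy, estimate_clinician_policy, policy_iteration

logger = logging.getLogger("sepsisrl")

FEATURE_MODELS = ("FULL", "NO_LAB", "CARDIO", "BASELINE", "PCA80", "PCA15")
CONSTRAINED_MODELS = ("RAND", "NO_DRUGS", "NO_VASOPRESSORS", "NO_FLUID")
ALL_MODELS = FEATURE_MODELS + CONSTRAINED_MODELS + ("CLINICIAN",)


@dataclass
class ExperimentConfig:
    """Protocol settings for :func:`run_comparison`."""

    n_trials: int = 250
    k_values: tuple[int, ...] = (750, 250)
    models: tuple[str, ...] = ALL_MODELS
    gamma: float = 0.99
    transition_threshold: int = 5
    bootstrap_B: int = 2000
    p_greedy: float = 0.99
    master_seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.models:
            raise ValueError("models must be non-empty")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown model name(s): {sorted(unknown)}")


@dataclass
class TrialResult:
    """Summaries of one (model, k, trial) pass."""

    model: str
    trial: int
    k: int
    seed: int
    wis_estimate: float
    mean_policy_value: float
    lb95: float
    lb99: float
    clinician_value: float

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "trial": self.trial,
            "k": self.k,
            "seed": self.seed,
            "wis_estimate": self.wis_estimate,
            "mean_policy_value": self.mean_policy_value,
            "lb95": self.lb95,
            "lb99": self.lb99,
            "clinician_value": self.clinician_value,
        }


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [
        c
        for c in table.columns
        if c
        not in {"patient_id", "bin_index", "vaso_dose", "fluid_volume", "outcome", "split"}
    ]


def _prepare_log(
    table: pd.DataFrame,
    spec: FeatureSetSpec | str,
    k: int,
    seed: int,
    threshold: int,
    gamma: float,
):
    """Shared front half of a trial: states, actions, MDP, clinician policy.

    Returns everything downstream policies need.  The clinician policy is
    estimated from the unfiltered counts of the *whole* log (train and test)
    so every logged action has positive behavior probability in the
    importance ratios.
    """
    train = table[table.split == "train"]
    tf = FeatureSetTransformer(spec)
    cols = _feature_cols(table)
    tf.fit(train[cols])
    reduced = tf.transform(table[cols])
    red_cols = list(reduced.columns)
    reduced = pd.concat(
        [table[["patient_id", "bin_index", "vaso_dose", "fluid_volume", "outcome", "split"]], reduced],
        axis=1,
    )
    train_red = reduced[reduced.split == "train"]

    sm = StateDiscretizer(k=k, seed=seed).fit(train_red[red_cols].to_numpy(float))
    ag = ActionDiscretizer().fit(
        train.vaso_dose.to_numpy(), train.fluid_volume.to_numpy()
    )

    def seq_and_actions(sub: pd.DataFrame):
        seqs = assign_states(sub, sm, red_cols)
        acts = {}
        for pid, grp in sub.groupby("patient_id", sort=True):
            grp = grp.sort_values("bin_index")
            acts[pid] = ag.transform(
                grp.vaso_dose.to_numpy(), grp.fluid_volume.to_numpy()
            )
        return seqs, acts

    train_seqs, train_acts = seq_and_actions(train_red)
    test_red = reduced[reduced.split == "test"]
    test_seqs, test_acts = seq_and_actions(test_red)

    mdp = build_mdp(train_seqs, train_acts, k, gamma=gamma, threshold=threshold)
    all_counts = mdp.raw_counts.copy()
    # add test-split visits so the behavior policy covers every logged action
    from .mdp import count_transitions

    test_counts, _ = count_transitions(test_seqs, test_acts, k, mdp.n_actions)
    pi_c = estimate_clinician_policy(all_counts + test_counts)
    test_trajs = trajectories_from_sequences(test_seqs, test_acts, k)
    clin_majority = np.argmax((all_counts + test_counts).sum(axis=2), axis=1)
    return sm, ag, mdp, pi_c, test_trajs, clin_majority


def run_trial(
    table: pd.DataFrame,
    spec: FeatureSetSpec | str,
    k: int,
    seed: int,
    config: ExperimentConfig | None = None,
    trial: int = 0,
) -> TrialResult:
    """One full model pass; trial-to-trial variation comes from ``seed``."""
    config = config or ExperimentConfig()
    name = spec if isinstance(spec, str) else spec.name
    sm, ag, mdp, pi_c, test_trajs, clin_majority = _prepare_log(
        table, spec, k, seed, config.transition_threshold, config.gamma
    )
    pi_ai, _, _ = policy_iteration(mdp)
    target = soften(
        mdp, pi_ai, p_greedy=config.p_greedy, fallback_actions=clin_majority
    )
    res = bootstrap_bounds(
        test_trajs, target, pi_c, config.gamma, config.bootstrap_B, seed
    )
    clin = wis_estimate(test_trajs, pi_c, pi_c, config.gamma)
    logger.info(
        "trial model=%s k=%d seed=%d mean=%.3f lb95=%.3f lb99=%.3f",
        name, k, seed, res.bootstrap_mean, res.lb95, res.lb99,
    )
    return TrialResult(
        model=name,
        trial=trial,
        k=k,
        seed=seed,
        wis_estimate=res.estimate,
        mean_policy_value=res.bootstrap_mean,
        lb95=res.lb95,
        lb99=res.lb99,
        clinician_value=clin.estimate,
    )


def run_comparison(
    table: pd.DataFrame, config: ExperimentConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All (model, k) × trials; returns (trial table, per-model best table).

    Trial seeds derive deterministically from the master seed; the train/test
    split is held fixed (it is part of the input table), so trial-to-trial
    variability is driven by the clustering seed alone.
    """
    config = config or ExperimentConfig()
    ss = np.random.SeedSequence(config.master_seed)
    rows = []
    for k in config.k_values:
        seeds = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_trials)
        ]
        feature_specs = [m for m in config.models if m in FEATURE_MODELS]
        for name in feature_specs:
            for t, seed in enumerate(seeds):
                rows.append(
                    run_trial(table, name, k, seed, config, trial=t).as_row()
                )
        wanted_constrained = [m for m in config.models if m in CONSTRAINED_MODELS]
        if wanted_constrained or "CLINICIAN" in config.models:
            for t, seed in enumerate(seeds):
                sm, ag, mdp, pi_c, test_trajs, clin_majority = _prepare_log(
                    table, "FULL", k, seed, config.transition_threshold, config.gamma
                )
                clin = bootstrap_bounds(
                    test_trajs, pi_c, pi_c, config.gamma, config.bootstrap_B, seed
                )
                if wanted_constrained:
                    results = evaluate_constrained_policies(
                        mdp,
                        test_trajs,
                        pi_c,
                        config.gamma,
                        config.bootstrap_B,
                        seed,
                        config.p_greedy,
                        clin_majority,
                    )
                    for name in wanted_constrained:
                        r = results[name]
                        rows.append(
                            TrialResult(
                                model=name,
                                trial=t,
                                k=k,
                                seed=seed,
                                wis_estimate=r.estimate,
                                mean_policy_value=r.bootstrap_mean,
                                lb95=r.lb95,
                                lb99=r.lb99,
                                clinician_value=clin.estimate,
                            ).as_row()
                        )
                if "CLINICIAN" in config.models:
                    rows.append(
                        TrialResult(
                            model="CLINICIAN",
                            trial=t,
                            k=k,
                            seed=seed,
                            wis_estimate=clin.estimate,
                            mean_policy_value=clin.bootstrap_mean,
                            lb95=clin.lb95,
                            lb99=clin.lb99,
                            clinician_value=clin.estimate,
                        ).as_row()
                    )
    trials = pd.DataFrame(rows)
    best = (
        trials.groupby(["model", "k"])
        .agg(
            best_mean_policy_value=("mean_policy_value", "max"),
            best_lb95=("lb95", "max"),
            best_lb99=("lb99", "max"),
            median_mean_policy_value=("mean_policy_value", "median"),
            n_trials=("trial", "count"),
        )
        .reset_index()
    )
    return trials, best


def action_frequency_table(
    policy_probs: np.ndarray, state_visit_weights: np.ndarray
) -> np.ndarray:
    """5×5 (vaso bin × fluid bin) action frequencies under a policy.

    Frequencies are the visit-weighted average of the policy's action
    probabilities over states, normalized to sum to 1.
    """
    w = np.asarray(state_visit_weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("state visit weights must have positive total")
    freq_a = (w[:, None] * policy_probs).sum(axis=0) / w.sum()
    vaso, fluid = action_components(np.arange(policy_probs.shape[1]))
    table = np.zeros((5, 5))
    np.add.at(table, (vaso, fluid), freq_a)
    return table / table.sum()
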