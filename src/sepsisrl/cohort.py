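"""Synthetic septic ICU cohort generator.

Emulates the statistical structure of a sepsis cohort extracted from an EHR
database: 48 mixed-frequency variables on a 4-hour grid spanning 24 h before to
48 h after sepsis onset, sparse laboratory values, zero-inflated vasopressor and
IV-fluid doses, and 90-day mortality driven by a latent severity process that
responds to treatment.  The latent process is the known ground truth: it lets
tests check that a policy learned downstream recovers the latent-optimal
treatment, something impossible with real data.

Latent model
------------
Each patient carries a severity level ``z`` in ``0..n_latent_states-1``:
0 is absorbing recovery (the patient is discharged and exits observation as a
survivor), the top level is the pre-death state.  Per 4-h bin the patient
(1) emits features, (2) receives a dose pair chosen by a behavior policy,
(3) dies with probability ``mortality_base`` if at the top level, and
otherwise (4) transitions.  If the administered action equals the
latent-optimal action, the transition is replaced, with probability
``1 - exp(-treatment_effect)``, by a one-level improvement; with
``treatment_effect = 0`` dynamics are exactly the no-treatment baseline, so
outcomes are independent of actions.

Features are Gaussian emissions of the latent level plus a shared low-rank
factor term that induces the strong cross-variable correlation typical of ICU
data (a handful of physiological axes drive most variables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (
    BASELINE_FEATURES,
    CARDIO_FEATURES,
    FULL_FEATURES,
    LAB_FEATURES,
)

N_ACTIONS = 25
N_DOSE_BINS = 5

#: Reference lognormal dose distributions (median, sigma of log).  The
#: generator's internal action bins sit at the quartiles of these laws, so a
#: nonzero draw is uniform over bins 1..4 by construction.
VASO_MEDIAN, VASO_LOG_SD = 0.1, 0.9  # µg/kg/min
FLUID_MEDIAN, FLUID_LOG_SD = 250.0, 0.8  # mL per 4-h bin

# per-feature (baseline mean, sd) in native units; slope = latent effect in
# sd units per severity level
_FEATURE_MODEL: dict[str, tuple[float, float, float]] = {
    "heart_rate": (72.0, 9.0, 1.8),
    "systolic_bp": (128.0, 12.0, -1.6),
    "diastolic_bp": (74.0, 8.0, -1.3),
    "shock_index": (0.55, 0.10, 2.0),
    "spo2": (98.0, 1.5, -1.3),
    "mech_vent": (0.05, 0.18, 1.2),  # Bernoulli propensity, see _emit
    "gender": (0.5, 0.5, 0.0),
    "total_fluid_input": (500.0, 200.0, 0.0),
    "body_temperature": (37.0, 0.6, 0.0),
    "weight": (80.0, 15.0, 0.0),
    "readmission": (0.3, 0.46, 0.0),
    "age": (66.0, 14.0, 0.0),
    "elixhauser": (3.0, 2.0, 0.0),
    "sofa": (4.0, 2.5, 0.8),
    "gcs": (13.0, 2.5, -0.8),
    "respiratory_rate": (18.0, 4.0, 0.5),
    "mean_bp": (88.0, 10.0, -0.8),
    "urine_output": (120.0, 60.0, -0.5),
    "cumulative_balance": (1500.0, 1200.0, 0.3),
    "fio2": (0.35, 0.15, 0.5),
    "sedation": (0.2, 0.4, 0.3),
    "height": (170.0, 10.0, 0.0),
    "chloride": (104.0, 4.0, 0.0),
    "potassium": (4.1, 0.5, 0.2),
    "sodium": (139.0, 4.0, 0.1),
    "glucose": (130.0, 35.0, 0.3),
    "creatinine": (1.1, 0.5, 0.5),
    "bun": (22.0, 10.0, 0.4),
    "magnesium": (2.0, 0.3, 0.1),
    "calcium": (8.8, 0.7, -0.2),
    "ionized_calcium": (1.12, 0.08, -0.2),
    "co2": (24.0, 4.0, -0.3),
    "sgot": (45.0, 30.0, 0.3),
    "sgpt": (40.0, 28.0, 0.3),
    "total_bilirubin": (0.9, 0.6, 0.3),
    "albumin": (3.2, 0.5, -0.3),
    "hemoglobin": (10.8, 1.8, -0.2),
    "wbc": (11.0, 4.5, 0.4),
    "platelets": (220.0, 80.0, -0.3),
    "ptt": (35.0, 10.0, 0.3),
    "pt": (14.5, 3.0, 0.3),
    "inr": (1.3, 0.4, 0.3),
    "arterial_ph": (7.38, 0.05, -0.5),
    "pao2": (110.0, 35.0, -0.3),
    "paco2": (40.0, 7.0, 0.1),
    "lactate": (1.8, 1.0, 0.8),
    "base_excess": (-1.0, 3.5, -0.5),
    "bicarbonate": (23.0, 3.5, -0.5),
}

#: Features constant within a patient (demographics, admission-level values).
PATIENT_CONSTANT_FEATURES = frozenset(
    {"gender", "readmission", "age", "weight", "height", "elixhauser"}
)

_BINARY_FEATURES = frozenset({"gender", "readmission", "mech_vent"})

#: Number of shared latent factors, their variance relative to the
#: idiosyncratic noise, and their lag-1 autocorrelation.  Factors follow a
#: stationary AR(1) per patient: physiological axes drift slowly, so a stale
#: forward-filled lab still reflects the current state.  Chosen so the leading
#: ~25 principal components of the standardized 48-column matrix carry ~80% of
#: the variance, mimicking the collinearity of real ICU variables.
N_FACTORS = 12
FACTOR_VARIANCE_RATIO = 4.0
CARDIO_FACTOR_RATIO = 0.5  # cardio variables carry mostly severity signal
FACTOR_AR1 = 0.8


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    Parameters
    ----------
    n_patients : int
        Cohort size.
    seed : int
        Master seed; patient ``i`` draws from the independent substream
        ``(seed, i)`` so output is reproducible regardless of patient order.
    n_bins_max : int
        Trajectory horizon in 4-h bins (default 18 = −24 h..+48 h).
    feature_names : tuple of 48 unique names
        Must contain the cardiorespiratory and reference-baseline sets.
    lab_features : tuple of names
        Subset of ``feature_names`` deleted per bin with ``lab_missing_prob``.
    lab_missing_prob : float
        Per-bin deletion probability of each lab value (labs are sparse).
    dose_zero_prob_vaso, dose_zero_prob_fluid : float
        Zero-inflation of the marginal dose laws (clinicians give no
        vasopressor most of the time; fluids more often).
    treatment_effect : float
        Strength of the survival benefit of latent-appropriate dosing;
        improvement boost is ``1 - exp(-treatment_effect)``.
    mortality_base : float
        Per-bin death probability while at the worst severity level.
    """

    n_patients: int
    seed: int
    n_bins_max: int = 18
    feature_names: tuple[str, ...] = FULL_FEATURES
    lab_features: tuple[str, ...] = LAB_FEATURES
    lab_missing_prob: float = 0.7
    dose_zero_prob_vaso: float = 0.7
    dose_zero_prob_fluid: float = 0.25
    treatment_effect: float = 1.0
    mortality_base: float = 0.4

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        if self.n_bins_max < 2:
            raise ValueError("n_bins_max must be at least 2")
        names = tuple(self.feature_names)
        if len(names) != 48 or len(set(names)) != 48:
            raise ValueError("feature_names must hold exactly 48 unique names")
        missing = [f for f in CARDIO_FEATURES + BASELINE_FEATURES if f not in names]
        if missing:
            raise ValueError(f"required feature(s) absent: {missing}")
        if set(CARDIO_FEATURES) & set(BASELINE_FEATURES):
            raise ValueError("cardio and baseline sets must be disjoint")
        if not set(self.lab_features) <= set(names):
            raise ValueError("lab_features must be a subset of feature_names")
        for p in (
            self.lab_missing_prob,
            self.dose_zero_prob_vaso,
            self.dose_zero_prob_fluid,
            self.mortality_base,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.treatment_effect < 0:
            raise ValueError("treatment_effect must be nonnegative")


@dataclass(frozen=True)
class LatentGroundTruth:
    """The hidden severity process and its optimal treatment map.

    ``latent_transition_base`` is the no-treatment severity dynamics (rows sum
    to 1); level 0 is absorbing recovery.  ``optimal_action_by_latent`` maps
    each level to the action id (``5*vaso_bin + fluid_bin``) that triggers the
    treatment-effect improvement boost.  ``emission_means``/``emission_sds``
    are latent-by-feature Gaussian emission parameters; ``factor_loadings``
    adds shared cross-feature variation.
    """

    n_latent_states: int
    latent_transition_base: np.ndarray  # (L, L)
    optimal_action_by_latent: np.ndarray  # (L,)
    emission_means: np.ndarray  # (L, F)
    emission_sds: np.ndarray  # (L, F)
    factor_loadings: np.ndarray  # (F, N_FACTORS)
    start_dist: np.ndarray  # (L,)

    def __post_init__(self):
        L = self.n_latent_states
        P = np.asarray(self.latent_transition_base, dtype=float)
        if P.shape != (L, L):
            raise ValueError("latent_transition_base must be (L, L)")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("latent_transition_base rows must sum to 1")
        if np.any(P < 0):
            raise ValueError("latent_transition_base must be nonnegative")
        a = np.asarray(self.optimal_action_by_latent)
        if a.shape != (L,):
            raise ValueError("optimal_action_by_latent must cover every level")
        if np.any((a < 0) | (a >= N_ACTIONS)):
            raise ValueError("optimal actions must lie in [0, 25)")
        if self.emission_means.shape != self.emission_sds.shape:
            raise ValueError("emission means/sds shapes differ")
        if self.emission_means.shape[0] != L:
            raise ValueError("emission matrices must have one row per level")
        if not np.isclose(self.start_dist.sum(), 1.0, atol=1e-12):
            raise ValueError("start_dist must sum to 1")

    @classmethod
    def default(
        cls,
        feature_names: tuple[str, ...] = FULL_FEATURES,
        n_latent_states: int = 5,
        informative: str = "all",
        truth_seed: int = 0,
    ) -> "LatentGroundTruth":
        """Build the standard ground truth.

        ``informative="all"`` uses the clinically shaped latent slopes of
        every variable; ``informative="cardio_only"`` zeroes every slope
        except the six cardiorespiratory ones, producing a cohort whose
        outcome carries information only through those features.
        """
        if informative not in {"all", "cardio_only"}:
            raise ValueError("informative must be 'all' or 'cardio_only'")
        L = n_latent_states
        F = len(feature_names)
        means = np.empty((L, F))
        sds = np.empty((L, F))
        for j, name in enumerate(feature_names):
            base, sd, slope = _FEATURE_MODEL.get(name, (0.0, 1.0, 0.0))
            if informative == "cardio_only" and name not in CARDIO_FEATURES:
                slope = 0.0
            means[:, j] = base + slope * sd * np.arange(L)
            sds[:, j] = sd
        # no-treatment dynamics: sticky with a drift toward deterioration;
        # level 0 absorbs (recovery)
        P = np.zeros((L, L))
        P[0, 0] = 1.0
        # untreated sepsis deteriorates quickly: strong upward drift
        for z in range(1, L):
            P[z, z] = 0.55
            P[z, min(z + 1, L - 1)] += 0.35
            P[z, z - 1] += 0.10
        P /= P.sum(axis=1, keepdims=True)
        # treatment escalates with severity: both the vasopressor and the
        # fluid bin equal the severity level (the action-grid diagonal);
        # level 0 is discharge-bound and needs no drug
        optimal = np.array([0, 6, 12, 18, 24])[:L]
        rng = np.random.default_rng(truth_seed)
        raw = rng.normal(size=(F, N_FACTORS))
        # scale loadings per feature: cardiorespiratory variables carry their
        # own severity-driven signal (low factor share); the rest co-move
        # strongly along shared physiological axes
        ratio = np.array(
            [
                CARDIO_FACTOR_RATIO if n in CARDIO_FEATURES else FACTOR_VARIANCE_RATIO
                for n in feature_names
            ]
        )
        row_norm = np.sqrt((raw**2).sum(axis=1, keepdims=True))
        loadings = raw / row_norm * np.sqrt(ratio)[:, None] * sds[0][:, None]
        # a sepsis cohort presents with at least moderate organ dysfunction:
        # nobody starts recovered (level 0 = discharge) or merely mild
        # (level 1 is a transient stage passed through during recovery)
        start = np.zeros(L)
        if L > 2:
            start[2:] = [0.35, 0.40, 0.25][: L - 2]
            start[2] += 1.0 - start.sum()
        else:
            start[-1] = 1.0
        return cls(
            n_latent_states=L,
            latent_transition_base=P,
            optimal_action_by_latent=optimal,
            emission_means=means,
            emission_sds=sds,
            factor_loadings=loadings,
            start_dist=start,
        )


@dataclass
class RawCohort:
    """Generator output, tidy tables mirroring an EHR extract.

    ``observations`` is long format (patient_id, bin_index, feature_name,
    value) with missing entries simply absent; ``latents`` records the hidden
    severity per bin and exists only so tests can compare learned policies
    with the ground truth — no downstream stage may read it.
    """

    observations: pd.DataFrame
    doses: pd.DataFrame
    outcomes: pd.DataFrame
    events: pd.DataFrame
    latents: pd.DataFrame | None = None

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(out / "observations.csv", index=False)
        self.doses.to_csv(out / "doses.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        if self.latents is not None:
            self.latents.to_csv(out / "latents.csv", index=False)

    @classmethod
    def read(cls, in_dir) -> "RawCohort":
        from pathlib import Path

        d = Path(in_dir)
        lat = d / "latents.csv"
        return cls(
            observations=pd.read_csv(d / "observations.csv"),
            doses=pd.read_csv(d / "doses.csv"),
            outcomes=pd.read_csv(d / "outcomes.csv"),
            events=pd.read_csv(d / "events.csv"),
            latents=pd.read_csv(lat) if lat.exists() else None,
        )


# --- dose machinery -------------------------------------------------------

from scipy.special import ndtri  # noqa: E402  (fast scalar normal quantile)


def _lognorm_ppf(median: float, log_sd: float, u) -> float:
    return median * np.exp(log_sd * ndtri(u))


_VASO_Q = np.array([_lognorm_ppf(VASO_MEDIAN, VASO_LOG_SD, q) for q in (0.25, 0.5, 0.75)])
_FLUID_Q = np.array(
    [_lognorm_ppf(FLUID_MEDIAN, FLUID_LOG_SD, q) for q in (0.25, 0.5, 0.75)]
)


def reference_dose_quartiles() -> tuple[np.ndarray, np.ndarray]:
    """Quartiles (q25, q50, q75) of the nonzero vaso and fluid dose laws."""
    return _VASO_Q.copy(), _FLUID_Q.copy()


def _dose_in_bin(median: float, log_sd: float, b: int, u: float) -> float:
    """Inverse-CDF draw from the quartile slice ``b`` (1..4) of the dose law."""
    return float(_lognorm_ppf(median, log_sd, (b - 1 + u) / 4.0))


def _dose_to_bin(quartiles: np.ndarray, dose: float) -> int:
    if dose <= 0:
        return 0
    return int(np.searchsorted(quartiles, dose, side="left")) + 1


BEHAVIOR_MODES = ("eps_optimal", "always_optimal", "never_treat", "marginal")


def _behavior_step(
    mode: str,
    p_optimal: float,
    optimal_action: int,
    config: CohortConfig,
    u: np.ndarray,
) -> tuple[int, float, float]:
    """One behavior-policy draw: returns (action id, vaso dose, fluid dose).

    ``u`` is a vector of 5 uniforms from the patient substream.
    """
    take_optimal = mode == "always_optimal" or (
        mode == "eps_optimal" and u[0] < p_optimal
    )
    if mode == "never_treat":
        return 0, 0.0, 0.0
    if take_optimal:
        # standard titration increments: the midpoint-quantile dose of the
        # target bin, the discrete levels clinicians actually order
        vb, fb = divmod(optimal_action, N_DOSE_BINS)
        vaso = 0.0 if vb == 0 else _dose_in_bin(VASO_MEDIAN, VASO_LOG_SD, vb, 0.5)
        fluid = 0.0 if fb == 0 else _dose_in_bin(FLUID_MEDIAN, FLUID_LOG_SD, fb, 0.5)
        return optimal_action, vaso, fluid
    # exploration / marginal: zero-inflated lognormal per treatment
    vaso = (
        0.0
        if u[1] < config.dose_zero_prob_vaso
        else _lognorm_ppf(VASO_MEDIAN, VASO_LOG_SD, u[3])
    )
    fluid = (
        0.0
        if u[2] < config.dose_zero_prob_fluid
        else _lognorm_ppf(FLUID_MEDIAN, FLUID_LOG_SD, u[4])
    )
    action = N_DOSE_BINS * _dose_to_bin(_VASO_Q, vaso) + _dose_to_bin(_FLUID_Q, fluid)
    return action, vaso, fluid


# --- main generator -------------------------------------------------------


def generate_cohort(
    config: CohortConfig,
    truth: LatentGroundTruth | None = None,
    behavior: str = "eps_optimal",
    p_optimal: float = 0.5,
) -> RawCohort:
    """Simulate a cohort under a behavior (data-generating) policy.

    ``behavior`` selects how the clinician stand-in doses:

    - ``eps_optimal`` (default): latent-optimal action with probability
      ``p_optimal``, otherwise a zero-inflated lognormal marginal draw —
      imperfect clinicians with guaranteed overlap over all 25 actions.
    - ``always_optimal`` / ``never_treat``: degenerate policies for
      treatment-effect calibration tests.
    - ``marginal``: pure zero-inflated draws, independent of the latent state.

    Deterministic given ``(config, truth, behavior, p_optimal)``; patient ``i``
    uses the substream ``(config.seed, i)``.
    """
    if truth is None:
        truth = LatentGroundTruth.default(config.feature_names)
    if behavior not in BEHAVIOR_MODES:
        raise ValueError(f"behavior must be one of {BEHAVIOR_MODES}")
    F = len(config.feature_names)
    if truth.emission_means.shape[1] != F:
        raise ValueError(
            "truth emission matrices inconsistent with config feature count"
        )
    names = np.asarray(config.feature_names)
    lab_mask = np.isin(names, np.asarray(config.lab_features))
    const_mask = np.array([n in PATIENT_CONSTANT_FEATURES for n in names])
    binary_mask = np.array([n in _BINARY_FEATURES for n in names])
    name_to_col = {n: j for j, n in enumerate(names)}
    boost = 1.0 - np.exp(-config.treatment_effect)
    L = truth.n_latent_states
    worst = L - 1
    cum_base = np.cumsum(truth.latent_transition_base, axis=1)

    obs_frames, dose_rows, out_rows, event_rows, latent_rows = [], [], [], [], []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        nb = config.n_bins_max
        z = int(np.searchsorted(np.cumsum(truth.start_dist), rng.random()))
        eps = rng.normal(size=(nb, F))
        eta = rng.normal(size=(nb, N_FACTORS))
        for t_ in range(1, nb):  # stationary AR(1) factor paths
            eta[t_] = FACTOR_AR1 * eta[t_ - 1] + np.sqrt(1 - FACTOR_AR1**2) * eta[t_]
        u_beh = rng.random(size=(nb, 5))
        u_dyn = rng.random(size=(nb, 3))
        u_bin = rng.random(size=(nb, F))
        lab_del = rng.random(size=(nb, F))
        const_eps = eps[0].copy()

        died = False
        zs, vasos, fluids, actions = [], [], [], []
        values = np.empty((nb, F))
        t = 0
        for t in range(nb):
            mu = truth.emission_means[z] + truth.factor_loadings @ eta[t]
            row = mu + truth.emission_sds[z] * eps[t]
            row[const_mask] = (
                truth.emission_means[z][const_mask]
                + truth.emission_sds[z][const_mask] * const_eps[const_mask]
            )
            # binary features: the continuous value is a propensity
            p_bin = np.clip(row[binary_mask], 0.0, 1.0)
            row[binary_mask] = (u_bin[t][binary_mask] < p_bin).astype(float)
            values[t] = row
            a_star = int(truth.optimal_action_by_latent[z])
            a, vaso, fluid = _behavior_step(
                behavior, p_optimal, a_star, config, u_beh[t]
            )
            zs.append(z)
            actions.append(a)
            vasos.append(vaso)
            fluids.append(fluid)
            if z == worst and u_dyn[t, 0] < config.mortality_base:
                died = True
                break
            if a == a_star and z > 0 and u_dyn[t, 1] < boost:
                z = z - 1
            else:
                z = int(np.searchsorted(cum_base[z], u_dyn[t, 2]))
            if z == 0:  # absorbing recovery: discharged, exits observation
                break
        n_obs_bins = t + 1
        values = values[:n_obs_bins]

        keep = np.ones((n_obs_bins, F), dtype=bool)
        keep[:, lab_mask] = lab_del[:n_obs_bins, lab_mask] >= config.lab_missing_prob
        bi, fj = np.nonzero(keep)
        obs_frames.append(
            pd.DataFrame(
                {
                    "patient_id": i,
                    "bin_index": bi,
                    "feature_name": names[fj],
                    "value": values[bi, fj],
                }
            )
        )
        for t_, (v, fl) in enumerate(zip(vasos, fluids)):
            dose_rows.append((i, t_, v, fl))
        for t_, (z_, a_) in enumerate(zip(zs, actions)):
            latent_rows.append((i, t_, z_, a_))

        age = float(values[0][name_to_col["age"]]) if "age" in name_to_col else 65.0
        out_rows.append((i, int(died), True, True, age))

        record_end = 4.0 * n_obs_bins
        event_rows.append((i, 24.0, "micro_sample"))
        if rng.random() < 0.5:
            event_rows.append((i, 24.0 + 1 + 47 * rng.random(), "antibiotic"))
        else:
            # antibiotic first, sampling follows within 24 h; onset is still
            # the earliest event of the pair, so shift both to keep onset=24
            event_rows[-1] = (i, 24.0 + 1 + 19 * rng.random(), "micro_sample")
            event_rows.append((i, 24.0, "antibiotic"))
        for t_, v in enumerate(vasos):
            if v > 0:
                event_rows.append((i, 4.0 * t_ + 2.0, "vaso_admin"))
        event_rows.append((i, record_end, "record_end"))
        if died:
            event_rows.append((i, record_end + 12.0 * rng.random(), "death_time"))

    observations = (
        pd.concat(obs_frames, ignore_index=True)
        if obs_frames
        else pd.DataFrame(
            columns=["patient_id", "bin_index", "feature_name", "value"]
        )
    )
    doses = pd.DataFrame(
        dose_rows, columns=["patient_id", "bin_index", "vaso_dose", "fluid_volume"]
    )
    outcomes = pd.DataFrame(
        out_rows,
        columns=[
            "patient_id",
            "died_90d",
            "outcome_documented",
            "fluids_documented",
            "age",
        ],
    )
    events = pd.DataFrame(
        event_rows, columns=["patient_id", "event_time", "event_type"]
    )
    latents = pd.DataFrame(
        latent_rows, columns=["patient_id", "bin_index", "latent", "action"]
    )
    return RawCohort(observations, doses, outcomes, events, latents)


def generate_events_for_onset(
    config: CohortConfig,
    seed: int,
    proportions: tuple[float, float, float] = (0.4, 0.4, 0.2),
) -> pd.DataFrame:
    """Emit antibiotic / microbiological-sampling event pairs for onset tests.

    Three pair geometries in the given proportions: (1) sampling first with
    the antibiotic within 72 h (qualifies), (2) antibiotic first with sampling
    within 24 h (qualifies), (3) sampling first with the antibiotic beyond
    72 h (does not qualify).
    """
    if not np.isclose(sum(proportions), 1.0):
        raise ValueError("proportions must sum to 1")
    rows = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([seed, i])
        case = int(rng.choice(3, p=list(proportions)))
        t0 = 10.0
        if case == 0:
            rows.append((i, t0, "micro_sample"))
            rows.append((i, t0 + 1 + 71 * rng.random(), "antibiotic"))
        elif case == 1:
            rows.append((i, t0, "antibiotic"))
            rows.append((i, t0 + 1 + 23 * rng.random(), "micro_sample"))
        else:
            rows.append((i, t0, "micro_sample"))
            rows.append((i, t0 + 73 + 48 * rng.random(), "antibiotic"))
    return pd.DataFrame(rows, columns=["patient_id", "event_time", "event_type"])
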