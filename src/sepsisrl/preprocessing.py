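"""Cohort rules and temporal harmonization of raw EHR-style tables.

Turns the tidy generator output (or any table of the same schema) into a wide
trajectory table: one row per patient × 4-hour bin, a complete 48-column
feature vector, the dose pair, the 90-day outcome, and a train/test flag.

Pipeline order: sepsis-onset identification → exclusions → treatment-withdrawal
filter → binning/aggregation → physiological capping → patient-level split →
imputation (zero-order hold, leading back-fill, training-median fallback).
The split precedes imputation so fallback medians come from training patients
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import RawCohort
from .features import FULL_FEATURES

#: Default cap bounds (native units) for variables with well-known
#: physiological ranges; other variables are left uncapped unless configured.
DEFAULT_CAP_BOUNDS: dict[str, tuple[float, float]] = {
    "heart_rate": (20.0, 220.0),
    "systolic_bp": (40.0, 250.0),
    "diastolic_bp": (20.0, 160.0),
    "mean_bp": (30.0, 180.0),
    "shock_index": (0.1, 3.0),
    "spo2": (0.0, 100.0),
    "body_temperature": (32.0, 42.0),
    "respiratory_rate": (4.0, 60.0),
    "weight": (30.0, 250.0),
    "height": (120.0, 220.0),
    "fio2": (0.21, 1.0),
    "gcs": (3.0, 15.0),
    "arterial_ph": (6.8, 7.8),
    "spo2_": (0.0, 100.0),
}

#: Flow-like variables accumulate within a bin (sums); everything else is a
#: level and is averaged.
DEFAULT_SUM_FEATURES: tuple[str, ...] = (
    "total_fluid_input",
    "urine_output",
)


@dataclass
class PreprocessConfig:
    """Binning, capping, aggregation and split settings.

    ``aggregation`` maps each feature to ``"mean"`` or ``"sum"``; features
    absent from the mapping raise a configuration error at binning time.
    """

    bin_hours: int = 4
    window_before_onset_h: int = 24
    window_after_onset_h: int = 48
    cap_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CAP_BOUNDS)
    )
    aggregation: dict[str, str] = field(
        default_factory=lambda: {
            f: ("sum" if f in DEFAULT_SUM_FEATURES else "mean")
            for f in FULL_FEATURES
        }
    )
    train_fraction: float = 0.8
    split_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        for f, (lo, hi) in self.cap_bounds.items():
            if not lo < hi:
                raise ValueError(f"cap bounds for {f!r} must satisfy low < high")
        bad = {v for v in self.aggregation.values()} - {"mean", "sum"}
        if bad:
            raise ValueError(f"aggregation rules must be mean/sum, got {bad}")

    @property
    def n_bins(self) -> int:
        return (self.window_before_onset_h + self.window_after_onset_h) // self.bin_hours


# --- cohort rules ---------------------------------------------------------


def identify_sepsis_onset(events: pd.DataFrame) -> dict:
    """Suspected-infection (sepsis-3 style) onset per patient, or ``None``.

    A patient qualifies if (a) a microbiological sampling precedes an
    antibiotic administration given no later than 72 h after it, or (b) a
    sampling occurs within 24 h after a previous antibiotic.  Onset is the
    earliest event of the earliest qualifying pair.  The rule is insensitive
    to row order.
    """
    onsets: dict = {}
    for pid, grp in events.groupby("patient_id"):
        samples = np.sort(
            grp.loc[grp.event_type == "micro_sample", "event_time"].to_numpy(float)
        )
        abx = np.sort(
            grp.loc[grp.event_type == "antibiotic", "event_time"].to_numpy(float)
        )
        best = None
        for s in samples:
            for a in abx:
                qualifies = (s < a <= s + 72.0) or (a < s <= a + 24.0)
                if qualifies:
                    t = min(s, a)
                    best = t if best is None else min(best, t)
        onsets[pid] = best
    return onsets


def apply_exclusions(raw: RawCohort, onsets: dict) -> RawCohort:
    """Retain adult patients with a qualifying onset and documented outcome
    and fluid administration."""
    out = raw.outcomes
    keep = out.patient_id.map(lambda p: onsets.get(p) is not None)
    keep &= out.age >= 18.0
    keep &= out.outcome_documented.astype(bool)
    keep &= out.fluids_documented.astype(bool)
    kept_ids = set(out.loc[keep, "patient_id"])
    return _subset(raw, kept_ids)


def apply_withdrawal_filter(raw: RawCohort) -> RawCohort:
    """Drop patients whose treatment was withdrawn.

    Withdrawal means all three of: death within 24 h of the end of data
    recording; no vasopressor administration during the final 24 h recorded;
    at least one vasopressor administration earlier.
    """
    ev = raw.events
    kept_ids = set(raw.outcomes.patient_id)
    for pid, grp in ev.groupby("patient_id"):
        ends = grp.loc[grp.event_type == "record_end", "event_time"]
        deaths = grp.loc[grp.event_type == "death_time", "event_time"]
        if ends.empty or deaths.empty:
            continue
        end = float(ends.min())
        death = float(deaths.min())
        vaso = grp.loc[grp.event_type == "vaso_admin", "event_time"].to_numpy(float)
        died_soon = death <= end + 24.0
        no_recent_vaso = not np.any((vaso > end - 24.0) & (vaso <= end))
        earlier_vaso = np.any(vaso <= end - 24.0)
        if died_soon and no_recent_vaso and earlier_vaso:
            kept_ids.discard(pid)
    return _subset(raw, kept_ids)


def _subset(raw: RawCohort, kept_ids: set) -> RawCohort:
    def f(df):
        return df[df.patient_id.isin(kept_ids)].reset_index(drop=True)

    return RawCohort(
        observations=f(raw.observations),
        doses=f(raw.doses),
        outcomes=f(raw.outcomes),
        events=f(raw.events),
        latents=None if raw.latents is None else f(raw.latents),
    )


# --- temporal harmonization ----------------------------------------------


def bin_and_aggregate(
    raw: RawCohort, onsets: dict, config: PreprocessConfig
) -> pd.DataFrame:
    """Aggregate observations into 4-h bins over the onset-centred window.

    Bin 0 covers ``[onset − 24 h, onset − 20 h)``.  Observations may carry
    either a precomputed ``bin_index`` or an absolute ``time_h`` column; in
    the latter case bins are derived from each patient's onset.  Within a bin,
    multiple values of one variable are averaged or summed according to the
    variable's declared type.  Returns a wide table with missing entries (NaN)
    where a variable was never observed in a bin.
    """
    obs = raw.observations.copy()
    features = sorted(obs.feature_name.unique())
    missing_rules = [f for f in features if f not in config.aggregation]
    if missing_rules:
        raise ValueError(f"no aggregation rule declared for: {missing_rules}")

    if "time_h" in obs.columns and "bin_index" not in obs.columns:
        onset = obs.patient_id.map(onsets)
        rel = obs.time_h - (onset - config.window_before_onset_h)
        obs["bin_index"] = np.floor(rel / config.bin_hours).astype(int)
    obs = obs[(obs.bin_index >= 0) & (obs.bin_index < config.n_bins)]

    rule = obs.feature_name.map(config.aggregation)
    parts = []
    for how in ("mean", "sum"):
        sub = obs[rule == how]
        if len(sub):
            parts.append(
                sub.groupby(["patient_id", "bin_index", "feature_name"])["value"]
                .agg(how)
                .unstack("feature_name")
            )
    wide = pd.concat(parts, axis=1).sort_index(axis=1) if parts else pd.DataFrame()

    doses = raw.doses[
        (raw.doses.bin_index >= 0) & (raw.doses.bin_index < config.n_bins)
    ]
    # vasopressor is a rate -> mean within bin; fluid is a volume -> sum
    agg = doses.groupby(["patient_id", "bin_index"]).agg(
        vaso_dose=("vaso_dose", "mean"), fluid_volume=("fluid_volume", "sum")
    )
    wide = agg.join(wide, how="outer") if len(wide) else agg
    wide = wide.reset_index()
    out = raw.outcomes.set_index("patient_id")
    wide["outcome"] = (
        wide.patient_id.map(out.died_90d).map({0: "survived", 1: "died"})
    )
    front = ["patient_id", "bin_index"]
    feat_cols = [c for c in wide.columns if c not in front + ["vaso_dose", "fluid_volume", "outcome"]]
    wide = wide[front + feat_cols + ["vaso_dose", "fluid_volume", "outcome"]]
    return wide.sort_values(front).reset_index(drop=True)


def cap_values(table: pd.DataFrame, config: PreprocessConfig) -> pd.DataFrame:
    """Clamp each configured feature into its plausible physiological range."""
    table = table.copy()
    for f, (lo, hi) in config.cap_bounds.items():
        if f in table.columns:
            table[f] = table[f].clip(lo, hi)
    return table


def split_train_test(table: pd.DataFrame, config: PreprocessConfig) -> pd.DataFrame:
    """Assign each patient (never individual bins) to train or test."""
    pids = np.sort(table.patient_id.unique())
    if len(pids) < 5:
        raise ValueError("need at least 5 patients to split")
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(pids)
    n_train = int(round(config.train_fraction * len(pids)))
    train_ids = set(perm[:n_train])
    table = table.copy()
    table["split"] = np.where(
        table.patient_id.isin(train_ids), "train", "test"
    )
    return table


def impute(
    table: pd.DataFrame, feature_cols: list[str] | None = None
) -> pd.DataFrame:
    """Fill missing feature values; idempotent.

    Per patient and feature: zero-order hold (carry the last observed value
    forward), then back-fill leading gaps from the first observation.  A
    feature never observed for a patient is filled with the training-cohort
    median (all-cohort median when no split column is present).  A feature
    observed nowhere in the cohort is a data error.
    """
    table = table.copy().sort_values(["patient_id", "bin_index"])
    if feature_cols is None:
        feature_cols = [
            c
            for c in table.columns
            if c
            not in {"patient_id", "bin_index", "vaso_dose", "fluid_volume", "outcome", "split"}
        ]
    never = [f for f in feature_cols if table[f].isna().all()]
    if never:
        raise ValueError(f"feature(s) observed nowhere in the cohort: {never}")
    g = table.groupby("patient_id")[feature_cols]
    filled = g.ffill()
    filled = filled.groupby(table.patient_id).bfill()
    ref = table if "split" not in table.columns else table[table.split == "train"]
    medians = ref[feature_cols].median()
    table[feature_cols] = filled.fillna(medians)
    table[["vaso_dose", "fluid_volume"]] = table[
        ["vaso_dose", "fluid_volume"]
    ].fillna(0.0)
    return table.reset_index(drop=True)


def preprocess(
    raw: RawCohort, config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Full pipeline from raw tables to an imputed, split trajectory table."""
    config = config or PreprocessConfig()
    onsets = identify_sepsis_onset(raw.events)
    raw = apply_exclusions(raw, onsets)
    raw = apply_withdrawal_filter(raw)
    table = bin_and_aggregate(raw, onsets, config)
    table = cap_values(table, config)
    table = split_train_test(table, config)
    return impute(table)
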