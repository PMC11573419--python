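"""Cohort rules, binning, capping, imputation and the split."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_events
from sepsisrl.cohort import RawCohort
from sepsisrl.preprocessing import (
    PreprocessConfig,
    apply_exclusions,
    apply_withdrawal_filter,
    bin_and_aggregate,
    cap_values,
    identify_sepsis_onset,
    impute,
    split_train_test,
)


def _raw(observations=None, doses=None, outcomes=None, events=None):
    empty_obs = pd.DataFrame(
        columns=["patient_id", "bin_index", "feature_name", "value"]
    )
    empty_doses = pd.DataFrame(
        columns=["patient_id", "bin_index", "vaso_dose", "fluid_volume"]
    )
    empty_out = pd.DataFrame(
        columns=[
            "patient_id",
            "died_90d",
            "outcome_documented",
            "fluids_documented",
            "age",
        ]
    )
    return RawCohort(
        observations=observations if observations is not None else empty_obs,
        doses=doses if doses is not None else empty_doses,
        outcomes=outcomes if outcomes is not None else empty_out,
        events=events if events is not None else make_events([]),
    )


class TestOnset:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            # sampling first, antibiotic 30 h later (<=72 h): onset = sampling
            ([(0, 10, "micro_sample"), (0, 40, "antibiotic")], 10.0),
            # antibiotic first, sampling 10 h later (<=24 h): onset = antibiotic
            ([(0, 10, "antibiotic"), (0, 20, "micro_sample")], 10.0),
            # antibiotic more than 72 h after sampling: no onset
            ([(0, 0, "micro_sample"), (0, 100, "antibiotic")], None),
            # sampling more than 24 h after antibiotic: no onset
            ([(0, 0, "antibiotic"), (0, 30, "micro_sample")], None),
        ],
    )
    def test_worked_examples(self, rows, expected):
        assert identify_sepsis_onset(make_events(rows)).get(0) == expected

    def test_row_order_insensitive(self):
        rows = [
            (0, 40, "antibiotic"),
            (0, 10, "micro_sample"),
            (1, 5, "antibiotic"),
            (1, 12, "micro_sample"),
            (2, 50, "micro_sample"),
        ]
        base = identify_sepsis_onset(make_events(rows))
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = make_events(rows).sample(frac=1, random_state=rng.integers(1e6))
            assert identify_sepsis_onset(shuffled) == base

    def test_earliest_qualifying_pair_wins(self):
        rows = [
            (0, 50, "micro_sample"),
            (0, 60, "antibiotic"),
            (0, 5, "micro_sample"),
            (0, 30, "antibiotic"),
        ]
        assert identify_sepsis_onset(make_events(rows))[0] == 5.0


class TestExclusions:
    def _outcomes(self, **over):
        row = dict(
            patient_id=0,
            died_90d=0,
            outcome_documented=True,
            fluids_documented=True,
            age=50.0,
        )
        row.update(over)
        return pd.DataFrame([row])

    def test_age_threshold_boundary(self):
        onsets = {0: 5.0}
        assert apply_exclusions(
            _raw(outcomes=self._outcomes(age=17.9)), onsets
        ).outcomes.empty
        assert (
            len(apply_exclusions(_raw(outcomes=self._outcomes(age=18.0)), onsets).outcomes)
            == 1
        )

    def test_undocumented_outcome_excluded(self):
        out = self._outcomes(outcome_documented=False)
        assert apply_exclusions(_raw(outcomes=out), {0: 5.0}).outcomes.empty

    def test_all_qualifying_cohort_is_identity(self):
        out = pd.concat([self._outcomes(patient_id=i) for i in range(10)])
        onsets = {i: 1.0 for i in range(10)}
        assert len(apply_exclusions(_raw(outcomes=out.reset_index(drop=True)), onsets).outcomes) == 10

    def test_no_onset_excluded(self):
        assert apply_exclusions(_raw(outcomes=self._outcomes()), {0: None}).outcomes.empty


class TestWithdrawal:
    def _cohort(self, events, died=1):
        out = pd.DataFrame(
            [dict(patient_id=0, died_90d=died, outcome_documented=True,
                  fluids_documented=True, age=60.0)]
        )
        return _raw(outcomes=out, events=make_events(events))

    def test_withdrawn_patient_excluded(self):
        # died 10 h after record end, last vasopressor 30 h before end,
        # with an earlier administration: all three clauses hold
        ev = [(0, 100, "record_end"), (0, 110, "death_time"), (0, 70, "vaso_admin")]
        assert apply_withdrawal_filter(self._cohort(ev)).outcomes.empty

    def test_recent_vasopressor_retains(self):
        ev = [
            (0, 100, "record_end"),
            (0, 110, "death_time"),
            (0, 70, "vaso_admin"),
            (0, 95, "vaso_admin"),
        ]
        assert len(apply_withdrawal_filter(self._cohort(ev)).outcomes) == 1

    def test_survivor_always_retained(self):
        ev = [(0, 100, "record_end"), (0, 70, "vaso_admin")]
        assert len(apply_withdrawal_filter(self._cohort(ev, died=0)).outcomes) == 1

    def test_never_treated_patient_retained(self):
        # clause three fails: no earlier vasopressor at all
        ev = [(0, 100, "record_end"), (0, 110, "death_time")]
        assert len(apply_withdrawal_filter(self._cohort(ev)).outcomes) == 1


class TestBinning:
    def _config(self):
        return PreprocessConfig(
            aggregation={"heart_rate": "mean", "total_fluid_input": "sum"},
            cap_bounds={},
        )

    def test_mean_and_sum_rules(self):
        obs = pd.DataFrame(
            [
                (0, 2, "heart_rate", 80.0),
                (0, 2, "heart_rate", 90.0),
                (0, 2, "total_fluid_input", 200.0),
                (0, 2, "total_fluid_input", 300.0),
            ],
            columns=["patient_id", "bin_index", "feature_name", "value"],
        )
        doses = pd.DataFrame(
            [(0, 2, 0.1, 250.0)],
            columns=["patient_id", "bin_index", "vaso_dose", "fluid_volume"],
        )
        out = pd.DataFrame(
            [dict(patient_id=0, died_90d=0, outcome_documented=True,
                  fluids_documented=True, age=40.0)]
        )
        wide = bin_and_aggregate(_raw(obs, doses, out), {0: 24.0}, self._config())
        row = wide[wide.bin_index == 2].iloc[0]
        assert row.heart_rate == 85.0
        assert row.total_fluid_input == 500.0

    def test_observation_outside_window_dropped(self):
        # absolute-time path: onset 24 h -> window [0, 72) h; 24+49=73 h is out
        obs = pd.DataFrame(
            [
                dict(patient_id=0, time_h=73.0, feature_name="heart_rate", value=99.0),
                dict(patient_id=0, time_h=30.0, feature_name="heart_rate", value=80.0),
            ]
        )
        doses = pd.DataFrame(
            [(0, 0, 0.0, 0.0)],
            columns=["patient_id", "bin_index", "vaso_dose", "fluid_volume"],
        )
        out = pd.DataFrame(
            [dict(patient_id=0, died_90d=0, outcome_documented=True,
                  fluids_documented=True, age=40.0)]
        )
        wide = bin_and_aggregate(_raw(obs, doses, out), {0: 24.0}, self._config())
        assert not (wide.heart_rate == 99.0).any()
        assert (wide.heart_rate.dropna() == 80.0).any()

    def test_missing_aggregation_rule_raises(self):
        obs = pd.DataFrame(
            [(0, 0, "mystery", 1.0)],
            columns=["patient_id", "bin_index", "feature_name", "value"],
        )
        with pytest.raises(ValueError, match="aggregation"):
            bin_and_aggregate(_raw(obs), {0: 24.0}, self._config())


class TestCapping:
    def test_clamp_and_identity(self):
        cfg = PreprocessConfig(cap_bounds={"heart_rate": (20, 220), "spo2": (0, 100)})
        t = pd.DataFrame({"heart_rate": [300.0, 85.0], "spo2": [-1.0, 99.0]})
        capped = cap_values(t, cfg)
        assert capped.heart_rate.tolist() == [220.0, 85.0]
        assert capped.spo2.tolist() == [0.0, 99.0]

    def test_idempotent(self):
        cfg = PreprocessConfig(cap_bounds={"heart_rate": (20, 220)})
        t = pd.DataFrame({"heart_rate": np.linspace(-50, 400, 23)})
        once = cap_values(t, cfg)
        pd.testing.assert_frame_equal(cap_values(once, cfg), once)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(cap_bounds={"heart_rate": (220, 20)})


class TestImpute:
    def _table(self, series, split=None):
        t = pd.DataFrame(
            {
                "patient_id": 0,
                "bin_index": range(len(series)),
                "f": series,
                "vaso_dose": 0.0,
                "fluid_volume": 0.0,
                "outcome": "survived",
            }
        )
        if split is not None:
            t["split"] = split
        return t

    def test_zero_order_hold(self):
        out = impute(self._table([5.0, np.nan, np.nan, 7.0, np.nan]))
        assert out.f.tolist() == [5.0, 5.0, 5.0, 7.0, 7.0]

    def test_leading_gap_backfilled(self):
        out = impute(self._table([np.nan, np.nan, 3.0]))
        assert out.f.tolist() == [3.0, 3.0, 3.0]

    def test_training_median_fallback(self):
        a = self._table([np.nan, np.nan], split="test")
        b = pd.DataFrame(
            {
                "patient_id": [1, 2, 3],
                "bin_index": 0,
                "f": [4.0, 4.2, 5.0],
                "vaso_dose": 0.0,
                "fluid_volume": 0.0,
                "outcome": "survived",
                "split": "train",
            }
        )
        out = impute(pd.concat([a, b], ignore_index=True))
        assert (out.loc[out.patient_id == 0, "f"] == 4.2).all()

    def test_idempotent(self, small_table):
        pd.testing.assert_frame_equal(impute(small_table), small_table)

    def test_feature_never_observed_raises(self):
        with pytest.raises(ValueError, match="nowhere"):
            impute(self._table([np.nan, np.nan]))


class TestSplit:
    def _table(self, n):
        return pd.DataFrame(
            {"patient_id": np.repeat(np.arange(n), 2), "bin_index": [0, 1] * n}
        )

    def test_80_20_split_of_ten(self):
        out = split_train_test(self._table(10), PreprocessConfig(split_seed=4))
        per_patient = out.drop_duplicates("patient_id")
        assert (per_patient.split == "train").sum() == 8
        assert (per_patient.split == "test").sum() == 2

    def test_deterministic_given_seed(self):
        cfg = PreprocessConfig(split_seed=9)
        a = split_train_test(self._table(50), cfg)
        b = split_train_test(self._table(50), cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_assignment(self):
        a = split_train_test(self._table(100), PreprocessConfig(split_seed=1))
        b = split_train_test(self._table(100), PreprocessConfig(split_seed=2))
        assert not a.split.equals(b.split)

    def test_no_patient_in_both_splits(self, small_table):
        sides = small_table.groupby("patient_id").split.nunique()
        assert (sides == 1).all()

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(self._table(3), PreprocessConfig())


def test_pipeline_output_complete(small_table):
    assert not small_table.isna().any().any()
    assert set(small_table.outcome) <= {"survived", "died"}
    assert small_table.groupby("patient_id").bin_index.apply(
        lambda s: (np.diff(np.sort(s)) == 1).all()
    ).all()
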