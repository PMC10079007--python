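"""Outcome statistics: attrition arithmetic and conservation, end-of-line
classification, Kaplan-Meier estimation against a brute-force oracle,
regimen shares and the demographic summary."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from claimlines import (attrition_percent, attrition_table,
                        classify_line_outcome, km_estimate,
                        regimen_share_table, table1_summary)

from conftest import day


def km_oracle(durations, events):
    """Brute-force product-limit: recompute the risk set at every distinct
    time (deaths before censorings at ties)."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    surv = 1.0
    out = {}
    for t in np.unique(durations):
        at_risk = int((durations >= t).sum())
        deaths = int(((durations == t) & events).sum())
        if deaths:
            surv *= 1.0 - deaths / at_risk
        out[float(t)] = surv
    return out


class TestAttritionArithmetic:
    def test_percentage_definition_and_rounding(self):
        assert attrition_percent(740, 510) == 31.1
        assert attrition_percent(100, 100) == 0.0
        assert attrition_percent(8, 7) == 12.5
        # half-up at one decimal, not banker's rounding
        assert attrition_percent(1000, 625) == 37.5
        assert attrition_percent(400, 299) == 25.3

    def test_zero_previous_frequency_is_an_error(self):
        with pytest.raises(ValueError):
            attrition_percent(0, 0)


def _lines_frame(spec):
    """spec: {patient: [(line, start_off, end_off), ...]}"""
    rows = []
    for pid, lines in spec.items():
        for line_no, s, e in lines:
            rows.append({"patient_id": pid, "line_number": line_no,
                         "regimen": "Vd", "start": day(s), "end": day(e)})
    return pd.DataFrame(rows)


def _patients_frame(spec):
    """spec: {patient: (death_off or None, data_end_off)}"""
    rows = []
    for pid, (death, data_end) in spec.items():
        rows.append({"patient_id": pid,
                     "death_date": day(death) if death is not None else None,
                     "data_end": day(data_end),
                     "index_date": day(0)})
    return pd.DataFrame(rows)


class TestAttritionTable:
    @pytest.fixture()
    def small(self):
        lines = _lines_frame({
            "A": [(1, 0, 100), (2, 200, 300)],
            "B": [(1, 0, 90)],
            "C": [(1, 0, 80)],
            "D": [(1, 0, 120)],
        })
        patients = _patients_frame({
            "A": (None, 400),   # subsequent treatment at 1L
            "B": (150, 150),    # death after line end
            "C": (None, 100),   # data end 20 days after line -> lost
            "D": (None, 400),   # alive, long follow-up, no next line
        })
        return attrition_table(lines, patients)

    def test_frequencies_and_attrition(self, small):
        assert list(small["frequency"]) == [4, 1]
        assert np.isnan(small.loc[0, "pct_attrition"])
        assert small.loc[1, "pct_attrition"] == 75.0

    def test_end_reason_counts_sum_to_frequency(self, small):
        reason_cols = [c for c in small.columns if c.endswith("_n")]
        assert (small[reason_cols].sum(axis=1) == small["frequency"]).all()

    def test_subsequent_count_equals_next_line_frequency(self, small):
        assert small.loc[0, "subsequent_treatment_n"] == small.loc[1, "frequency"]

    def test_each_outcome_classified(self, small):
        row = small.iloc[0]
        assert row["death_n"] == 1
        assert row["lost_to_followup_n"] == 1
        assert row["no_subsequent_treatment_n"] == 1
        assert row["subsequent_treatment_n"] == 1

    def test_duration_reported_in_months(self, small):
        # line durations 101, 91, 81, 121 days -> mean 98.5 d = 3.2 months
        assert small.loc[0, "duration_mean_months"] == 3.2


class TestClassifyLineOutcome:
    def test_next_line_wins(self):
        assert classify_line_outcome(day(100), True, day(120), day(130)) \
            == "subsequent_treatment"

    def test_death_without_next_line(self):
        assert classify_line_outcome(day(100), False, day(130), day(130)) \
            == "death"

    def test_short_residual_followup_is_lost(self):
        assert classify_line_outcome(day(100), False, None, day(120)) \
            == "lost_to_followup"

    def test_window_boundary(self):
        assert classify_line_outcome(day(100), False, None, day(159)) \
            == "lost_to_followup"
        assert classify_line_outcome(day(100), False, None, day(160)) \
            == "no_subsequent_treatment"


class TestKaplanMeier:
    def test_hand_worked_example(self):
        est = km_estimate([2, 3, 4], [True, False, True])
        s = dict(zip(est.times, est.survival))
        assert s[2.0] == pytest.approx(2 / 3, abs=1e-12)
        assert s[4.0] == pytest.approx(0.0, abs=1e-12)
        assert est.median == 4.0

    def test_all_censored_median_not_estimable(self):
        est = km_estimate([5, 8, 13], [False, False, False])
        assert est.median is None
        assert est.render(est.median) == "NE"

    def test_no_censoring_reduces_to_empirical_survival(self):
        times = [1, 2, 3, 4, 5]
        est = km_estimate(times, [True] * 5)
        for t, s in zip(est.times, est.survival):
            assert s == pytest.approx(1 - t / 5, abs=1e-12)
        assert est.median == 3.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            durations = rng.integers(1, 20, size=n).astype(float)
            events = rng.random(n) < 0.6
            est = km_estimate(durations, events)
            oracle = km_oracle(durations, events)
            for t, s in zip(est.times, est.survival):
                assert abs(s - oracle[t]) < 1e-12

    def test_quartiles(self):
        est = km_estimate(np.arange(1, 101), [True] * 100)
        assert est.q25 == 25.0
        assert est.median == 50.0
        assert est.q75 == 75.0


class TestRegimenShare:
    def test_simple_share(self):
        lines = pd.DataFrame({
            "patient_id": list("ABCD"),
            "line_number": [1] * 4,
            "regimen": ["Vd", "Vd", "Rd", "MP"],
        })
        out = regimen_share_table(lines, phase="first-line")
        assert out.loc[out["regimen"] == "Vd", "pct"].item() == 50.0

    def test_top_k_with_other_bucket(self):
        lines = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(14)],
            "line_number": [1] * 14,
            "regimen": (["Vd"] * 5 + ["Rd"] * 3 + ["MP"] * 2
                        + ["VRd", "VCd", "DRd", "IRd"]),
        })
        out = regimen_share_table(lines, phase="first-line", top_k=5)
        assert len(out) == 6
        assert out.iloc[-1]["regimen"] == "other"
        assert out["n"].sum() == 14

    def test_empty_cell(self):
        lines = pd.DataFrame(columns=["patient_id", "line_number", "regimen"])
        assert regimen_share_table(lines, phase="first-line").empty


class TestTable1:
    def _cohort(self):
        rng = np.random.default_rng(0)
        n = 60
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "eligible": [True] * 56 + [False] * 4,
            "sex": rng.choice(["F", "M"], n),
            "era": rng.choice(["2003-2015", "2016-2020"], n),
            "age": rng.integers(30, 95, n),
            "cci": rng.integers(0, 7, n),
            "sct_conducted": rng.random(n) < 0.3,
            "renal_impairment": rng.random(n) < 0.1,
        })

    def test_subgroup_columns_sum_to_eligible_total(self):
        t1 = table1_summary(self._cohort())
        n_rows = t1[t1["item"] == "N"].set_index("stratum")["n"]
        subgroups = [s for s in n_rows.index if s != "eligible"]
        assert n_rows[subgroups].sum() == n_rows["eligible"] == 56

    def test_band_counts_partition_each_stratum(self):
        t1 = table1_summary(self._cohort())
        for stratum, g in t1.groupby("stratum"):
            total = g.loc[g["item"] == "N", "n"].item()
            ages = g[g["item"].str.startswith("age_")]
            assert ages["n"].sum() == total
            ccis = g[g["item"].str.startswith("cci_")]
            assert ccis["n"].sum() == total

    def test_single_patient_stratum_has_no_sd(self):
        cohort = self._cohort().iloc[:1].assign(
            eligible=True, sct_conducted=True, renal_impairment=True)
        t1 = table1_summary(cohort)
        row = t1[(t1["stratum"] == "sct_conducted_with_renal")
                 & (t1["item"] == "age")]
        assert np.isnan(row["sd"].item())

    def test_percentage_arithmetic(self):
        cohort = self._cohort()
        t1 = table1_summary(cohort)
        female = t1[(t1["stratum"] == "eligible") & (t1["item"] == "female")]
        n = female["n"].item()
        assert female["pct"].item() == pytest.approx(
            round(100 * n / 56, 1), abs=0.051)


class TestPopulationConservation:
    def test_attrition_conservation_on_synthetic_cohort(self, population):
        cohort = population["cohort"]
        lines = population["lines"]
        eligible = cohort[cohort["eligible"]]
        att = attrition_table(lines, eligible)
        reason_cols = [c for c in att.columns if c.endswith("_n")]
        assert (att[reason_cols].sum(axis=1) == att["frequency"]).all()
        assert (att["frequency"].diff().dropna() <= 0).all()
        for i in range(len(att) - 1):
            assert att.loc[i, "subsequent_treatment_n"] \
                == att.loc[i + 1, "frequency"]
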