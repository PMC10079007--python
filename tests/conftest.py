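"""Shared fixtures: a synthetic population generated once per session and
small helpers for hand-building patient timelines."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from claimlines import (ClaimsBundle, PatientTimeline, SimulationConfig,
                        build_cohort, generate_population)
from claimlines.pipeline import derive_population_lines

D0 = dt.date(2017, 3, 1)


def day(offset: int) -> dt.date:
    """Date at a fixed origin plus ``offset`` days (test shorthand)."""
    return D0 + dt.timedelta(days=offset)


def make_timeline(*, birth_year=1950, sex="F", data_start=-500, data_end=600,
                  diagnoses=(), drugs=(), procedures=(), hospitalizations=(),
                  index_date=None, death_date=None) -> PatientTimeline:
    """Build a PatientTimeline with day offsets relative to ``D0``."""
    def d(x):
        return day(x) if isinstance(x, int) else x

    t = PatientTimeline(
        patient_id="T1",
        birth_year=birth_year,
        sex=sex,
        data_start=d(data_start),
        data_end=d(data_end),
        diagnoses=[(d(a), b, c, e) for a, b, c, e in diagnoses],
        drug_events=[(d(a), b) for a, b in drugs],
        procedures=[(d(a), b) for a, b in procedures],
        hospitalizations=[(d(a), d(b), c) for a, b, c in hospitalizations],
        index_date=d(index_date) if index_date is not None else None,
        death_date=d(death_date) if death_date is not None else None,
    )
    t.diagnoses.sort(key=lambda r: r[0])
    t.drug_events.sort()
    return t


def mm_diagnosis(offset: int, confirmed: bool = True, local: str = "2030003"):
    return (offset, "C90.0", local, confirmed)


@pytest.fixture(scope="session")
def population():
    """150-patient synthetic population with cohort and derived lines."""
    cfg = SimulationConfig(n_patients=150, seed=3)
    bundle, truth = generate_population(cfg)
    cohort = build_cohort(bundle)
    lines = derive_population_lines(bundle, cohort)
    return {"config": cfg, "bundle": bundle, "truth": truth,
            "cohort": cohort, "lines": lines}


@pytest.fixture(scope="session")
def truth_lines_eligible(population):
    """Planted lines of eligible patients, with parsed dates."""
    truth = population["truth"]
    tl = truth.lines.copy()
    for c in ("start", "end"):
        tl[c] = pd.to_datetime(tl[c]).dt.date
    keep = truth.patients.loc[truth.patients["eligible"], "patient_id"]
    return tl[tl["patient_id"].isin(set(keep))]
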