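"""In-memory containers for a claims population and, for synthetic data,
its exported ground truth.

A :class:`ClaimsBundle` mirrors the structure of DPC-style hospital claims
extracts: a patient master table plus four longitudinal event tables
(diagnoses, drug administrations, procedures, hospitalizations), all in
delimited text.  Dates are ISO ``YYYY-MM-DD`` strings on disk and
``datetime.date`` in memory; interval arithmetic is in whole days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ClaimsBundle", "GroundTruth", "PatientTimeline"]

_TABLES = {
    "patients": ["patient_id", "birth_year", "sex", "data_start", "data_end"],
    "diagnoses": ["patient_id", "date", "icd10", "disease_code", "confirmed"],
    "drugs": ["patient_id", "date", "drug", "days_supply", "route"],
    "procedures": ["patient_id", "date", "procedure_type"],
    "hospitalizations": [
        "patient_id", "admission_date", "discharge_date", "discharged_to_death",
    ],
}

_DATE_COLS = {"date", "data_start", "data_end", "admission_date", "discharge_date",
              "index_date", "start", "end", "sct_date", "death_date"}


def _parse_dates(df: pd.DataFrame) -> pd.DataFrame:
    for c in df.columns:
        if c in _DATE_COLS:
            df[c] = pd.to_datetime(df[c], format="ISO8601", errors="coerce").dt.date
    return df


@dataclass
class ClaimsBundle:
    """The five claims tables for a patient population."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    drugs: pd.DataFrame
    procedures: pd.DataFrame
    hospitalizations: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "ClaimsBundle":
        path = Path(in_dir)
        frames = {}
        for name, cols in _TABLES.items():
            f = path / f"{name}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing event table: {f}")
            df = pd.read_csv(f, dtype={"disease_code": str, "patient_id": str})
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{f}: missing columns {sorted(missing)}")
            frames[name] = _parse_dates(df)
        return cls(**frames)

    def for_patient(self, patient_id: str) -> dict[str, pd.DataFrame]:
        return {
            name: getattr(self, name)[getattr(self, name)["patient_id"] == patient_id]
            for name in _TABLES
        }


@dataclass
class GroundTruth:
    """Planted truth for a synthetic population.

    ``patients`` has one row per patient: index date, eligibility verdict
    with the violated rule (first in evaluation order, if any), subgroup
    labels and death date.  ``lines`` has one row per planted therapy line.
    """

    patients: pd.DataFrame
    lines: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "truth_patients.csv", index=False)
        self.lines.to_csv(out / "truth_lines.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "GroundTruth":
        path = Path(in_dir)
        patients = _parse_dates(
            pd.read_csv(path / "truth_patients.csv", dtype={"patient_id": str})
        )
        lines = _parse_dates(
            pd.read_csv(path / "truth_lines.csv", dtype={"patient_id": str})
        )
        return cls(patients=patients, lines=lines)


@dataclass
class PatientTimeline:
    """One patient's date-ordered events with the derived analysis window."""

    patient_id: str
    birth_year: int
    sex: str
    data_start: object  # datetime.date
    data_end: object
    diagnoses: list = field(default_factory=list)   # (date, icd10, disease_code, confirmed)
    drug_events: list = field(default_factory=list)  # (date, drug)
    procedures: list = field(default_factory=list)   # (date, procedure_type)
    hospitalizations: list = field(default_factory=list)  # (adm, dis, death_flag)
    index_date: object = None
    death_date: object = None

    def event_dates(self) -> list:
        """All claim dates, sorted (used for the continuous-care check)."""
        dates = (
            [d[0] for d in self.diagnoses]
            + [d[0] for d in self.drug_events]
            + [p[0] for p in self.procedures]
            + [h[0] for h in self.hospitalizations]
            + [h[1] for h in self.hospitalizations]
        )
        return sorted(dates)
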