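"""Cohort selection: index MM diagnosis, eligibility rules, subgroup labels
and the baseline Charlson Comorbidity Index.

The selection flow mirrors standard claims-cohort construction for
multiple myeloma:

1. **Index date** — earliest confirmed diagnosis record carrying ICD-10
   C90.0 together with one of the Japanese local disease codes.
2. **Eligibility** — age >= 20 at index; >= 12 months of baseline data
   (waived when a stem-cell-transplant record exists); >= 60 days of
   follow-up unless the patient died as an inpatient within those 60 days;
   continuous care (no claim-free gap longer than a configurable 180 days
   inside the analysis window); and no evidence of MM, another primary
   cancer, or metastatic disease during the 12-month baseline.
3. **Subgroups** — index era (2003-2015 vs 2016-2020), SCT conducted after
   the index date, and baseline renal impairment from the dedicated ICD-10
   list.

All checks are order-independent with respect to event-table row order:
only dates and codes matter, never input ordering.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from . import codes
from ._util import as_date
from .bundle import ClaimsBundle, PatientTimeline
from .config import CohortConfig

__all__ = [
    "EligibilityVerdict",
    "SubgroupLabel",
    "identify_index_date",
    "check_eligibility",
    "assign_subgroups",
    "compute_cci",
    "timelines_from_bundle",
    "build_cohort",
]


@dataclass(frozen=True)
class EligibilityVerdict:
    eligible: bool
    reasons: tuple[str, ...]
    baseline_start: dt.date
    followup_end: dt.date

    def __post_init__(self):
        assert self.eligible == (len(self.reasons) == 0)


@dataclass(frozen=True)
class SubgroupLabel:
    index_era: str            # "2003-2015" or "2016-2020"
    sct_conducted: bool
    renal_impairment: bool


def identify_index_date(timeline: PatientTimeline,
                        mm_codes: dict | None = None) -> dt.date | None:
    """Earliest confirmed diagnosis record matching both code systems.

    Returns ``None`` when no record qualifies (an unconfirmed, rule-out
    C90.0 or a C90.0 without a listed local disease code never indexes a
    patient).
    """
    mm = mm_codes or codes.load_mm_codes()
    icd10 = {c.upper() for c in mm["icd10"]}
    local = set(mm["japanese_disease_codes"])
    dates = [
        d for d, code, disease_code, confirmed in timeline.diagnoses
        if confirmed
        and codes.normalize_icd10(code) in icd10
        and str(disease_code) in local
    ]
    return min(dates) if dates else None


def _baseline_window(index_date: dt.date, config: CohortConfig):
    """Baseline is [index - baseline_days, index): the index day itself is
    follow-up, not baseline."""
    return index_date - dt.timedelta(days=config.baseline_days), index_date


def check_eligibility(timeline: PatientTimeline, index_date,
                      config: CohortConfig | None = None) -> EligibilityVerdict:
    """Evaluate every eligibility rule and record all violations."""
    config = config or CohortConfig()
    index_date = as_date(index_date)
    if not (timeline.data_start <= index_date <= timeline.data_end):
        raise ValueError(
            f"index date {index_date} outside the data window "
            f"[{timeline.data_start}, {timeline.data_end}]"
        )
    reasons: list[str] = []
    baseline_start, baseline_end = _baseline_window(index_date, config)

    # (1) adult at index
    age = index_date.year - timeline.birth_year
    if age < config.min_age:
        reasons.append("age_under_20")

    # (2) 12-month baseline, waived by any SCT procedure record
    has_sct = any(p[1] == "SCT" for p in timeline.procedures)
    coverage = (index_date - timeline.data_start).days
    if coverage < config.baseline_days and not has_sct:
        reasons.append("missing_baseline")

    # (3) >= 60 days of follow-up unless the patient died earlier
    followup = (timeline.data_end - index_date).days
    if followup < config.min_followup_days and timeline.death_date is None:
        reasons.append("short_followup_no_death")

    # (4) continuous care: no claim-free gap beyond the threshold within
    # [baseline start (clipped to data start), follow-up end]
    window_lo = max(baseline_start, timeline.data_start)
    dates = [d for d in timeline.event_dates()
             if window_lo <= d <= timeline.data_end]
    span = sorted({window_lo, *dates, timeline.data_end})
    if any((b - a).days > config.continuous_care_gap_days
           for a, b in zip(span, span[1:])):
        reasons.append("no_continuous_care")

    # (5) baseline evidence of MM, other primary cancer, or metastasis
    mm = codes.load_mm_codes()
    mm_prefixes = tuple(mm["icd10"])
    bad = tuple(config.other_cancer_prefixes) + tuple(config.metastatic_prefixes)
    for d, code, _, _ in timeline.diagnoses:
        if baseline_start <= d < baseline_end:
            if codes.icd10_matches(code, mm_prefixes) or codes.icd10_matches(code, bad):
                reasons.append("baseline_malignancy")
                break

    return EligibilityVerdict(
        eligible=not reasons,
        reasons=tuple(reasons),
        baseline_start=baseline_start,
        followup_end=timeline.data_end,
    )


def assign_subgroups(timeline: PatientTimeline, index_date,
                     config: CohortConfig | None = None) -> SubgroupLabel:
    """Era / SCT / renal-impairment labels for an eligible patient."""
    config = config or CohortConfig()
    index_date = as_date(index_date)
    era = "2003-2015" if index_date.year < 2016 else "2016-2020"
    sct = any(p[1] == "SCT" and p[0] > index_date for p in timeline.procedures)
    baseline_start, baseline_end = _baseline_window(index_date, config)
    renal_prefixes = codes.load_renal_prefixes()
    renal = any(
        baseline_start <= d < baseline_end and codes.icd10_matches(code, renal_prefixes)
        for d, code, _, _ in timeline.diagnoses
    )
    return SubgroupLabel(index_era=era, sct_conducted=sct, renal_impairment=renal)


def compute_cci(timeline: PatientTimeline, index_date,
                config: CohortConfig | None = None,
                mapping: dict | None = None) -> int:
    """Charlson Comorbidity Index from baseline diagnoses.

    Uses the Quan ICD-10 coding algorithm with the original Charlson
    weights; each comorbidity category counts at most once and
    hierarchical pairs (e.g. metastatic disease over any malignancy) score
    only the severe member.
    """
    config = config or CohortConfig()
    index_date = as_date(index_date)
    mapping = mapping or codes.load_charlson_map()
    baseline_start, baseline_end = _baseline_window(index_date, config)
    present: set[str] = set()
    baseline_codes = [code for d, code, _, _ in timeline.diagnoses
                      if baseline_start <= d < baseline_end]
    for cat, info in mapping["categories"].items():
        if any(codes.icd10_matches(c, info["prefixes"]) for c in baseline_codes):
            present.add(cat)
    for severe, mild in mapping["hierarchies"]:
        if severe in present:
            present.discard(mild)
    return sum(mapping["categories"][c]["weight"] for c in present)


def timelines_from_bundle(bundle: ClaimsBundle) -> list[PatientTimeline]:
    """Split the population tables into per-patient timelines."""
    dx = {pid: g for pid, g in bundle.diagnoses.groupby("patient_id", sort=False)}
    rx = {pid: g for pid, g in bundle.drugs.groupby("patient_id", sort=False)}
    px = {pid: g for pid, g in bundle.procedures.groupby("patient_id", sort=False)}
    hosp = {pid: g for pid, g in bundle.hospitalizations.groupby("patient_id", sort=False)}
    timelines = []
    for row in bundle.patients.itertuples():
        pid = row.patient_id
        g = hosp.get(pid)
        hospitalizations = (
            [(as_date(r.admission_date), as_date(r.discharge_date),
              bool(r.discharged_to_death)) for r in g.itertuples()]
            if g is not None else []
        )
        deaths = [h[1] for h in hospitalizations if h[2]]
        t = PatientTimeline(
            patient_id=pid,
            birth_year=int(row.birth_year),
            sex=str(row.sex),
            data_start=as_date(row.data_start),
            data_end=as_date(row.data_end),
            diagnoses=[
                (as_date(r.date), str(r.icd10), str(r.disease_code), bool(r.confirmed))
                for r in dx.get(pid, _EMPTY_DX).itertuples()
            ],
            drug_events=[
                (as_date(r.date), str(r.drug))
                for r in rx.get(pid, _EMPTY_RX).itertuples()
            ],
            procedures=[
                (as_date(r.date), str(r.procedure_type))
                for r in px.get(pid, _EMPTY_PX).itertuples()
            ],
            hospitalizations=hospitalizations,
            death_date=max(deaths) if deaths else None,
        )
        t.diagnoses.sort(key=lambda r: r[0])
        t.drug_events.sort()
        t.procedures.sort()
        t.index_date = identify_index_date(t)
        timelines.append(t)
    return timelines


_EMPTY_DX = pd.DataFrame(columns=["date", "icd10", "disease_code", "confirmed"])
_EMPTY_RX = pd.DataFrame(columns=["date", "drug"])
_EMPTY_PX = pd.DataFrame(columns=["date", "procedure_type"])


def build_cohort(bundle: ClaimsBundle,
                 config: CohortConfig | None = None) -> pd.DataFrame:
    """Run the full selection flow over a population.

    Returns one row per patient with an index diagnosis:
    ``patient_id, index_date, eligible, reasons, era, sct_conducted,
    renal_impairment, age, sex, cci, death_date, data_end``.
    Patients with no confirmed MM record are omitted (they never enter the
    selection flowchart).
    """
    config = config or CohortConfig()
    rows = []
    for t in timelines_from_bundle(bundle):
        if t.index_date is None:
            continue
        verdict = check_eligibility(t, t.index_date, config)
        label = assign_subgroups(t, t.index_date, config)
        rows.append({
            "patient_id": t.patient_id,
            "index_date": t.index_date,
            "eligible": verdict.eligible,
            "reasons": ";".join(verdict.reasons),
            "era": label.index_era,
            "sct_conducted": label.sct_conducted,
            "renal_impairment": label.renal_impairment,
            "age": t.index_date.year - t.birth_year,
            "sex": t.sex,
            "cci": compute_cci(t, t.index_date, config),
            "death_date": t.death_date,
            "data_end": t.data_end,
        })
    return pd.DataFrame(rows)
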