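"""Outcome statistics over derived therapy lines: per-line attrition with
end-of-line classification, duration summaries, demographic summaries,
regimen-share tables, and Kaplan-Meier time to inpatient death.

Death is observable only through hospital discharge records, so every
patient without a discharge-to-death record is right-censored at the end
of their data - the standard treatment of inpatient-only death capture in
DPC-style claims.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._util import days_to_months, round_half_up
from .config import OutcomesConfig

__all__ = [
    "KMEstimate",
    "attrition_percent",
    "attrition_table",
    "classify_line_outcome",
    "km_estimate",
    "time_to_death_table",
    "regimen_share_table",
    "table1_summary",
]

OUTCOME_LEVELS = ("death", "lost_to_followup", "no_subsequent_treatment",
                  "subsequent_treatment")

AGE_BANDS = (
    ("18-59", 18, 59), ("60-64", 60, 64), ("65-69", 65, 69),
    ("70-74", 70, 74), ("75-79", 75, 79), ("80-84", 80, 84),
    ("85-89", 85, 89), ("90-94", 90, 94), ("95-99", 95, 99),
    ("100-", 100, 10**6),
)


def attrition_percent(previous_n: int, n: int) -> float:
    """Percentage of patients on the previous line who did not reach this
    one, rounded half-up to one decimal.

    Computed in exact decimal arithmetic so ties round the way printed
    tables do (e.g. 299/400 -> 25.25 -> 25.3).
    """
    if previous_n <= 0:
        raise ValueError("previous line frequency must be positive")
    from decimal import ROUND_HALF_UP, Decimal
    pct = Decimal(100) * (1 - Decimal(n) / Decimal(previous_n))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_line_outcome(line_end: dt.date, has_next: bool,
                          death_date: dt.date | None, data_end: dt.date,
                          window_days: int = 60) -> str:
    """What happened after a patient's line at a given level.

    ``subsequent_treatment`` when a next line exists; ``death`` when an
    inpatient death was recorded (the line is then the patient's last);
    ``lost_to_followup`` when the data end within ``window_days`` of the
    line end without a death record; otherwise
    ``no_subsequent_treatment``.
    """
    if has_next:
        return "subsequent_treatment"
    if death_date is not None:
        return "death"
    if (data_end - line_end).days < window_days:
        return "lost_to_followup"
    return "no_subsequent_treatment"


def attrition_table(lines: pd.DataFrame, patients: pd.DataFrame,
                    config: OutcomesConfig | None = None) -> pd.DataFrame:
    """Per-line frequencies, % attrition, end-of-line classification and
    duration summaries.

    ``lines`` needs columns patient_id, line_number, start, end;
    ``patients`` needs patient_id, death_date, data_end.  Percentages are
    rounded half-up to one decimal; % attrition at line 1 is NaN (rendered
    as "-").
    """
    config = config or OutcomesConfig()
    if lines.empty:
        return pd.DataFrame()
    info = patients.set_index("patient_id")[["death_date", "data_end"]]
    max_line = int(lines["line_number"].max())
    per_patient_max = lines.groupby("patient_id")["line_number"].max()
    rows = []
    prev_n = None
    for level in range(1, max_line + 1):
        at_level = lines[lines["line_number"] == level]
        n = len(at_level)
        counts = dict.fromkeys(OUTCOME_LEVELS, 0)
        for r in at_level.itertuples():
            death = info.at[r.patient_id, "death_date"]
            death = None if pd.isna(death) else death
            outcome = classify_line_outcome(
                r.end, per_patient_max[r.patient_id] > level,
                death, info.at[r.patient_id, "data_end"],
                config.lost_to_followup_window_days,
            )
            counts[outcome] += 1
        dur_months = np.array([
            days_to_months((r.end - r.start).days + 1) for r in at_level.itertuples()
        ])
        row = {
            "line": level,
            "frequency": n,
            "pct_attrition": (attrition_percent(prev_n, n)
                              if prev_n is not None else np.nan),
        }
        for k in OUTCOME_LEVELS:
            row[f"{k}_n"] = counts[k]
            row[f"{k}_pct"] = round_half_up(100.0 * counts[k] / n, 1) if n else np.nan
        row["duration_mean_months"] = round_half_up(float(dur_months.mean()), 1)
        row["duration_sd_months"] = (
            round_half_up(float(dur_months.std(ddof=1)), 2)
            if len(dur_months) > 1 else np.nan
        )
        row["duration_median_months"] = round_half_up(float(np.median(dur_months)), 1)
        rows.append(row)
        prev_n = n
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate with percentile summaries.

    ``median``/``q25``/``q75`` are ``None`` when the curve never reaches
    the corresponding survival level (reported as "NE").
    """

    times: np.ndarray          # distinct event times (days)
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size at each event time
    censor_times: np.ndarray
    n: int
    median: float | None
    q25: float | None
    q75: float | None

    def quantile(self, p: float) -> float | None:
        """Smallest time with S(t) <= 1 - p (deaths precede censorings at
        tied times, the standard product-limit convention)."""
        level = 1.0 - p
        idx = np.nonzero(self.survival <= level + 1e-12)[0]
        return float(self.times[idx[0]]) if idx.size else None

    def render(self, value: float | None) -> str:
        return "NE" if value is None else f"{value:g}"


def km_estimate(durations, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator of time to inpatient death.

    ``durations`` in days; ``events`` truthy for death, falsy for
    right-censoring at the last observation.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("empty input: no durations to estimate from")
    if durations.shape != events.shape:
        raise ValueError("durations and event flags differ in length")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    est = KMEstimate(
        times=times,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(durations[~events]),
        n=int(durations.size),
        median=None, q25=None, q75=None,
    )
    object.__setattr__(est, "median", est.quantile(0.5))
    object.__setattr__(est, "q25", est.quantile(0.25))
    object.__setattr__(est, "q75", est.quantile(0.75))
    return est


def time_to_death_table(lines: pd.DataFrame, patients: pd.DataFrame,
                        config: OutcomesConfig | None = None) -> pd.DataFrame:
    """Per-patient, per-line survival input: time from the origin (line
    start by default, index date optionally) to inpatient death or
    censoring at data end."""
    config = config or OutcomesConfig()
    info = patients.set_index("patient_id")
    rows = []
    for r in lines.itertuples():
        p = info.loc[r.patient_id]
        origin = r.start if config.time_origin == "line" else p["index_date"]
        death = p["death_date"]
        death = None if pd.isna(death) else death
        if death is not None:
            time, event = (death - origin).days, True
        else:
            time, event = (p["data_end"] - origin).days, False
        rows.append({
            "patient_id": r.patient_id,
            "line": r.line_number,
            "time_days": max(time, 1),
            "event": event,
        })
    return pd.DataFrame(rows)


def regimen_share_table(lines: pd.DataFrame, phase: str | None = None,
                        patient_ids=None, top_k: int | None = None) -> pd.DataFrame:
    """Regimen counts and percentages for a phase x cohort cell.

    ``phase`` is one of ``first-line`` (line number 1), ``induction``,
    ``post-SCT`` (phase labels) or ``None`` (all lines).  Each patient
    contributes their earliest qualifying line; percentages are over the
    patients in the cell.  ``top_k`` keeps the k most used regimens and
    buckets the rest as "other".
    """
    sel = lines
    if patient_ids is not None:
        sel = sel[sel["patient_id"].isin(set(patient_ids))]
    if phase == "first-line":
        sel = sel[sel["line_number"] == 1]
    elif phase is not None:
        if "phase" not in sel.columns:
            raise ValueError("lines table has no phase labels")
        sel = sel[sel["phase"] == phase]
    if sel.empty:
        return pd.DataFrame(columns=["regimen", "n", "pct"])
    first = sel.sort_values(["patient_id", "line_number"]).groupby(
        "patient_id", sort=False).first()
    denom = len(first)
    counts = first["regimen"].value_counts()
    if top_k is not None and len(counts) > top_k:
        top = counts.iloc[:top_k]
        other = counts.iloc[top_k:].sum()
        counts = pd.concat([top, pd.Series({"other": other})])
    out = pd.DataFrame({
        "regimen": counts.index,
        "n": counts.to_numpy(),
    })
    out["pct"] = [round_half_up(100.0 * c / denom, 1) for c in out["n"]]
    return out.reset_index(drop=True)


def _num_summary(values: pd.Series) -> dict:
    values = values.dropna().astype(float)
    if values.empty:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan,
                "min": np.nan, "max": np.nan}
    return {
        "mean": round_half_up(float(values.mean()), 1),
        "sd": round_half_up(float(values.std(ddof=1)), 2) if len(values) > 1 else np.nan,
        "median": round_half_up(float(values.median()), 1),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def table1_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographic and clinical summary, stratified by the SCT x renal
    subgroups, for the eligible population.

    Returns a long-format table: (stratum, item, n, pct, mean, sd, median,
    min, max).  Strata are ``eligible`` plus the four SCT x renal cells;
    the four cells partition the eligible population.
    """
    eligible = cohort[cohort["eligible"]]
    strata = {"eligible": eligible}
    for sct in (True, False):
        for renal in (True, False):
            key = (f"sct_{'conducted' if sct else 'not_conducted'}"
                   f"_{'with' if renal else 'without'}_renal")
            strata[key] = eligible[
                (eligible["sct_conducted"] == sct)
                & (eligible["renal_impairment"] == renal)
            ]
    rows = []

    def add(stratum, item, n=np.nan, pct=np.nan, **num):
        rows.append({"stratum": stratum, "item": item, "n": n, "pct": pct,
                     "mean": num.get("mean", np.nan), "sd": num.get("sd", np.nan),
                     "median": num.get("median", np.nan),
                     "min": num.get("min", np.nan), "max": num.get("max", np.nan)})

    for name, g in strata.items():
        total = len(g)
        add(name, "N", n=total)

        def pct(k):
            return round_half_up(100.0 * k / total, 1) if total else np.nan

        for sex, label in (("F", "female"), ("M", "male")):
            k = int((g["sex"] == sex).sum())
            add(name, label, n=k, pct=pct(k))
        for era in ("2003-2015", "2016-2020"):
            k = int((g["era"] == era).sum())
            add(name, f"era_{era}", n=k, pct=pct(k))
        add(name, "age", **_num_summary(g["age"]))
        for band, lo, hi in AGE_BANDS:
            k = int(g["age"].between(lo, hi).sum())
            add(name, f"age_{band}", n=k, pct=pct(k))
        add(name, "cci", **_num_summary(g["cci"]))
        for level in ("0", "1", "2", "3", "4+"):
            if level == "4+":
                k = int((g["cci"] >= 4).sum())
            else:
                k = int((g["cci"] == int(level)).sum())
            add(name, f"cci_{level}", n=k, pct=pct(k))
    return pd.DataFrame(rows)
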