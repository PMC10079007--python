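"""Synthetic DPC-style claims generator with exported ground truth.

The generator emulates the record structure of a Japanese hospital-claims
extract for a multiple-myeloma population: confirmed MM diagnoses coded as
ICD-10 C90.0 plus a local disease code, drug administration histories that
form named regimens (Vd, VRd, Rd, MP, ...), stem-cell-transplant procedure
records, baseline comorbidity and renal-impairment diagnoses, inpatient
death via hospital discharge records, and routine visit claims that keep
enrolment continuous.

Every planted construct is exported as ground truth (true index dates,
eligibility verdicts, subgroup labels, therapy lines with end reasons and
death dates) so each downstream stage has a known-answer test bed.  The
planted schedules respect the line-derivation rules by construction:
within a line, consecutive administrations of each drug stay strictly
inside its grace period; between lines, gaps strictly exceed every grace
period plus the discontinuation slack unless the transition is a switch.

Contaminant patients violating a single eligibility rule each are mixed in
at configurable rates; the generator records the violated rule so the
cohort stage's rejections can be verified reason by reason.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codes
from .bundle import ClaimsBundle, GroundTruth, PatientTimeline
from .config import ConfigError, RegimenSpec, SimulationConfig

__all__ = ["generate_population", "inject_contaminant", "write_population"]

ERA_PRE, ERA_POST = "2003-2015", "2016-2020"

# Regimen-share weight tables by era and treatment phase.  First-line
# shares plant the study conditions the analysis reports (e.g. Vd the
# dominant pre-2016 induction regimen, VRd afterwards); later-line shares
# reflect the drift toward triplets containing post-2015 agents.
SCT_INDUCTION_WEIGHTS = {
    ERA_PRE: {"Vd": 0.539, "VCd": 0.20, "VAD": 0.11, "VRd": 0.07, "Rd": 0.081},
    ERA_POST: {"VRd": 0.443, "Vd": 0.28, "VCd": 0.17, "DRd": 0.057, "Rd": 0.05},
}
POST_SCT_WEIGHTS = {
    ERA_PRE: {"Rd": 0.503, "Vd": 0.21, "VRd": 0.14, "MP": 0.147},
    ERA_POST: {"Rd": 0.495, "VRd": 0.21, "IRd": 0.15, "DRd": 0.145},
}
NONSCT_FIRSTLINE_WEIGHTS = {
    ERA_PRE: {"Vd": 0.399, "MP": 0.215, "Rd": 0.12, "VMP": 0.10,
              "Cy+Dex": 0.086, "VCd": 0.08},
    ERA_POST: {"Vd": 0.363, "Rd": 0.309, "VRd": 0.12, "DRd": 0.10,
               "VMP": 0.058, "MP": 0.05},
}
LATER_LINE_WEIGHTS = {
    ERA_PRE: {"Rd": 0.30, "Vd": 0.25, "MP": 0.15, "VCd": 0.15, "Cy+Dex": 0.15},
    ERA_POST: {"Rd": 0.25, "DRd": 0.25, "IRd": 0.15, "KRd": 0.15,
               "Vd": 0.10, "VCd": 0.10},
}

# Benign visit codes (not in the Charlson mapping, never exclusions).
VISIT_CODES = ("I10", "E78.5", "M54.5", "J30.1", "K21.0")
# Charlson-relevant baseline comorbidities for Table-1-style realism.
COMORBIDITY_CODES = ("E11.9", "I50.0", "J44.9", "K25.9", "I63.9", "M05.9")
RENAL_SAMPLE = ("N18.3", "N18.5", "I12.0", "Z49.1", "N03.2", "Z99.2")
OTHER_CANCER_SAMPLE = ("C34.1", "C18.0", "C61", "C50.9")
METASTATIC_SAMPLE = ("C78.0", "C79.5")


@dataclass
class TruthLine:
    line_number: int
    regimen: str
    drugs: frozenset
    start: dt.date
    end: dt.date
    end_reason: str
    phase: str = ""
    # internal bookkeeping
    admins: dict = field(default_factory=dict)      # drug -> list[date]
    alive_until: dt.date = None


@dataclass
class PatientPlan:
    """Internal per-patient scratch record assembled by the generator."""

    patient_id: str
    era: str
    index_date: dt.date
    birth_year: int
    sex: str
    data_start: dt.date
    data_end: dt.date = None
    sct_date: dt.date = None
    renal: bool = False
    death_date: dt.date = None
    violated_rule: str = None
    lines: list = field(default_factory=list)
    diagnoses: list = field(default_factory=list)
    drug_rows: list = field(default_factory=list)
    procedures: list = field(default_factory=list)
    hospitalizations: list = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return self.violated_rule is None


def _days(rng, lo: int, hi: int) -> int:
    """Uniform integer in [lo, hi]."""
    return int(rng.integers(lo, hi + 1))


def _weighted_choice(rng, weights: dict[str, float]) -> str:
    names = list(weights)
    p = np.asarray([weights[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=p / p.sum()))]


def _line_duration(rng, spec: RegimenSpec) -> int:
    max_cad = max(spec.cadence_days.values())
    mu = math.log(spec.median_duration_days)
    dur = int(round(float(rng.lognormal(mu, spec.duration_sigma))))
    return max(dur, 2 * max_cad, 42)


def _admin_schedule(spec: RegimenSpec, start: dt.date, duration: int) -> dict:
    """Per-drug administration dates from line start over the duration."""
    out = {}
    for drug, cad in spec.cadence_days.items():
        dates = [start + dt.timedelta(days=k)
                 for k in range(0, duration + 1, cad)]
        out[drug] = dates
    return out


def _alive_until(admins: dict, grace) -> dt.date:
    slack = grace.discontinuation_slack_days
    return max(
        dates[-1] + dt.timedelta(days=grace.grace(d) + slack)
        for d, dates in admins.items() if dates
    )


def _has_new_nonsteroid(prev: frozenset, spec: RegimenSpec, grace) -> bool:
    return any(d not in prev and not grace.is_steroid(d) for d in spec.drugs)


def _plan_treatment(plan: PatientPlan, config: SimulationConfig, rng,
                    sct: bool) -> None:
    """Plant the therapy lines, drug schedules and (for SCT patients) the
    transplant date.  Death truncation happens later."""
    catalog = {s.name: s for s in config.catalog()}
    grace = config.grace
    n_target = 1
    while (n_target < config.max_lines
           and rng.random() < config.continuation_prob[
               min(n_target - 1, len(config.continuation_prob) - 1)]):
        n_target += 1
    if sct and n_target < 2 and rng.random() < 0.7:
        n_target = 2  # most transplanted patients get post-SCT therapy

    # draw the regimen sequence up front so transition planning and the
    # actual next line always agree
    names = []
    for k in range(1, n_target + 1):
        if sct and k == 1:
            table = SCT_INDUCTION_WEIGHTS[plan.era]
        elif sct and k == 2:
            table = POST_SCT_WEIGHTS[plan.era]
        elif k == 1:
            table = NONSCT_FIRSTLINE_WEIGHTS[plan.era]
        else:
            table = LATER_LINE_WEIGHTS[plan.era]
        names.append(_weighted_choice(rng, table))

    start = plan.index_date + dt.timedelta(days=_days(rng, 7, 45))
    for k in range(1, n_target + 1):
        spec = catalog[names[k - 1]]
        duration = _line_duration(rng, spec)
        admins = _admin_schedule(spec, start, duration)
        end_admin = max(dates[-1] for dates in admins.values())
        line = TruthLine(
            line_number=k,
            regimen=spec.name,
            drugs=frozenset(spec.drugs),
            start=start,
            end=end_admin,
            end_reason="discontinuation-gap",
            admins=admins,
            alive_until=_alive_until(admins, grace),
        )
        plan.lines.append(line)
        if k == n_target:
            break
        # transition to the next line
        if sct and k == 1:
            plan.sct_date = end_admin + dt.timedelta(days=_days(rng, 30, 50))
            start = plan.sct_date + dt.timedelta(days=_days(rng, 30, 72))
        else:
            want_switch = rng.random() < config.switch_prob
            if want_switch and _has_new_nonsteroid(line.drugs, catalog[names[k]], grace):
                t_s = end_admin + dt.timedelta(days=_days(rng, 3, 15))
                line.end = t_s - dt.timedelta(days=1)
                line.end_reason = "switch"
                start = t_s
            else:
                start = end_admin + dt.timedelta(
                    days=_days(rng, config.gap_days[0], config.gap_days[1]))
    if sct and plan.sct_date is None:
        # transplanted but no further planted line
        plan.sct_date = plan.lines[-1].end + dt.timedelta(days=_days(rng, 30, 50))


def _apply_death(plan: PatientPlan, death_date: dt.date, grace) -> None:
    """Truncate the planted schedule at death, re-deriving the terminal
    line's end reason exactly as the derivation rules would."""
    kept = []
    for i, line in enumerate(plan.lines):
        if death_date < line.start:
            break  # death before this line starts: it and later lines vanish
        nxt = plan.lines[i + 1] if i + 1 < len(plan.lines) else None
        if nxt is not None and nxt.start <= death_date:
            kept.append(line)  # death belongs to a later line
            continue
        if death_date <= line.end:
            # death inside the line; nudge it past the point where every
            # member drug has its second administration so the regimen
            # stays established
            max_cad = max((dates[1] - dates[0]).days
                          for dates in line.admins.values() if len(dates) > 1)
            death_date = max(death_date, line.start + dt.timedelta(days=max_cad))
            line.admins = {d: [t for t in dates if t <= death_date]
                           for d, dates in line.admins.items()}
            line.end = death_date
            line.end_reason = "death"
        elif death_date <= line.alive_until:
            # death in the silence after the last administration but
            # before discontinuation could be declared
            line.end = death_date
            line.end_reason = "death"
        else:
            # death after the line lapsed, before any further treatment
            line.end = max(dates[-1] for dates in line.admins.values())
            line.end_reason = "discontinuation-gap"
        kept.append(line)
        break
    for j, line in enumerate(kept):
        line.line_number = j + 1
    plan.lines = kept
    plan.death_date = death_date
    plan.data_end = death_date
    if plan.sct_date is not None and plan.sct_date > death_date:
        plan.sct_date = None


def _finish_followup(plan: PatientPlan, config: SimulationConfig, rng) -> None:
    """Set the data end for surviving patients and the final line's reason."""
    grace = config.grace
    if not plan.lines:
        plan.data_end = plan.index_date + dt.timedelta(
            days=61 + _days(rng, config.tail_followup_days[0],
                            config.tail_followup_days[1]))
        return
    last = plan.lines[-1]
    if rng.random() < config.still_on_therapy_prob:
        # data ends while the line is still alive -> censored by data end
        min_grace = min(grace.grace(d) for d in last.drugs)
        offset = _days(rng, 0, min_grace + grace.discontinuation_slack_days - 1)
        data_end = last.end + dt.timedelta(days=offset)
        data_end = max(data_end, plan.index_date + dt.timedelta(days=61))
        last.end = data_end
        last.end_reason = "data-end"
        plan.data_end = data_end
    else:
        plan.data_end = last.end + dt.timedelta(
            days=_days(rng, config.tail_followup_days[0],
                       config.tail_followup_days[1]))


def _emit_claims(plan: PatientPlan, config: SimulationConfig, rng) -> None:
    """Materialise diagnosis / drug / procedure / hospitalization rows."""
    mm = codes.load_mm_codes()
    dictionary = codes.load_drug_dictionary()
    jp = mm["japanese_disease_codes"]
    index = plan.index_date

    # index MM diagnosis (confirmed, both code systems on the same record)
    plan.diagnoses.append((index, "C90.0", jp[_days(rng, 0, len(jp) - 1)], True))
    # follow-up MM records
    t = index + dt.timedelta(days=_days(rng, 30, 90))
    while t < plan.data_end:
        plan.diagnoses.append((t, "C90.0", jp[_days(rng, 0, len(jp) - 1)], True))
        t += dt.timedelta(days=_days(rng, 60, 180))

    # routine visits keep enrolment continuous (gap <= 60 days)
    t = plan.data_start
    while t <= plan.data_end:
        code = VISIT_CODES[_days(rng, 0, len(VISIT_CODES) - 1)]
        confirmed = rng.random() < 0.8
        plan.diagnoses.append((t, code, "-", confirmed))
        t += dt.timedelta(days=_days(rng, 20, 60))

    coverage = (index - plan.data_start).days
    # baseline comorbidities (about a third of patients)
    if rng.random() < 0.35 and coverage > 30:
        n = _days(rng, 1, 2)
        for _ in range(n):
            code = COMORBIDITY_CODES[_days(rng, 0, len(COMORBIDITY_CODES) - 1)]
            back = _days(rng, 1, coverage - 1)
            plan.diagnoses.append((index - dt.timedelta(days=back), code, "-", True))
    if plan.renal and coverage > 15:
        code = RENAL_SAMPLE[_days(rng, 0, len(RENAL_SAMPLE) - 1)]
        back = _days(rng, 1, min(360, coverage - 1))
        plan.diagnoses.append((index - dt.timedelta(days=back), code, "-", True))
    if plan.violated_rule == "baseline_malignancy":
        pool = OTHER_CANCER_SAMPLE + METASTATIC_SAMPLE
        code = pool[_days(rng, 0, len(pool) - 1)]
        back = _days(rng, 10, max(11, min(330, coverage - 1)))
        plan.diagnoses.append((index - dt.timedelta(days=back), code, "-", True))

    # drug administrations
    for line in plan.lines:
        for drug, dates in line.admins.items():
            info = dictionary[drug]
            supply = min(config.grace.grace(drug) - 14, 30) if info["route"] == "oral" else 1
            for d in dates:
                plan.drug_rows.append((d, drug, max(supply, 1), info["route"]))

    # procedures
    if plan.sct_date is not None:
        plan.procedures.append((plan.sct_date, "SCT"))

    # hospitalizations
    if plan.death_date is not None:
        adm = max(plan.death_date - dt.timedelta(days=_days(rng, 2, 15)),
                  plan.data_start)
        plan.hospitalizations.append((adm, plan.death_date, True))
    elif rng.random() < 0.25:
        span = (plan.data_end - index).days
        if span > 30:
            adm = index + dt.timedelta(days=_days(rng, 0, span - 25))
            dis = adm + dt.timedelta(days=_days(rng, 3, 21))
            plan.hospitalizations.append((adm, min(dis, plan.data_end), False))

    plan.diagnoses.sort(key=lambda r: r[0])
    plan.drug_rows.sort(key=lambda r: (r[0], r[1]))


def _verify_truth_verdict(plan: PatientPlan, config: SimulationConfig) -> None:
    """Record the eligibility verdict implied by the planted facts, in the
    fixed rule order.  For contaminants this re-confirms the injected rule;
    for clean patients whose random draws happened to break a rule (e.g. a
    short-baseline transplant candidate who died before the transplant),
    the verdict is downgraded honestly."""
    index = plan.index_date
    age = index.year - plan.birth_year
    if age < 20:
        plan.violated_rule = "age_under_20"
        return
    has_sct = plan.sct_date is not None
    if (index - plan.data_start).days < 365 and not has_sct:
        plan.violated_rule = "missing_baseline"
        return
    followup = (plan.data_end - index).days
    if followup < 60 and plan.death_date is None:
        plan.violated_rule = "short_followup_no_death"
        return
    if plan.violated_rule not in (None, "baseline_malignancy"):
        # injected rule no longer holds (should not happen)
        plan.violated_rule = None


def _generate_patient(pid: str, config: SimulationConfig, rng) -> PatientPlan:
    # contaminant assignment
    rule = None
    u = float(rng.random())
    acc = 0.0
    for r, p in config.contaminant_rates.items():
        acc += p
        if u < acc:
            rule = r
            break

    era = ERA_PRE if rng.random() < config.era_mix[ERA_PRE] else ERA_POST
    year = _days(rng, 2003, 2015) if era == ERA_PRE else _days(rng, 2016, 2020)
    index = dt.date(year, 1, 1) + dt.timedelta(days=_days(rng, 0, 364))

    treated = rule != "short_followup_no_death" and rng.random() < config.treated_prob
    sct = treated and rule is None and rng.random() < config.sct_fraction

    if rule == "age_under_20":
        age = _days(rng, 12, 19)
    elif sct:
        age = int(np.clip(round(rng.normal(58, 7)), 40, 69))
    else:
        age = int(np.clip(round(rng.normal(73, 10)), 20, 99))

    if rule == "missing_baseline":
        data_start = index - dt.timedelta(days=_days(rng, 30, 330))
    elif sct and rng.random() < 0.3:
        # short baseline, waived by the transplant record
        data_start = index - dt.timedelta(days=_days(rng, 90, 330))
    else:
        data_start = index - dt.timedelta(days=_days(rng, 365, 760))

    plan = PatientPlan(
        patient_id=pid,
        era=era,
        index_date=index,
        birth_year=year - age,
        sex="M" if rng.random() < 0.534 else "F",
        data_start=data_start,
        renal=rng.random() < config.renal_fraction,
        violated_rule=rule,
    )

    if treated:
        _plan_treatment(plan, config, rng, sct)

    if rule == "short_followup_no_death":
        plan.data_end = index + dt.timedelta(days=45)
    else:
        death_after = (float(rng.exponential(1.0 / config.death_hazard))
                       if config.death_hazard > 0 else math.inf)
        if math.isfinite(death_after):
            death_date = index + dt.timedelta(days=max(1, math.ceil(death_after)))
        else:
            death_date = None
        # provisional data end to bound the death draw
        _finish_followup(plan, config, rng)
        if death_date is not None and death_date < plan.data_end:
            _apply_death(plan, death_date, config.grace)

    # post-SCT phase labels from the planted transplant date
    for line in plan.lines:
        if plan.sct_date is None:
            line.phase = ""
        elif line.start < plan.sct_date:
            line.phase = "induction"
        elif (line.start - plan.sct_date).days <= 122:
            line.phase = "post-SCT"
        else:
            line.phase = "other"

    _verify_truth_verdict(plan, config)
    _emit_claims(plan, config, rng)
    return plan


def generate_population(config: SimulationConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a synthetic claims population with exported ground truth.

    Deterministic: the same configuration (including seed) reproduces the
    same tables byte for byte.
    """
    if not isinstance(config, SimulationConfig):
        raise ConfigError("config must be a SimulationConfig")
    rng = np.random.default_rng(config.seed)
    plans = [_generate_patient(f"P{i + 1:06d}", config, rng)
             for i in range(config.n_patients)]
    return _to_bundle(plans), _to_truth(plans)


def _to_bundle(plans: list[PatientPlan]) -> ClaimsBundle:
    pat, dx, rx, px, hosp = [], [], [], [], []
    for p in plans:
        pat.append((p.patient_id, p.birth_year, p.sex,
                    p.data_start, p.data_end))
        dx.extend((p.patient_id, d, code, local, conf)
                  for d, code, local, conf in p.diagnoses)
        rx.extend((p.patient_id, d, drug, supply, route)
                  for d, drug, supply, route in p.drug_rows)
        px.extend((p.patient_id, d, t) for d, t in p.procedures)
        hosp.extend((p.patient_id, a, b, flag)
                    for a, b, flag in p.hospitalizations)
    return ClaimsBundle(
        patients=pd.DataFrame(pat, columns=[
            "patient_id", "birth_year", "sex", "data_start", "data_end"]),
        diagnoses=pd.DataFrame(dx, columns=[
            "patient_id", "date", "icd10", "disease_code", "confirmed"]),
        drugs=pd.DataFrame(rx, columns=[
            "patient_id", "date", "drug", "days_supply", "route"]),
        procedures=pd.DataFrame(px, columns=[
            "patient_id", "date", "procedure_type"]),
        hospitalizations=pd.DataFrame(hosp, columns=[
            "patient_id", "admission_date", "discharge_date",
            "discharged_to_death"]),
    )


def _to_truth(plans: list[PatientPlan]) -> GroundTruth:
    pat, lines = [], []
    for p in plans:
        pat.append((
            p.patient_id, p.index_date, p.eligible,
            p.violated_rule or "", p.era,
            p.sct_date is not None, p.sct_date, p.renal, p.death_date,
            len(p.lines),
        ))
        for ln in p.lines:
            lines.append((
                p.patient_id, ln.line_number, ln.regimen,
                ln.start, ln.end, ln.end_reason, ln.phase,
            ))
    return GroundTruth(
        patients=pd.DataFrame(pat, columns=[
            "patient_id", "index_date", "eligible", "violated_rule", "era",
            "sct_conducted", "sct_date", "renal_impairment", "death_date",
            "n_lines"]),
        lines=pd.DataFrame(lines, columns=[
            "patient_id", "line_number", "regimen", "start", "end",
            "end_reason", "phase"]),
    )


def inject_contaminant(timeline: PatientTimeline, rule: str,
                       seed: int = 0) -> PatientTimeline:
    """Return a copy of ``timeline`` violating exactly the named
    eligibility rule (used to build adversarial fixtures by hand)."""
    import copy

    from .config import ELIGIBILITY_RULES

    if rule not in ELIGIBILITY_RULES:
        raise ValueError(f"unknown eligibility rule {rule!r}")
    if timeline.index_date is None:
        raise ValueError("timeline needs an index date before contamination")
    rng = np.random.default_rng(seed)
    t = copy.deepcopy(timeline)
    index = t.index_date
    if rule == "age_under_20":
        t.birth_year = index.year - 19
    elif rule == "missing_baseline":
        t.data_start = index - dt.timedelta(days=_days(rng, 30, 330))
        t.diagnoses = [d for d in t.diagnoses if d[0] >= t.data_start]
        t.drug_events = [d for d in t.drug_events if d[0] >= t.data_start]
        t.procedures = [p for p in t.procedures
                        if p[0] >= t.data_start and p[1] != "SCT"]
        t.hospitalizations = [h for h in t.hospitalizations
                              if h[0] >= t.data_start]
    elif rule == "baseline_malignancy":
        back = _days(rng, 10, 330)
        when = max(index - dt.timedelta(days=back), t.data_start)
        t.diagnoses.append((when, OTHER_CANCER_SAMPLE[0], "-", True))
        t.diagnoses.sort(key=lambda r: r[0])
    elif rule == "short_followup_no_death":
        cutoff = index + dt.timedelta(days=45)
        t.data_end = cutoff
        t.death_date = None
        t.diagnoses = [d for d in t.diagnoses if d[0] <= cutoff]
        t.drug_events = [d for d in t.drug_events if d[0] <= cutoff]
        t.procedures = [p for p in t.procedures if p[0] <= cutoff]
        t.hospitalizations = [h for h in t.hospitalizations
                              if h[1] <= cutoff and not h[2]]
    elif rule == "no_continuous_care":
        # carve a >180-day claim-free window straddling the index date
        lo = index - dt.timedelta(days=200)
        keep = lambda d: not (lo < d < index)
        t.diagnoses = [r for r in t.diagnoses if keep(r[0])]
        t.drug_events = [r for r in t.drug_events if keep(r[0])]
        t.procedures = [r for r in t.procedures if keep(r[0]) and r[1] != "SCT"]
        t.hospitalizations = [r for r in t.hospitalizations if keep(r[0])]
    return t


def write_population(config: SimulationConfig, out_dir) -> tuple[ClaimsBundle, GroundTruth]:
    bundle, truth = generate_population(config)
    bundle.write(out_dir)
    truth.write(out_dir)
    return bundle, truth
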