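# Methods

`claimlines` implements a treatment-pattern analysis pipeline for
multiple myeloma over DPC-style Japanese hospital claims: cohort
selection from raw event tables, rule-based derivation of lines of
therapy (LoT), and outcome statistics (attrition by line, treatment
duration, Kaplan–Meier time to inpatient death). Because real claims
extracts are proprietary, the package ships a synthetic claims generator
that plants known cohorts, lines and death times; every stage is
validated against that planted truth.

## Data model

Five delimited-text tables describe a population: a patient master
(birth year, sex, data window) and four longitudinal event tables —
diagnoses (date, ICD-10 code, Japanese local disease code,
confirmed-diagnosis flag), drug administrations (date, generic name,
days of supply, route), procedures (date, type; stem-cell
transplantation is the type `SCT`), and hospitalizations (admission,
discharge, discharged-to-death flag). Dates are calendar days; all
interval arithmetic is in whole days and intervals are closed on both
ends, matching the day granularity of claims.

## Cohort selection

The index diagnosis date is the earliest confirmed record carrying
ICD-10 C90.0 together with one of the eight Japanese local disease codes
for myeloma (2030003, 8839397, 8840039, 8842090, 8847152, 8847175,
8847250, 8847258); both codes must sit on the same dated record.
Unconfirmed (rule-out) records never index a patient.

Eligibility rules, evaluated in a fixed order with all violations
recorded:

1. age ≥ 20 years at index (age = index year − birth year);
2. ≥ 12 months (365 days) of data before index — waived whenever any
   SCT procedure record exists;
3. ≥ 60 days of follow-up after index, except patients with an inpatient
   death record before day 60;
4. continuous care: no claim-free gap longer than 180 days between
   consecutive claims inside the analysis window (threshold
   configurable). Claims enrolment is not explicit in hospital-claims
   extracts, so some gap-based proxy is unavoidable; 180 days is a
   common choice and the value is surfaced in `CohortConfig` rather than
   buried;
5. no baseline evidence of myeloma, another primary cancer, or
   metastatic disease: any C90.0 record dated before index inside the
   baseline window, any code in C00–C97 excluding C90.0, or any code in
   C77–C79. The cancer/metastasis code lists are configurable because
   the underlying concepts, not code lists, are what published analyses
   state.

The baseline window is `[index − 365 d, index)`; the index day itself
belongs to follow-up. Subgroup labels: index era (2003–2015 vs
2016–2020, split at index year ≥ 2016), SCT conducted (an SCT procedure
dated after index), and baseline renal impairment (any baseline
diagnosis in I12.0, I13.1, N03.2–N03.7, N05.2–N05.7, N18.x, N19.x,
N25.0, Z49.0–Z49.2, Z94.0, Z99.2; `x` wildcards expand by prefix
matching).

The Charlson Comorbidity Index uses the Quan ICD-10 coding algorithm
with the original Charlson weights; each category counts at most once
and hierarchical pairs (complicated over uncomplicated diabetes,
moderate/severe over mild liver disease, metastatic disease over any
malignancy) score only the severe member. Other mapping dialects can be
supplied as alternative YAML files.

## Line-of-therapy derivation

Three rules reconstruct regimens from dated drug administrations:

* **Establishment.** A drug founds a regimen only if it is administered
  again within its grace period. The grace period is the maximum
  interval between successive administrations for the drug to count as
  continuously given; defaults are 28 days for parenteral drugs and 42
  days for orals (a 28-day supply plus 14 days), reflecting typical 3–4
  week myeloma cycles and supply-aware persistence for oral agents. All
  values are per-drug configurable and recorded in the run manifest.
* **Addition.** A drug first administered within 28 days of the
  regimen's first administration — and itself persisting under its own
  grace period — joins the regimen rather than starting a new one.
* **Switch.** A drug outside the current regimen, newly administered
  while the regimen is still active and itself persisting, starts a new
  regimen on its first administration date. Drugs of the old regimen
  that continue past the switch join the new regimen through the
  addition window, so Rd plus newly persisting daratumumab becomes DRd.

A line of therapy ends at the earliest of: the day before a
switch-initiated regimen; the last administration once **every** member
drug has been silent for more than its grace period plus a 14-day slack
(discontinuation); the death date; or the end of the data, when either
falls inside the line's alive window. Line liveness is a union over
members: the line stays alive at a given day as long as at least one
member's last administration is within its own grace-plus-slack of that
day, so one drug may pause and resume while another carries the line.
Lines are numbered consecutively from 1; a restart of the same drug set
after a discontinuation gap starts a new line with the same regimen
name. Duration is the closed interval `end − start + 1` days; months
for reporting use 30.4375 days per month.

Steroids (dexamethasone, prednisolone) join regimens but by default
neither anchor a line nor trigger a switch; otherwise ubiquitous steroid
prescriptions would fragment lines into artifacts. The drug dictionary
covers anti-myeloma agents only — supportive-care drugs
(bisphosphonates, antivirals) are excluded, and unknown drug codes are
dropped with a warning.

Drug sets map to canonical regimen names (Vd, VRd, Rd, MP, VMP, VCd,
DRd, IRd, KRd, VAD, Cy+Dex) through a versioned YAML map; unmapped sets
render deterministically as the sorted `+`-joined drug abbreviations
with steroids last. For transplanted patients each line carries a phase
label: *induction* (initiated before the SCT date), *post-SCT*
(initiated within 4 months = 122 days after SCT), or *other*. Fixed
conversions — 12 months = 365 days, 4 months = 122 days — are applied
everywhere and noted here once.

## Outcome statistics

**Attrition.** For each line level L, frequency n(L) is the number of
patients reaching L, and % attrition = 100 × (1 − n(L)/n(L−1)) for
L ≥ 2, computed in exact decimal arithmetic and rounded half-up to one
decimal (printed tables round half-up, Python's built-in `round` does
not). Each patient's line at level L is classified into exactly one of:
*subsequent treatment* (a line L+1 exists), *death* (an inpatient death
record, no further line), *lost to follow-up* (data end within 60 days
of the line end without death), or *no subsequent treatment* (data
continue ≥ 60 days with neither). The 60-day boundary between lost to
follow-up and no subsequent treatment mirrors the 60-day follow-up
floor and is configurable; published analyses do not state the rule
they used, so this is a declared package decision. By construction,
end-reason counts sum to n(L) and the subsequent-treatment count at L
equals n(L+1).

**Kaplan–Meier.** Time to inpatient death is measured from each line's
start date by default (matching how per-line survival is reported),
with a configuration switch for index-date origin. Inpatient death is
the only death signal in DPC-style claims; all other patients are
right-censored at their data end. The product-limit estimator is
computed by `lifelines`; percentile summaries use the standard
convention (median = smallest time with S(t) ≤ 0.5, quartiles
likewise), deaths precede censorings at tied times, and a median the
curve never reaches is reported as the literal token `NE`. A
brute-force risk-set recomputation serves as an independent oracle in
the tests (agreement to 1e-12).

**Regimen shares.** Percentages are over patients in a phase × cohort
cell (each patient contributes the earliest qualifying line of the
phase); a top-k filter buckets the remainder as `other`.

## Synthetic claims generator

The generator's defaults emulate the population structure reported for
a large Japanese myeloma claims cohort: era mix 22.9 % / 77.1 %
(2003–2015 / 2016–2020), 53.4 % male, transplantation in ≈ 19.5 % of
treated patients with ages ≈ N(58, 7) years against N(73, 10) for the
non-transplanted, ≈ 1.8 % baseline renal impairment, and first-line
regimen mixes dominated by Vd in the early era and VRd/Rd in the late
era. Line continuation probabilities (0.60, 0.65, 0.60, 0.60, 0.55)
give per-line attrition in the 35–50 % range of the published table;
line durations are lognormal with regimen-specific medians (120–240
days, σ = 0.6); 90 % of eligible patients start therapy.

Planted schedules satisfy the derivation rules by construction: every
component drug is administered on a fixed cadence strictly inside its
grace period; inter-line gaps (70–160 days) strictly exceed every grace
period plus slack unless the transition is a switch, in which case the
new regimen starts 3–15 days after the previous line's last
administration, while it is still alive. A switch is only planted when
the next regimen introduces a non-steroid drug absent from the current
one; otherwise the transition falls back to a gap — exactly the
condition under which the rules themselves could not register a switch.
Transplants are placed 30–50 days after induction ends, with post-SCT
therapy starting 30–72 days after the transplant (inside the 122-day
window).

Inpatient death is exponential from index with per-day hazard 4e-4 by
default; death truncates the schedule, is nudged past each member
drug's second administration when it would otherwise land before the
regimen is established (claims after death cannot exist, and an
unestablished fragment would contradict the planted truth), and is
recorded as a discharged-to-death hospitalization. Survivors' data end
either inside the last line's alive window (still on therapy,
probability 0.25) or 70–400 days after it. Routine visit claims every
20–60 days keep enrolment continuous.

Contaminants violating a single eligibility rule each (age < 20, short
baseline without SCT, baseline malignancy, short follow-up without
death) are mixed in at configurable rates, one rule per patient so that
rejection-reason tests are unambiguous. The exported verdict is
computed from the planted facts at the end of generation, so rare
interactions (e.g. a short-baseline transplant candidate who dies
before the transplant, losing the baseline waiver) are recorded
honestly rather than asserted.

What the generator does **not** emulate: dosing intensity, costs or DPC
reimbursement structure; non-inpatient mortality; coding noise
(misspelled or out-of-dictionary codes beyond what tests inject);
irregular real-world administration timing *within* a line. Passing
round-trip tests therefore demonstrates that the engine implements the
stated rules exactly, not that the rules recover clinicians' intent on
real prescriptions, where grace-period choices genuinely matter.

## Validation strategy and problem sizes

* worked-example arithmetic (attrition, eligibility percentages)
  against published counts — exact;
* exact planted-line recovery (boundaries, names, end reasons) and
  contaminant rejection on a 500-patient population;
* property tests: equivalence of the event-driven engine with an
  independent day-stepping reference on randomized small inputs,
  translation invariance, gap monotonicity, order independence of
  cohort selection;
* Kaplan–Meier versus a brute-force oracle (100 random instances,
  n ≤ 50, heavy ties) to 1e-12;
* parameter recovery: planted exponential hazard 1.5e-3/day at
  n = 2000 with extended follow-up (600–1600 days past the last line),
  KM median within 10 % of ln 2 / λ ≈ 462 days.

Population sizes (150 for fixtures, 500 for recovery, 2000 for the
hazard study) keep the whole suite around ten seconds while leaving
hundreds of lines and dozens of contaminants per run.

## Known limitations

* Grace periods are analysis parameters, not facts; published analyses
  rarely state theirs, and derived lines can be sensitive to them.
* "Continuous care" and the lost-to-follow-up window are proxies with
  configurable thresholds, not observed enrolment.
* The engine requires both diagnosis code systems on the same dated
  record to index a patient; extracts that split them across claim
  lines would need a pre-join.
* Death is inpatient-only by design; survival estimates are for time to
  *inpatient* death and understate total mortality.
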