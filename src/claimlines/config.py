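"""Configuration objects for the simulation, cohort, line-derivation and
outcome stages.

Every threshold a reader might question (grace periods, the 28-day addition
window, the 14-day discontinuation slack, the continuous-care gap, the
lost-to-follow-up window) is an explicit field here rather than a constant,
so a run manifest can record exactly what was applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import codes

__all__ = [
    "ConfigError",
    "GraceConfig",
    "RegimenSpec",
    "SimulationConfig",
    "CohortConfig",
    "OutcomesConfig",
    "ELIGIBILITY_RULES",
]

# Eligibility rules in the fixed evaluation order.
ELIGIBILITY_RULES = (
    "age_under_20",
    "missing_baseline",
    "short_followup_no_death",
    "no_continuous_care",
    "baseline_malignancy",
)


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass(frozen=True)
class GraceConfig:
    """Persistence parameters of the line-of-therapy engine.

    grace_days
        Per-drug maximum interval (days) between successive administrations
        for the drug to count as continuously given.  Defaults come from
        the drug dictionary: 28 d for parenteral drugs, 42 d for orals
        (a 28-day supply plus 14 days).
    addition_window_days
        A drug administered within this many days of a regimen's first
        administration joins the regimen instead of starting a new one.
    discontinuation_slack_days
        Extra silence beyond a drug's grace period before the line is
        declared discontinued.
    """

    grace_days: dict[str, int] = field(default_factory=dict)
    addition_window_days: int = 28
    discontinuation_slack_days: int = 14
    steroid_neutral: bool = True  # steroids never anchor lines or trigger switches

    def __post_init__(self):
        if self.addition_window_days < 0:
            raise ConfigError("addition_window_days must be >= 0")
        if self.discontinuation_slack_days < 0:
            raise ConfigError("discontinuation_slack_days must be >= 0")
        for d, g in self.grace_days.items():
            if g < 1:
                raise ConfigError(f"grace_days[{d!r}] must be >= 1 day")

    def grace(self, drug: str) -> int:
        if drug in self.grace_days:
            return self.grace_days[drug]
        info = codes.load_drug_dictionary().get(drug)
        if info is None:
            raise KeyError(f"drug {drug!r} not in dictionary and no grace override")
        return info["grace_days"]

    def is_steroid(self, drug: str) -> bool:
        if not self.steroid_neutral:
            return False
        info = codes.load_drug_dictionary().get(drug)
        return bool(info and info["steroid"])


@dataclass(frozen=True)
class RegimenSpec:
    """One entry of the simulator's regimen catalog.

    cadence_days maps each component drug to its administration interval;
    intervals must stay strictly inside the drug's grace period so planted
    lines never fragment.
    """

    name: str
    drugs: tuple[str, ...]
    cadence_days: dict[str, int]
    median_duration_days: float = 180.0
    duration_sigma: float = 0.6  # lognormal shape on the duration

    def validate(self, grace: GraceConfig) -> None:
        dictionary = codes.load_drug_dictionary()
        for d in self.drugs:
            if d not in dictionary:
                raise ConfigError(f"regimen_catalog[{self.name}]: unknown drug {d!r}")
            cad = self.cadence_days.get(d)
            if cad is None or cad < 1:
                raise ConfigError(
                    f"regimen_catalog[{self.name}]: cadence_days missing/invalid for {d!r}"
                )
            if cad >= grace.grace(d):
                raise ConfigError(
                    f"regimen_catalog[{self.name}]: cadence {cad} d for {d!r} "
                    f"not strictly within its {grace.grace(d)} d grace period"
                )
        if not any(not grace.is_steroid(d) for d in self.drugs):
            raise ConfigError(
                f"regimen_catalog[{self.name}]: needs at least one non-steroid drug"
            )
        if self.median_duration_days <= 0:
            raise ConfigError(f"regimen_catalog[{self.name}]: duration must be positive")


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic claims generator (see docs/methods.md)."""

    n_patients: int = 200
    seed: int = 0
    # Mix of index eras (probabilities for 2003-2015 vs 2016-2020).
    era_mix: dict[str, float] = field(
        default_factory=lambda: {"2003-2015": 0.229, "2016-2020": 0.771}
    )
    sct_fraction: float = 0.195
    renal_fraction: float = 0.018
    # Probability of continuing to the next line given the current one.
    continuation_prob: tuple[float, ...] = (0.60, 0.65, 0.60, 0.60, 0.55)
    switch_prob: float = 0.35  # line transition is a switch (vs a gap)
    gap_days: tuple[int, int] = (70, 160)  # inter-line gap range (gap transitions)
    death_hazard: float = 4e-4  # per-day hazard of inpatient death from index
    treated_prob: float = 0.9   # eligible patients who start any therapy
    still_on_therapy_prob: float = 0.25  # last line censored by data end
    tail_followup_days: tuple[int, int] = (70, 400)  # data continues after last line
    contaminant_rates: dict[str, float] = field(
        default_factory=lambda: {
            "age_under_20": 0.02,
            "missing_baseline": 0.03,
            "baseline_malignancy": 0.03,
            "short_followup_no_death": 0.02,
        }
    )
    max_lines: int = 6
    regimen_catalog: tuple[RegimenSpec, ...] = ()
    grace: GraceConfig = field(default_factory=GraceConfig)

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigError("n_patients must be a non-negative integer")
        if abs(sum(self.era_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("era_mix proportions must sum to 1")
        _check_prob(self.sct_fraction, "sct_fraction")
        _check_prob(self.renal_fraction, "renal_fraction")
        _check_prob(self.switch_prob, "switch_prob")
        _check_prob(self.treated_prob, "treated_prob")
        _check_prob(self.still_on_therapy_prob, "still_on_therapy_prob")
        if self.tail_followup_days[0] <= 0 \
                or self.tail_followup_days[1] < self.tail_followup_days[0]:
            raise ConfigError("tail_followup_days must be a positive (low, high) range")
        for i, p in enumerate(self.continuation_prob):
            _check_prob(p, f"continuation_prob[{i}]")
        if not (0.0 <= self.death_hazard < 1.0):
            raise ConfigError("death_hazard must be a per-day probability in [0, 1)")
        if self.gap_days[0] <= 0 or self.gap_days[1] < self.gap_days[0]:
            raise ConfigError("gap_days must be a positive (low, high) range")
        for rule, p in self.contaminant_rates.items():
            if rule not in ELIGIBILITY_RULES:
                raise ConfigError(f"contaminant_rates: unknown rule {rule!r}")
            _check_prob(p, f"contaminant_rates[{rule}]")
        if sum(self.contaminant_rates.values()) > 1.0:
            raise ConfigError("contaminant_rates must sum to <= 1")
        if self.regimen_catalog:
            for spec in self.regimen_catalog:
                spec.validate(self.grace)

    def catalog(self) -> tuple[RegimenSpec, ...]:
        return self.regimen_catalog or default_regimen_catalog()


def default_regimen_catalog() -> tuple[RegimenSpec, ...]:
    """Catalog of the named regimens with field-typical cadences (days)."""

    def spec(name, cad, median=180.0):
        drugs = tuple(cad)
        return RegimenSpec(name=name, drugs=drugs, cadence_days=dict(cad),
                           median_duration_days=median)

    return (
        spec("Vd", {"bortezomib": 7, "dexamethasone": 7}, 150),
        spec("VRd", {"bortezomib": 7, "lenalidomide": 28, "dexamethasone": 7}, 120),
        spec("Rd", {"lenalidomide": 28, "dexamethasone": 28}, 240),
        spec("MP", {"melphalan": 35, "prednisolone": 35}, 210),
        spec("VMP", {"bortezomib": 7, "melphalan": 35, "prednisolone": 35}, 210),
        spec("VCd", {"bortezomib": 7, "cyclophosphamide": 21, "dexamethasone": 7}, 150),
        spec("DRd", {"daratumumab": 14, "lenalidomide": 28, "dexamethasone": 14}, 240),
        spec("IRd", {"ixazomib": 28, "lenalidomide": 28, "dexamethasone": 28}, 210),
        spec("KRd", {"carfilzomib": 7, "lenalidomide": 28, "dexamethasone": 7}, 180),
        spec("VAD", {"vincristine": 21, "doxorubicin": 21, "dexamethasone": 21}, 120),
        spec("Cy+Dex", {"cyclophosphamide": 21, "dexamethasone": 21}, 150),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-selection thresholds (explicit operationalisations)."""

    baseline_days: int = 365
    min_followup_days: int = 60
    continuous_care_gap_days: int = 180
    min_age: int = 20
    other_cancer_prefixes: tuple[str, ...] = codes.OTHER_CANCER_PREFIXES
    metastatic_prefixes: tuple[str, ...] = codes.METASTATIC_PREFIXES

    def __post_init__(self):
        for f in ("baseline_days", "min_followup_days", "continuous_care_gap_days"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f} must be positive")


@dataclass(frozen=True)
class OutcomesConfig:
    """Outcome-reporting settings."""

    lost_to_followup_window_days: int = 60
    time_origin: str = "line"  # "line": per-line start; "index": index date

    def __post_init__(self):
        if self.time_origin not in ("line", "index"):
            raise ConfigError("time_origin must be 'line' or 'index'")
        if self.lost_to_followup_window_days <= 0:
            raise ConfigError("lost_to_followup_window_days must be positive")
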