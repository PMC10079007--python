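"""End-to-end orchestration: claims tables -> cohort -> therapy lines ->
outcome tables, with a run manifest for traceability.

Stage outputs are pure functions of (inputs, configuration, seed): running
the pipeline twice on the same inputs produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import codes
from ._util import as_date
from .bundle import ClaimsBundle
from .cohort import build_cohort, timelines_from_bundle
from .config import (CohortConfig, ConfigError, GraceConfig, OutcomesConfig,
                     SimulationConfig)
from .lot import classify_post_sct, derive_lines
from .outcomes import (attrition_table, km_estimate, regimen_share_table,
                       table1_summary, time_to_death_table)
from .simulate import generate_population

logger = logging.getLogger(__name__)

__all__ = ["derive_population_lines", "run_pipeline", "load_config"]


def derive_population_lines(bundle: ClaimsBundle, cohort: pd.DataFrame,
                            grace: GraceConfig | None = None) -> pd.DataFrame:
    """Derive numbered therapy lines for every eligible patient.

    Drug events before the index date are outside the treatment window and
    ignored.  For transplanted patients each line also carries its phase
    label (induction / post-SCT / other).
    """
    grace = grace or GraceConfig()
    eligible = cohort[cohort["eligible"]].set_index("patient_id")
    sct_dates: dict[str, dt.date] = {}
    for r in bundle.procedures.itertuples():
        if r.procedure_type == "SCT":
            d = as_date(r.date)
            if r.patient_id not in sct_dates or d < sct_dates[r.patient_id]:
                sct_dates[r.patient_id] = d
    rows = []
    for pid, g in bundle.drugs.groupby("patient_id", sort=False):
        if pid not in eligible.index:
            continue
        info = eligible.loc[pid]
        index_date = info["index_date"]
        events = [(as_date(r.date), str(r.drug)) for r in g.itertuples()
                  if as_date(r.date) >= index_date]
        if not events:
            continue
        death = info["death_date"]
        death = None if pd.isna(death) else death
        lines = derive_lines(events, death_date=death,
                             data_end=info["data_end"], grace=grace)
        sct = sct_dates.get(pid)
        phases = (classify_post_sct(lines, sct)
                  if sct is not None and sct > index_date else [""] * len(lines))
        for line, phase in zip(lines, phases):
            rows.append({
                "patient_id": pid,
                "line_number": line.line_number,
                "regimen": line.regimen,
                "start": line.start,
                "end": line.end,
                "duration_days": line.duration_days,
                "end_reason": line.end_reason,
                "phase": phase,
            })
    return pd.DataFrame(rows, columns=[
        "patient_id", "line_number", "regimen", "start", "end",
        "duration_days", "end_reason", "phase"])


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline configuration must be a mapping")
    return cfg


def _build_stage_configs(cfg: dict):
    grace = GraceConfig(**cfg.get("grace", {}))
    sim = None
    if "simulate" in cfg:
        sim = SimulationConfig(grace=grace, **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg["simulate"].items()
        })
    cohort_cfg = CohortConfig(**cfg.get("cohort", {}))
    out_cfg = OutcomesConfig(**{k: v for k, v in cfg.get("outcomes", {}).items()
                                if k != "top_k"})
    top_k = cfg.get("outcomes", {}).get("top_k", 5)
    return grace, sim, cohort_cfg, out_cfg, top_k


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 events_dir: str | Path | None = None) -> dict:
    """Run every stage and write all output tables plus ``manifest.json``.

    ``config`` may be a YAML path or an already-parsed mapping with
    optional sections ``simulate``, ``grace``, ``cohort``, ``outcomes``.
    Either a ``simulate`` section or an events directory must be given.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    grace, sim, cohort_cfg, out_cfg, top_k = _build_stage_configs(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": sim.seed if sim is not None else None,
        "grace": {"addition_window_days": grace.addition_window_days,
                  "discontinuation_slack_days": grace.discontinuation_slack_days,
                  "overrides": dict(grace.grace_days)},
        "code_lists": {
            "mm": sorted(codes.load_mm_codes()["japanese_disease_codes"]),
            "renal_n": len(codes.load_renal_prefixes()),
            "drugs_n": len(codes.load_drug_dictionary()),
            "regimens_n": len(codes.load_regimen_map()),
        },
        "row_counts": {},
        "started": dt.datetime.now().isoformat(timespec="seconds"),
    }

    if sim is not None:
        bundle, truth = generate_population(sim)
        bundle.write(out / "events")
        truth.write(out / "events")
        manifest["row_counts"]["simulated_patients"] = len(bundle.patients)
    elif events_dir is not None or "events" in cfg:
        bundle = ClaimsBundle.read(events_dir or cfg["events"])
    else:
        raise ConfigError("config needs a 'simulate' section or an events directory")

    cohort = build_cohort(bundle, cohort_cfg)
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest["row_counts"]["indexed_patients"] = len(cohort)
    manifest["row_counts"]["eligible_patients"] = int(cohort["eligible"].sum())

    lines = derive_population_lines(bundle, cohort, grace)
    lines.to_csv(out / "lines.csv", index=False)
    manifest["row_counts"]["therapy_lines"] = len(lines)

    table1 = table1_summary(cohort)
    table1.to_csv(out / "table1.csv", index=False)

    eligible = cohort[cohort["eligible"]]
    km_curve_rows, km_summary_rows = [], []
    for era in ("2003-2015", "2016-2020"):
        era_ids = set(eligible.loc[eligible["era"] == era, "patient_id"])
        att = attrition_table(lines[lines["patient_id"].isin(era_ids)],
                              eligible, out_cfg)
        att.to_csv(out / f"attrition_{era}.csv", index=False)
        share = regimen_share_table(lines, phase="first-line",
                                    patient_ids=era_ids, top_k=top_k)
        share.to_csv(out / f"regimen_share_first_line_{era}.csv", index=False)
        for sct_flag, sct_name in ((True, "sct"), (False, "no_sct")):
            ids = set(eligible.loc[(eligible["era"] == era)
                                   & (eligible["sct_conducted"] == sct_flag),
                                   "patient_id"])
            sub = lines[lines["patient_id"].isin(ids)]
            if sub.empty:
                continue
            ttd = time_to_death_table(sub, eligible, out_cfg)
            for level, g in ttd.groupby("line"):
                est = km_estimate(g["time_days"], g["event"])
                km_summary_rows.append({
                    "era": era, "group": sct_name, "line": level,
                    "n": est.n, "events": int(g["event"].sum()),
                    "median_days": est.render(est.median),
                    "q25_days": est.render(est.q25),
                    "q75_days": est.render(est.q75),
                })
                for t, s, r in zip(est.times, est.survival, est.at_risk):
                    km_curve_rows.append({
                        "era": era, "group": sct_name, "line": level,
                        "time_days": t, "survival": s, "at_risk": r,
                    })
    pd.DataFrame(km_summary_rows).to_csv(out / "km_summary.csv", index=False)
    pd.DataFrame(km_curve_rows).to_csv(out / "km_curves.csv", index=False)

    manifest["finished"] = dt.datetime.now().isoformat(timespec="seconds")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", manifest["row_counts"])
    return manifest
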