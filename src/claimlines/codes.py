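"""Versioned code lists: MM case definition, renal-impairment ICD-10 set,
baseline-malignancy exclusions, the anti-myeloma drug dictionary, regimen
name map, and the Charlson/Quan comorbidity mapping.

All lists ship as YAML data files inside the package so that analyses are
traceable to an explicit code-list version rather than constants buried in
logic.  Every loader accepts an optional path override.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "load_mm_codes",
    "load_renal_prefixes",
    "load_drug_dictionary",
    "load_regimen_map",
    "load_charlson_map",
    "icd10_matches",
    "OTHER_CANCER_PREFIXES",
    "METASTATIC_PREFIXES",
]

# Baseline-exclusion concepts: other primary cancers (ICD-10 C chapter
# minus the MM code itself) and metastatic disease.  The source analysis
# names the concepts, not the code lists; these ranges are this package's
# operationalisation and can be overridden in cohort configuration.
OTHER_CANCER_PREFIXES: tuple[str, ...] = tuple(
    f"C{i:02d}" for i in range(0, 98) if i != 90
) + ("C90.1", "C90.2", "C90.3")
METASTATIC_PREFIXES: tuple[str, ...] = ("C77", "C78", "C79")


def _read_yaml(name: str, path: str | Path | None = None) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("claimlines.data").joinpath(name)
    with ref.open() as fh:
        return yaml.safe_load(fh)


def normalize_icd10(code: str) -> str:
    """Uppercase and strip an ICD-10 code, keeping the dot if present."""
    return str(code).strip().upper()


def icd10_matches(code: str, prefixes) -> bool:
    """Prefix match with dot-insensitive comparison.

    ``N183`` and ``N18.3`` both match the prefix ``N18``; ``I12.0`` matches
    only the four-character subcode.
    """
    code = normalize_icd10(code).replace(".", "")
    for p in prefixes:
        if code.startswith(p.replace(".", "").upper()):
            return True
    return False


@functools.lru_cache(maxsize=None)
def load_mm_codes(path: str | Path | None = None) -> dict:
    """MM case definition: ICD-10 code(s) + Japanese local disease codes."""
    raw = _read_yaml("mm_codes.yaml", path)
    return {
        "icd10": tuple(raw["icd10"]),
        "japanese_disease_codes": tuple(str(c) for c in raw["japanese_disease_codes"]),
    }


@functools.lru_cache(maxsize=None)
def load_renal_prefixes(path: str | Path | None = None) -> tuple[str, ...]:
    return tuple(_read_yaml("renal_codes.yaml", path)["prefixes"])


@functools.lru_cache(maxsize=None)
def load_drug_dictionary(path: str | Path | None = None) -> dict:
    """Anti-myeloma drug dictionary.

    Returns a dict ``name -> {route, abbrev, steroid, grace_days}`` where
    the per-drug grace period defaults by route (parenteral 28 d, oral
    42 d) unless the YAML specifies ``grace_days`` for the drug.
    """
    raw = _read_yaml("drugs.yaml", path)
    route_grace = raw["grace_days"]
    out = {}
    for name, info in raw["drugs"].items():
        info = dict(info)
        info.setdefault("grace_days", route_grace[info["route"]])
        out[name] = info
    return out


@functools.lru_cache(maxsize=None)
def load_regimen_map(path: str | Path | None = None) -> dict[frozenset, str]:
    """Map from frozenset of generic drug names to canonical regimen name."""
    raw = _read_yaml("regimens.yaml", path)["regimens"]
    out: dict[frozenset, str] = {}
    for name, drugs in raw.items():
        key = frozenset(drugs)
        if key in out:
            raise ValueError(f"regimen map not injective: {sorted(key)}")
        out[key] = name
    return out


@functools.lru_cache(maxsize=None)
def load_charlson_map(path: str | Path | None = None) -> dict:
    raw = _read_yaml("charlson_quan.yaml", path)
    return {
        "categories": {
            k: {"weight": v["weight"], "prefixes": tuple(v["prefixes"])}
            for k, v in raw["categories"].items()
        },
        "hierarchies": [tuple(h) for h in raw["hierarchies"]],
    }
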