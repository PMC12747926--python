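"""Analysis configuration: diagnosis code lists, drug dictionaries, windows, thresholds.

Diagnosis groups are always derived from these code lists — downstream code never
trusts a free-text group column.  The default ICD-9-CM / ICD-10-CM lists shipped
here are a documented stand-in for the study-specific supplementary code lists
(which are not public); they cover the standard codes for juvenile arthritis,
spondyloarthritis features, uveitis and psoriasis and can be replaced wholesale
from a YAML file via :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

# ICD-9-CM codes apply to claims dated strictly before this day; ICD-10-CM from it on.
ICD10_SWITCH_DATE = date(2016, 1, 1)

# Stand-in diagnosis code lists (synthetic defaults, not the study's proprietary lists).
DEFAULT_DX_CODES: dict[str, dict[str, list[str]]] = {
    "JIA": {
        "ICD9CM": ["714.30", "714.31", "714.32", "714.33"],
        "ICD10CM": ["M08.0", "M08.2", "M08.3", "M08.4", "M08.8", "M08.9"],
    },
    # ankylosing spondylitis, sacroiliitis, other inflammatory spondylopathies,
    # psoriatic arthropathy
    "SpA_feature": {
        "ICD9CM": ["720.0", "720.2", "720.8", "720.9", "696.0"],
        "ICD10CM": ["M45", "M46.1", "M46.8", "M46.9", "L40.5"],
    },
    "uveitis": {
        "ICD9CM": ["364.00", "364.3"],
        "ICD10CM": ["H20.0", "H20.9"],
    },
    "psoriasis": {
        "ICD9CM": ["696.1"],
        "ICD10CM": ["L40.0"],
    },
}

DEFAULT_DRUG_CLASSES: dict[str, list[str]] = {
    "NSAID": ["naproxen", "ibuprofen", "diclofenac", "celecoxib", "indomethacin"],
    "steroid": ["prednisolone", "methylprednisolone"],
    "csDMARD": ["methotrexate", "sulfasalazine", "hydroxychloroquine", "leflunomide"],
    "biologic": ["etanercept", "adalimumab", "tocilizumab", "abatacept"],
}

# Biologics eligible to serve as the index drug (abatacept is excluded from the
# pattern analysis but still counts as a biologic exposure for switch/restart).
INDEX_BIOLOGICS = ("etanercept", "adalimumab", "tocilizumab")

AGE_BANDS = ("0-5", "6-11", "12-15")
AGE_BAND_EDGES = (0, 6, 12, 16)  # completed years, half-open bands


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds and windows governing the whole pipeline."""

    study_start: date = date(2011, 1, 1)
    study_end: date = date(2021, 1, 1)           # half-open
    identification_start: date = date(2012, 1, 1)
    identification_end: date = date(2020, 1, 1)  # half-open
    followup_cutoff: date = date(2020, 12, 31)

    grace_nsaid_days: int = 14
    grace_steroid_days: int = 14
    grace_csdmard_days: int = 14
    grace_biologic_days: int = 60
    chronic_days: int = 90          # "more than three consecutive months"
    nsaid_min_span_days: int = 15   # "more than 14 consecutive days"
    case_window_days: int = 365     # outpatient-code and NSAID lookforward windows
    age_cutoff_years: int = 16      # "under 16 years of age at the index date"

    prevalence_mode: str = "cumulative"    # or "active_claim"
    spa_same_day_only: bool = False        # strict same-day co-occurrence switch
    event_definition: str = "index_drug"   # or "any_biologic" for drug survival

    dx_codes: dict = field(default_factory=lambda: DEFAULT_DX_CODES)
    drug_classes: dict = field(default_factory=lambda: DEFAULT_DRUG_CLASSES)

    def grace_for_class(self, drug_class: str) -> int:
        return {
            "NSAID": self.grace_nsaid_days,
            "steroid": self.grace_steroid_days,
            "csDMARD": self.grace_csdmard_days,
            "biologic": self.grace_biologic_days,
        }.get(drug_class, self.grace_nsaid_days)

    def code_group(self, code: str, code_system: str) -> str:
        """Map a diagnosis code to its analytic group; unknown codes -> 'other'."""
        for group, by_system in self.dx_codes.items():
            if code in by_system.get(code_system, ()):
                return group
        return "other"

    def drug_class_of(self, drug_name: str) -> str:
        for cls, names in self.drug_classes.items():
            if drug_name in names:
                return cls
        return "other"


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig`, optionally overriding defaults from YAML.

    Recognised YAML keys mirror the dataclass field names; dates are ISO strings.
    """
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    updates: dict = {}
    for f in dataclasses.fields(AnalysisConfig):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name.endswith(("_start", "_end", "_cutoff")) and isinstance(value, str):
            value = date.fromisoformat(value)
        updates[f.name] = value
    return dataclasses.replace(cfg, **updates)
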