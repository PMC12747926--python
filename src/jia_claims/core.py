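"""Core claims tables: schemas, the in-memory bundle, validation, and CSV I/O.

The analytic unit is a :class:`ClaimsBundle` of four flat tables held as pandas
DataFrames:

``beneficiaries``
    one row per enrollment interval: person_id, sex, birth_date,
    enroll_start, enroll_end (half-open).
``diagnoses``
    one coded diagnosis claim: person_id, date, setting (inpatient/outpatient),
    code, code_system (ICD9CM/ICD10CM), dx_group (derived from the code lists),
    visit_id.
``prescriptions``
    one dispensing: person_id, fill_date, days_supply, drug_class (derived),
    drug_name, visit_id.
``denominators``
    annual under-16 population by age band and sex: year, age_group, sex,
    person_count, person_years.

All dates are ISO-8601 calendar dates; all intervals are half-open
``[start, end)``.  Diagnosis claims use ICD-9-CM strictly before 2016-01-01 and
ICD-10-CM from that day on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .config import ICD10_SWITCH_DATE, AnalysisConfig

log = logging.getLogger(__name__)

BENEFICIARY_COLUMNS = ["person_id", "sex", "birth_date", "enroll_start", "enroll_end"]
DIAGNOSIS_COLUMNS = ["person_id", "date", "setting", "code", "code_system", "dx_group", "visit_id"]
PRESCRIPTION_COLUMNS = ["person_id", "fill_date", "days_supply", "drug_class", "drug_name", "visit_id"]
DENOMINATOR_COLUMNS = ["year", "age_group", "sex", "person_count", "person_years"]

TABLE_FILES = {
    "beneficiaries": "beneficiaries.csv",
    "diagnoses": "diagnoses.csv",
    "prescriptions": "prescriptions.csv",
    "denominators": "denominators.csv",
}

_DATE_COLUMNS = {
    "beneficiaries": ["birth_date", "enroll_start", "enroll_end"],
    "diagnoses": ["date"],
    "prescriptions": ["fill_date"],
    "denominators": [],
}

_SCHEMAS = {
    "beneficiaries": BENEFICIARY_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "prescriptions": PRESCRIPTION_COLUMNS,
    "denominators": DENOMINATOR_COLUMNS,
}


class BundleFormatError(ValueError):
    """A claims table could not be parsed into the expected schema."""


_EPOCH_ORDINAL = date(1970, 1, 1).toordinal()


def date_to_day(d: date) -> int:
    """Calendar date -> integer day (days since 1970-01-01)."""
    return d.toordinal() - _EPOCH_ORDINAL


def day_to_date(day: int) -> date:
    return date.fromordinal(int(day) + _EPOCH_ORDINAL)


def to_days(series: pd.Series):
    """datetime64 Series -> int64 ndarray of days since 1970-01-01."""
    return series.values.astype("datetime64[D]").astype("int64")


@dataclass
class Violation:
    """One invariant violation, with a reference back to the offending row."""

    table: str
    row: int | None
    rule: str
    message: str


@dataclass
class ClaimsBundle:
    beneficiaries: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    denominators: pd.DataFrame
    study_window: tuple[date, date] = (date(2011, 1, 1), date(2021, 1, 1))
    identification_window: tuple[date, date] = (date(2012, 1, 1), date(2020, 1, 1))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "beneficiaries": self.beneficiaries,
            "diagnoses": self.diagnoses,
            "prescriptions": self.prescriptions,
            "denominators": self.denominators,
        }


def empty_bundle(config: AnalysisConfig | None = None) -> ClaimsBundle:
    config = config or AnalysisConfig()
    frames = {}
    for name, cols in _SCHEMAS.items():
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for c in _DATE_COLUMNS[name]:
            df[c] = pd.Series(dtype="datetime64[ns]")
        frames[name] = df
    return ClaimsBundle(
        study_window=(config.study_start, config.study_end),
        identification_window=(config.identification_start, config.identification_end),
        **frames,
    )


def age_completed_years(birth: date, on: date) -> int:
    """Completed years of age on a given date (birthday convention)."""
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def expected_code_system(d: date) -> str:
    return "ICD9CM" if d < ICD10_SWITCH_DATE else "ICD10CM"


def validate_bundle(bundle: ClaimsBundle, config: AnalysisConfig | None = None) -> list[Violation]:
    """Check every bundle invariant; return one record per violation.

    An empty list means the bundle is valid.  Checks: the code-dialect switch at
    2016-01-01, derived diagnosis groups, event dates inside the study window,
    sorted non-overlapping enrollment, birth before enrollment, positive
    days_supply, drug name/class consistency, and denominator sanity.
    """
    config = config or AnalysisConfig()
    out: list[Violation] = []
    lo, hi = bundle.study_window
    ilo, ihi = bundle.identification_window
    if not (lo <= ilo and ihi <= hi):
        out.append(Violation("bundle", None, "window_nesting",
                             "identification window not contained in study window"))

    dx = bundle.diagnoses
    if len(dx):
        dates = dx["date"].dt.date
        expected = dates.map(expected_code_system)
        for i in dx.index[dx["code_system"] != expected]:
            out.append(Violation("diagnoses", int(i), "code_dialect",
                                 f"code_system {dx.at[i, 'code_system']} inconsistent "
                                 f"with date {dates[i]}"))
        for i in dx.index[(dates < lo) | (dates >= hi)]:
            out.append(Violation("diagnoses", int(i), "out_of_window",
                                 f"diagnosis dated {dates[i]} outside study window"))
        derived = [config.code_group(c, s) for c, s in zip(dx["code"], dx["code_system"])]
        for i, (got, want) in enumerate(zip(dx["dx_group"], derived)):
            if got != want:
                out.append(Violation("diagnoses", int(dx.index[i]), "dx_group",
                                     f"dx_group {got!r} does not match code list ({want!r})"))
        bad_setting = ~dx["setting"].isin(["inpatient", "outpatient"])
        for i in dx.index[bad_setting]:
            out.append(Violation("diagnoses", int(i), "setting",
                                 f"unknown setting {dx.at[i, 'setting']!r}"))

    rx = bundle.prescriptions
    if len(rx):
        fdates = rx["fill_date"].dt.date
        for i in rx.index[rx["days_supply"].astype(int) < 1]:
            out.append(Violation("prescriptions", int(i), "days_supply",
                                 "days_supply must be >= 1"))
        for i in rx.index[(fdates < lo) | (fdates >= hi)]:
            out.append(Violation("prescriptions", int(i), "out_of_window",
                                 f"fill dated {fdates[i]} outside study window"))
        for i in rx.index:
            name, cls = rx.at[i, "drug_name"], rx.at[i, "drug_class"]
            known = config.drug_class_of(name)
            if known != "other" and known != cls:
                out.append(Violation("prescriptions", int(i), "drug_class",
                                     f"{name} is {known}, recorded as {cls}"))

    ben = bundle.beneficiaries
    if len(ben):
        for i in ben.index[ben["enroll_start"] >= ben["enroll_end"]]:
            out.append(Violation("beneficiaries", int(i), "interval",
                                 "enrollment interval empty or inverted"))
        for i in ben.index[ben["birth_date"] > ben["enroll_start"]]:
            out.append(Violation("beneficiaries", int(i), "birth_order",
                                 "birth_date after enrollment start"))
        for pid, grp in ben.groupby("person_id", sort=False):
            if len(grp) < 2:
                continue
            g = grp.sort_values("enroll_start")
            overlap = g["enroll_start"].iloc[1:].values < g["enroll_end"].iloc[:-1].values
            for i, bad in zip(g.index[1:], overlap):
                if bad:
                    out.append(Violation("beneficiaries", int(i), "enroll_overlap",
                                         f"overlapping enrollment intervals for {pid}"))

    den = bundle.denominators
    if len(den):
        for i in den.index[den["person_years"] > den["person_count"] + 1e-9]:
            out.append(Violation("denominators", int(i), "person_years",
                                 "person_years exceeds person_count"))
        for i in den.index[den["person_count"].astype(float) < 0]:
            out.append(Violation("denominators", int(i), "person_count",
                                 "negative person_count"))
    return out


def _parse_dates(df: pd.DataFrame, table: str, cols: list[str], path: Path) -> pd.DataFrame:
    for c in cols:
        try:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise BundleFormatError(
                f"{path}: column {c!r} is not ISO-8601 (YYYY-MM-DD): {exc}") from exc
    return df


def read_bundle(directory: str | Path, config: AnalysisConfig | None = None) -> ClaimsBundle:
    """Load the four CSV tables from a directory into a typed bundle.

    Diagnosis groups and drug classes are re-derived from the configured code
    lists; unknown codes map to group ``other`` and the count is logged.
    """
    config = config or AnalysisConfig()
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for table, fname in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing claims table file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = [c for c in _SCHEMAS[table] if c not in ("dx_group", "drug_class")]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise BundleFormatError(f"{path}: missing required column(s) {missing}")
        df = _parse_dates(df, table, _DATE_COLUMNS[table], path)
        frames[table] = df

    dx = frames["diagnoses"]
    if len(dx):
        dx["dx_group"] = [config.code_group(c, s)
                          for c, s in zip(dx["code"], dx["code_system"])]
        n_unknown = int((dx["dx_group"] == "other").sum())
        if n_unknown:
            log.warning("%d diagnosis codes not in any configured list; mapped to 'other'",
                        n_unknown)
    else:
        dx["dx_group"] = pd.Series(dtype=object)

    rx = frames["prescriptions"]
    if len(rx):
        rx["days_supply"] = rx["days_supply"].astype(int)
        rx["drug_class"] = [config.drug_class_of(n) for n in rx["drug_name"]]
        n_unknown = int((rx["drug_class"] == "other").sum())
        if n_unknown:
            log.warning("%d drug names not in any configured class; mapped to 'other'",
                        n_unknown)
    else:
        rx["drug_class"] = pd.Series(dtype=object)
        rx["days_supply"] = pd.Series(dtype=int)

    den = frames["denominators"]
    if len(den):
        den["year"] = den["year"].astype(int)
        den["person_count"] = den["person_count"].astype(int)
        den["person_years"] = den["person_years"].astype(float)
    else:
        den["year"] = pd.Series(dtype=int)
        den["person_count"] = pd.Series(dtype=int)
        den["person_years"] = pd.Series(dtype=float)

    return ClaimsBundle(
        beneficiaries=frames["beneficiaries"][BENEFICIARY_COLUMNS],
        diagnoses=dx[DIAGNOSIS_COLUMNS],
        prescriptions=rx[PRESCRIPTION_COLUMNS],
        denominators=den[DENOMINATOR_COLUMNS],
        study_window=(config.study_start, config.study_end),
        identification_window=(config.identification_start, config.identification_end),
    )


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> None:
    """Write the four tables as CSV; ``read_bundle`` round-trips the result."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table, df in bundle.tables().items():
        out = df.copy()
        for c in _DATE_COLUMNS[table]:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / TABLE_FILES[table], index=False)
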