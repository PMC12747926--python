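"""Prevalence and incidence estimation over annual under-16 denominators.

Annual prevalence divides the prevalent cases counted in a year by the under-16
population of that year; annual incidence proportion divides newly diagnosed
cases by the at-risk headcount (under-16 population minus previously diagnosed
and still-pediatric cases); the overall incidence rate divides all incident
cases in a window by the accumulated under-16 person-years.  All rates are per
100,000.  Rates are crude — no age standardisation.

The default prevalence numerator for year Y (``prevalence_mode="cumulative"``)
counts members whose index date falls on or before Dec 31 of Y, who are still
in follow-up in Y, and whose 16th birthday has not passed before Y — the
registry reading of a chronic-disease prevalence.  ``"active_claim"`` instead
requires at least one JIA claim during Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .config import AGE_BAND_EDGES, AGE_BANDS, AnalysisConfig

PER = 100_000


@dataclass
class RateEstimate:
    numerator: int
    denominator: float
    rate: float                      # per 100,000 (population or person-years)
    stratum: dict = field(default_factory=dict)   # year / age_group / sex, "all" wildcard


def age_band(age: int) -> str:
    """Completed age -> analytic band; ages past the pediatric range clamp to the last band."""
    for band, lo, hi in zip(AGE_BANDS, AGE_BAND_EDGES[:-1], AGE_BAND_EDGES[1:]):
        if lo <= age < hi:
            return band
    return AGE_BANDS[-1] if age >= AGE_BAND_EDGES[-1] else AGE_BANDS[0]


def _den_for_year(denominators: pd.DataFrame, year: int) -> pd.DataFrame:
    sub = denominators[denominators["year"] == year]
    if not len(sub):
        raise ValueError(f"no population denominator for year {year}")
    return sub


def _sixteenth_birthday_after(cohort: pd.DataFrame, day: date) -> pd.Series:
    cutoff_birth = pd.Timestamp(day) - pd.DateOffset(years=16)
    return cohort["birth_date"] > cutoff_birth


def _prevalent_mask(
    cohort: pd.DataFrame,
    year: int,
    config: AnalysisConfig,
    diagnoses: pd.DataFrame | None,
) -> pd.Series:
    y0, y1 = date(year, 1, 1), date(year, 12, 31)
    mask = (
        (cohort["index_date"] <= pd.Timestamp(y1))
        & (cohort["followup_end"] >= pd.Timestamp(y0))
        & _sixteenth_birthday_after(cohort, y0)
    )
    if config.prevalence_mode == "active_claim":
        if diagnoses is None:
            raise ValueError("active_claim prevalence requires the diagnoses table")
        jia = diagnoses[
            (diagnoses["dx_group"] == "JIA")
            & (diagnoses["date"].dt.year == year)
        ]
        mask &= cohort["person_id"].isin(set(jia["person_id"]))
    return mask


def annual_prevalence(
    cohort: pd.DataFrame,
    denominators: pd.DataFrame,
    year: int,
    config: AnalysisConfig | None = None,
    diagnoses: pd.DataFrame | None = None,
) -> RateEstimate:
    """Prevalent cases in ``year`` per 100,000 under-16 population."""
    config = config or AnalysisConfig()
    num = int(_prevalent_mask(cohort, year, config, diagnoses).sum()) if len(cohort) else 0
    den = int(_den_for_year(denominators, year)["person_count"].sum())
    if den <= 0:
        raise ValueError(f"non-positive denominator for year {year}")
    return RateEstimate(num, den, PER * num / den, {"year": year, "age_group": "all", "sex": "all"})


def annual_incidence_proportion(
    incident_cohort: pd.DataFrame,
    denominators: pd.DataFrame,
    year: int,
    config: AnalysisConfig | None = None,
) -> RateEstimate:
    """Newly diagnosed cases in ``year`` per 100,000 at-risk under-16 population.

    The at-risk denominator removes previously diagnosed members who are still
    under the age cutoff at the start of the year.
    """
    config = config or AnalysisConfig()
    if len(incident_cohort):
        idx_year = incident_cohort["index_date"].dt.year
        num = int((idx_year == year).sum())
        prior = int(
            (
                (idx_year < year)
                & _sixteenth_birthday_after(incident_cohort, date(year, 1, 1))
            ).sum()
        )
    else:
        num = prior = 0
    den = int(_den_for_year(denominators, year)["person_count"].sum()) - prior
    if den <= 0:
        raise ValueError(f"non-positive at-risk denominator for year {year}")
    return RateEstimate(num, den, PER * num / den, {"year": year, "age_group": "all", "sex": "all"})


def overall_incidence_rate(
    incident_cohort: pd.DataFrame,
    denominators: pd.DataFrame,
    window: tuple[int, int] = (2012, 2019),
) -> RateEstimate:
    """All incident cases over summed under-16 person-years, per 100,000 PY."""
    lo, hi = window
    if len(incident_cohort):
        idx_year = incident_cohort["index_date"].dt.year
        num = int(((idx_year >= lo) & (idx_year <= hi)).sum())
    else:
        num = 0
    den = float(
        denominators.loc[
            (denominators["year"] >= lo) & (denominators["year"] <= hi), "person_years"
        ].sum()
    )
    if den <= 0:
        raise ValueError("zero person-years in incidence window")
    return RateEstimate(num, den, PER * num / den,
                        {"year": f"{lo}-{hi}", "age_group": "all", "sex": "all"})


def stratified_rates(
    cohort: pd.DataFrame,
    denominators: pd.DataFrame,
    by: set[str],
    kind: str = "incidence",
    years: list[int] | None = None,
    config: AnalysisConfig | None = None,
    diagnoses: pd.DataFrame | None = None,
) -> list[RateEstimate]:
    """Rates partitioned by any of {year, age_group, sex}.

    Incidence strata use the year of and age band at the index date; prevalence
    strata use the mid-year attained age band.  Within each year the stratum
    numerators sum to the marginal numerator.
    """
    config = config or AnalysisConfig()
    bad = by - {"year", "age_group", "sex"}
    if bad:
        raise ValueError(f"unknown stratifiers: {sorted(bad)}")
    if years is None:
        years = sorted(denominators["year"].unique())

    out: list[RateEstimate] = []
    for year in years:
        den_year = _den_for_year(denominators, year)
        if kind == "incidence":
            members = cohort[cohort["index_date"].dt.year == year] if len(cohort) else cohort
            ages = members["age_at_index"] if len(members) else pd.Series(dtype=int)
        elif kind == "prevalence":
            mask = _prevalent_mask(cohort, year, config, diagnoses) if len(cohort) else pd.Series(dtype=bool)
            members = cohort[mask] if len(cohort) else cohort
            mid = pd.Timestamp(date(year, 7, 1))
            ages = ((mid - members["birth_date"]).dt.days // 365).astype(int) if len(members) else pd.Series(dtype=int)
        else:
            raise ValueError(f"unknown kind {kind!r}")

        bands = ages.map(age_band) if len(members) else pd.Series(dtype=object)
        groups = [("age_group", AGE_BANDS), ("sex", ("male", "female"))]
        keys: list[dict] = [{}]
        for name, levels in groups:
            if name in by:
                keys = [dict(k, **{name: lv}) for k in keys for lv in levels]
        for key in keys:
            m = pd.Series(True, index=members.index)
            d = den_year
            if "age_group" in key:
                m &= (bands == key["age_group"]).reindex(members.index, fill_value=False)
                d = d[d["age_group"] == key["age_group"]]
            if "sex" in key:
                m &= members["sex"] == key["sex"]
                d = d[d["sex"] == key["sex"]]
            num = int(m.sum())
            den = int(d["person_count"].sum())
            if den <= 0:
                if num > 0:
                    raise ValueError(f"zero denominator with nonzero numerator in {key}, {year}")
                continue
            stratum = {"year": year,
                       "age_group": key.get("age_group", "all"),
                       "sex": key.get("sex", "all")}
            out.append(RateEstimate(num, den, PER * num / den, stratum))

    if "year" not in by:
        # collapse across years: numerators and annual headcounts both add
        combined: dict[tuple, list] = {}
        for r in out:
            k = (r.stratum["age_group"], r.stratum["sex"])
            acc = combined.setdefault(k, [0, 0.0])
            acc[0] += r.numerator
            acc[1] += r.denominator
        out = [
            RateEstimate(n, d, PER * n / d, {"year": "all", "age_group": k[0], "sex": k[1]})
            for k, (n, d) in combined.items()
        ]
    return out


def rates_frame(rates: list[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [r.stratum.get("year", "all") for r in rates],
            "age_group": [r.stratum.get("age_group", "all") for r in rates],
            "sex": [r.stratum.get("sex", "all") for r in rates],
            "numerator": [r.numerator for r in rates],
            "denominator": [r.denominator for r in rates],
            "rate_per_100k": [r.rate for r in rates],
        }
    )
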