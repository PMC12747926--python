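"""Case definition, prevalent/incident cohort assembly, and SpA subgrouping.

A person enters the prevalent cohort when all four inclusion criteria hold:

1. at least one inpatient or three outpatient juvenile-arthritis diagnosis
   codes within 365 days, all inside the 2012-2019 identification window;
2. an enrollment record overlapping the identification window;
3. age under 16 (completed years) at the index date, the first JIA diagnosis
   inside the identification window;
4. systemic NSAID exposure for more than 14 consecutive days (14-day grace
   merging) intersecting the 365 days after the first JIA diagnosis.

The incident cohort further requires no JIA code before 2012-01-01 — the whole
available pre-window history (the database starts in 2011) serves as washout.
Members carry a SpA / non-SpA label: SpA iff any spondyloarthritis-feature code
(ankylosing spondylitis, sacroiliitis, inflammatory spondylopathy, psoriatic
arthropathy) appears in the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import ClaimsBundle, age_completed_years, date_to_day, day_to_date, to_days
from .episodes import build_episodes


@dataclass
class CohortMember:
    person_id: str
    index_date: date
    incident: bool
    age_at_index: int
    birth_date: date
    sex: str
    subgroup: str              # "SpA" | "non_SpA"
    followup_end: date
    uveitis: bool = False
    psoriasis: bool = False


def qualify_case(events: list[tuple[int, str]], window_days: int = 365) -> int | None:
    """Earliest day the diagnostic case criterion is met, or None.

    ``events`` are ``(day, setting)`` pairs for one person's JIA codes, sorted
    by day.  The criterion is met at the first inpatient code, or at the third
    outpatient code of any consecutive triple of distinct outpatient days whose
    first-to-third span is at most ``window_days`` (sliding window, not calendar
    year).  Duplicate same-day outpatient codes collapse to one visit day.
    """
    days = [d for d, _ in events]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("diagnosis events must be sorted by date")
    best: int | None = None
    inpat = [d for d, s in events if s == "inpatient"]
    if inpat:
        best = inpat[0]
    outpat = sorted({d for d, s in events if s == "outpatient"})
    for i in range(2, len(outpat)):
        if outpat[i] - outpat[i - 2] <= window_days:
            if best is None or outpat[i] < best:
                best = outpat[i]
            break  # triples are scanned in order; the first hit is the earliest
    return best


def nsaid_criterion(
    fills: list[tuple[int, int]],
    first_dx_day: int,
    grace: int = 14,
    min_span: int = 15,
    window_days: int = 365,
) -> bool:
    """NSAID use for more than 14 consecutive days near diagnosis.

    ``fills`` are ``(day, days_supply)`` pairs for the person's NSAID fills
    (all NSAID drugs pooled), sorted.  True iff some grace-merged episode spans
    at least ``min_span`` days and intersects
    ``[first_dx_day, first_dx_day + window_days)``.  The episode only needs to
    intersect the window, not start inside it.
    """
    lo, hi = first_dx_day, first_dx_day + window_days
    for ep in build_episodes(fills, grace):
        if ep.span_days >= min_span and ep.start < hi and ep.end > lo:
            return True
    return False


def classify_subgroup(
    person_dx: pd.DataFrame, config: AnalysisConfig | None = None
) -> str:
    """SpA iff a spondyloarthritis-feature code occurs anywhere in the record.

    With ``spa_same_day_only`` the feature code must share a calendar day with
    a JIA code (strict same-day co-occurrence).
    """
    config = config or AnalysisConfig()
    feat = person_dx[person_dx["dx_group"] == "SpA_feature"]
    if not len(feat):
        return "non_SpA"
    if config.spa_same_day_only:
        jia_days = set(person_dx.loc[person_dx["dx_group"] == "JIA", "date"])
        if not any(d in jia_days for d in feat["date"]):
            return "non_SpA"
    return "SpA"


def build_cohorts(
    bundle: ClaimsBundle, config: AnalysisConfig | None = None
) -> tuple[list[CohortMember], list[CohortMember], dict[str, int]]:
    """Apply the four inclusion criteria; return (prevalent, incident, flowchart).

    The flowchart dict logs the candidate count and the exclusions at each
    step, in application order.
    """
    config = config or AnalysisConfig()
    ilo = date_to_day(config.identification_start)
    ihi = date_to_day(config.identification_end)
    cutoff_day = date_to_day(config.followup_cutoff)

    dx = bundle.diagnoses
    dx_days = to_days(dx["date"]) if len(dx) else np.array([], dtype="int64")
    jia_mask = (dx["dx_group"] == "JIA").values if len(dx) else np.array([], dtype=bool)

    # only persons with at least one JIA code can become candidates
    jia_persons: set[str] = (
        set(dx.loc[jia_mask, "person_id"]) if len(dx) else set()
    )

    ben = bundle.beneficiaries
    ben_info: dict[str, dict] = {}
    if len(ben) and jia_persons:
        keep = ben["person_id"].isin(jia_persons).values
        ben = ben[keep]
        starts = to_days(ben["enroll_start"])
        ends = to_days(ben["enroll_end"])
        for i, pid in enumerate(ben["person_id"]):
            info = ben_info.setdefault(
                pid,
                {"sex": ben["sex"].iat[i],
                 "birth": ben["birth_date"].iat[i].date(),
                 "intervals": []},
            )
            info["intervals"].append((int(starts[i]), int(ends[i])))

    rx = bundle.prescriptions
    nsaid_by_person: dict[str, list[tuple[int, int]]] = {}
    if len(rx):
        nm = (rx["drug_class"] == "NSAID").values
        rdays = to_days(rx["fill_date"])
        sub = rx[nm]
        for day, supply, pid in zip(rdays[nm], sub["days_supply"], sub["person_id"]):
            nsaid_by_person.setdefault(pid, []).append((int(day), int(supply)))
    for v in nsaid_by_person.values():
        v.sort()

    flow = {
        "candidates": 0,
        "excluded_case_definition": 0,
        "excluded_enrollment": 0,
        "excluded_age": 0,
        "excluded_nsaid": 0,
        "prevalent": 0,
        "excluded_prior_history": 0,
        "incident": 0,
    }
    prevalent: list[CohortMember] = []
    incident: list[CohortMember] = []

    if not len(dx):
        return prevalent, incident, flow

    dx = dx.assign(_day=dx_days)
    dx = dx[dx["person_id"].isin(jia_persons)]
    dx_by_person = {pid: grp for pid, grp in dx.groupby("person_id", sort=True)}

    for pid in sorted(dx_by_person):
        person_dx = dx_by_person[pid]
        grp = pd.DataFrame({
            "day": person_dx["_day"].values,
            "setting": person_dx["setting"].values,
            "dx_group": person_dx["dx_group"].values,
        })
        jia = grp[grp["dx_group"] == "JIA"].sort_values("day")
        in_window = jia[(jia["day"] >= ilo) & (jia["day"] < ihi)]
        if not len(in_window):
            continue
        flow["candidates"] += 1

        qual = qualify_case(
            list(zip(in_window["day"], in_window["setting"])),
            window_days=config.case_window_days,
        )
        if qual is None:
            flow["excluded_case_definition"] += 1
            continue

        info = ben_info.get(pid)
        enrolled = info is not None and any(
            s < ihi and e > ilo for s, e in info["intervals"]
        )
        if not enrolled:
            flow["excluded_enrollment"] += 1
            continue

        index_day = int(in_window["day"].iloc[0])
        index_date = day_to_date(index_day)
        age = age_completed_years(info["birth"], index_date)
        if age >= config.age_cutoff_years:
            flow["excluded_age"] += 1
            continue

        if not nsaid_criterion(
            nsaid_by_person.get(pid, []),
            index_day,
            grace=config.grace_nsaid_days,
            min_span=config.nsaid_min_span_days,
            window_days=config.case_window_days,
        ):
            flow["excluded_nsaid"] += 1
            continue

        followup_end = day_to_date(min(cutoff_day, max(e for _, e in info["intervals"]) - 1))
        member = CohortMember(
            person_id=pid,
            index_date=index_date,
            incident=False,
            age_at_index=age,
            birth_date=info["birth"],
            sex=info["sex"],
            subgroup=classify_subgroup(person_dx, config),
            followup_end=followup_end,
            uveitis=bool((person_dx["dx_group"] == "uveitis").any()),
            psoriasis=bool((person_dx["dx_group"] == "psoriasis").any()),
        )
        flow["prevalent"] += 1
        prevalent.append(member)

        prior = jia[jia["day"] < ilo]
        if len(prior):
            flow["excluded_prior_history"] += 1
        else:
            member.incident = True
            flow["incident"] += 1
            incident.append(member)

    return prevalent, incident, flow


def cohort_frame(members: list[CohortMember]) -> pd.DataFrame:
    """Cohort as a DataFrame (the on-disk representation used by the CLI)."""
    return pd.DataFrame(
        {
            "person_id": [m.person_id for m in members],
            "index_date": pd.to_datetime([m.index_date for m in members]),
            "incident": [m.incident for m in members],
            "age_at_index": [m.age_at_index for m in members],
            "birth_date": pd.to_datetime([m.birth_date for m in members]),
            "sex": [m.sex for m in members],
            "subgroup": [m.subgroup for m in members],
            "followup_end": pd.to_datetime([m.followup_end for m in members]),
            "uveitis": [m.uveitis for m in members],
            "psoriasis": [m.psoriasis for m in members],
        }
    )
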