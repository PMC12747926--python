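"""Biologic treatment-course classification.

The first fill of etanercept, adalimumab or tocilizumab defines the index
biologic (abatacept is not eligible as index but still counts as biologic
exposure for switching and restart).  Walking events after the index start, the
first qualifying event fixes one of four mutually exclusive terminal patterns:

continuation
    the index-drug episode (60-day grace) persists to within 60 days of the
    end of follow-up, with no switch;
switching
    a different biologic is first filled on or before the index episode end
    plus 60 days (``within_gap``; a fill while the index episode is still
    covered counts, gap 0);
restart
    no biologic fill within 60 days of the index episode end, but some
    biologic is filled later — the restart drug may be the index drug or a
    different one (``after_interruption``);
discontinuation
    no biologic fill after the index episode, and the episode ends more than
    60 days before the end of follow-up.

Courses carry the drug-survival observation: the event clock starts at the
index fill and stops at switch (switch date) or at the end of the index
episode (interruption/discontinuation), or is censored at the end of
follow-up for continuers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import INDEX_BIOLOGICS, AnalysisConfig
from .core import ClaimsBundle, date_to_day, to_days
from .episodes import build_episodes, combination_csdmard

PATTERNS = ("continuation", "switching", "restart", "discontinuation")
DAYS_PER_YEAR = 365.25


@dataclass
class TreatmentCourse:
    person_id: str
    index_drug: str
    index_start: int                 # day
    index_episode_end: int           # day, half-open
    pattern: str
    switch_subtype: str = "none"     # "within_gap" | "after_interruption" | "none"
    restart_drug_same: bool | None = None
    restart_day: int | None = None
    combo_csdmard_first_year: bool = False
    combo_csdmard_after: bool = False
    followup_end: int = 0
    time_to_index_years: float | None = None
    index_duration_years: float = 0.0
    event_time_days: int = 1
    event: int = 0                   # 1 = discontinued/switched, 0 = censored


def find_index_biologic(
    fills: list[tuple[int, int, str]]
) -> tuple[str, int] | None:
    """Earliest eligible biologic fill -> (drug_name, day), or None.

    Ties on the same day break toward the larger days_supply, then
    alphabetically.
    """
    eligible = [(d, s, n) for d, s, n in fills if n in INDEX_BIOLOGICS]
    if not eligible:
        return None
    day, _, name = min(eligible, key=lambda f: (f[0], -f[1], f[2]))
    return name, day


def classify_course(
    fills: list[tuple[int, int, str]],
    followup_end: int,
    person_id: str = "",
    config: AnalysisConfig | None = None,
) -> TreatmentCourse:
    """Classify one person's biologic fills into a terminal treatment pattern.

    ``fills`` are ``(day, days_supply, drug_name)`` for every biologic fill
    (including abatacept), in any order.
    """
    config = config or AnalysisConfig()
    grace = config.grace_biologic_days
    index = find_index_biologic(fills)
    if index is None:
        raise ValueError("no eligible index biologic in fills")
    drug, start = index

    own = sorted((d, s) for d, s, n in fills if n == drug)
    eps = build_episodes(own, grace)
    index_ep = next(e for e in eps if e.start <= start < e.end)
    end = index_ep.end

    other = sorted((d, n) for d, s, n in fills if n != drug and d > start)
    later_same = [d for d, _ in own if d > end + grace]

    course = TreatmentCourse(
        person_id=person_id, index_drug=drug, index_start=start,
        index_episode_end=end, pattern="continuation", followup_end=followup_end,
    )
    switch = next(((d, n) for d, n in other if d <= end + grace), None)
    restarts = sorted(
        [(d, n) for d, n in other if d > end + grace] + [(d, drug) for d in later_same]
    )
    if switch is not None:
        course.pattern = "switching"
        course.switch_subtype = "within_gap"
        course.event = 1
        course.event_time_days = max(1, switch[0] - start)
    elif restarts:
        rday, rdrug = restarts[0]
        course.pattern = "restart"
        course.restart_drug_same = rdrug == drug
        course.switch_subtype = "none" if rdrug == drug else "after_interruption"
        course.restart_day = rday
        course.event = 1
        course.event_time_days = max(1, end - start)
    elif end + grace < followup_end:
        course.pattern = "discontinuation"
        course.event = 1
        course.event_time_days = max(1, end - start)
    else:
        course.pattern = "continuation"
        course.event = 0
        course.event_time_days = max(1, followup_end - start)

    if config.event_definition == "any_biologic":
        # event only when all biologic exposure ends before follow-up
        all_fills = sorted((d, s) for d, s, n in fills if d >= start)
        union = build_episodes(all_fills, grace)
        last_end = union[-1].end
        if last_end + grace < followup_end:
            course.event = 1
            course.event_time_days = max(1, last_end - start)
        else:
            course.event = 0
            course.event_time_days = max(1, followup_end - start)

    course.index_duration_years = (end - start) / DAYS_PER_YEAR
    return course


def course_times(
    course: TreatmentCourse, diagnosis_day: int
) -> tuple[float, float]:
    """(years from diagnosis to index biologic, index episode duration in years)."""
    if diagnosis_day > course.index_start:
        raise ValueError("diagnosis date must not be after the index biologic start")
    t2i = (course.index_start - diagnosis_day) / DAYS_PER_YEAR
    dur = (course.index_episode_end - course.index_start) / DAYS_PER_YEAR
    course.time_to_index_years = t2i
    course.index_duration_years = dur
    return t2i, dur


def tabulate_patterns(
    courses: list[TreatmentCourse], by_drug: bool = True
) -> pd.DataFrame:
    """Counts and percentages of the four patterns per index drug.

    Percentages are against the per-drug initiator count; switch after
    interruption is already tabulated under restart by the classifier.
    """
    rows = []
    drugs = sorted({c.index_drug for c in courses}) if by_drug else []
    for drug in drugs + ["all"]:
        sub = [c for c in courses if drug == "all" or c.index_drug == drug]
        n = len(sub)
        row: dict = {"index_drug": drug, "n": n}
        for p in PATTERNS:
            k = sum(1 for c in sub if c.pattern == p)
            row[p] = k
            row[f"{p}_pct"] = round(100.0 * k / n, 1) if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def extract_courses(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> list[TreatmentCourse]:
    """Classify every cohort member with at least one eligible biologic fill."""
    config = config or AnalysisConfig()
    rx = bundle.prescriptions
    bio = rx[rx["drug_class"] == "biologic"]
    if not len(bio):
        return []
    days = to_days(bio["fill_date"])
    fills_by_person: dict[str, list[tuple[int, int, str]]] = {}
    bio_visits: dict[str, list[tuple[int, str]]] = {}
    for day, supply, name, pid, visit in zip(
        days, bio["days_supply"], bio["drug_name"], bio["person_id"], bio["visit_id"]
    ):
        fills_by_person.setdefault(pid, []).append((int(day), int(supply), name))
        bio_visits.setdefault(pid, []).append((int(day), visit))
    cs = rx[rx["drug_class"] == "csDMARD"]
    cs_visits: dict[str, list[tuple[int, str]]] = {}
    if len(cs):
        cs_days = to_days(cs["fill_date"])
        for day, pid, visit in zip(cs_days, cs["person_id"], cs["visit_id"]):
            cs_visits.setdefault(pid, []).append((int(day), visit))

    courses: list[TreatmentCourse] = []
    for _, m in cohort.iterrows():
        fills = fills_by_person.get(m["person_id"])
        if not fills or find_index_biologic(fills) is None:
            continue
        course = classify_course(
            fills,
            date_to_day(m["followup_end"].date()),
            person_id=m["person_id"],
            config=config,
        )
        course_times(course, date_to_day(m["index_date"].date()))
        course.combo_csdmard_first_year, course.combo_csdmard_after = combination_csdmard(
            bio_visits.get(m["person_id"], []),
            cs_visits.get(m["person_id"], []),
            course.index_start,
            followup_end=course.followup_end,
        )
        courses.append(course)
    return courses


def courses_frame(courses: list[TreatmentCourse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [c.person_id for c in courses],
            "index_drug": [c.index_drug for c in courses],
            "index_start": [c.index_start for c in courses],
            "index_episode_end": [c.index_episode_end for c in courses],
            "pattern": [c.pattern for c in courses],
            "switch_subtype": [c.switch_subtype for c in courses],
            "restart_drug_same": [c.restart_drug_same for c in courses],
            "restart_day": [c.restart_day for c in courses],
            "combo_csdmard_first_year": [c.combo_csdmard_first_year for c in courses],
            "combo_csdmard_after": [c.combo_csdmard_after for c in courses],
            "followup_end": [c.followup_end for c in courses],
            "time_to_index_years": [c.time_to_index_years for c in courses],
            "index_duration_years": [c.index_duration_years for c in courses],
            "event_time_days": [c.event_time_days for c in courses],
            "event": [c.event for c in courses],
        }
    )
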