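"""Exposure-episode construction from prescription fills.

A fill covers the half-open day interval ``[fill_date, fill_date + days_supply)``.
Consecutive fills of the same drug are merged into one continuous exposure
episode as long as each new fill starts no more than ``grace`` days after the
running episode end; the grace period is 14 days for NSAIDs, systemic steroids
and csDMARDs and 60 days for biologics.  Overlapping supply extends coverage
from the maximum end (no stockpiling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class ExposureEpisode:
    """One merged half-open coverage interval, in integer days.

    ``start``/``end`` may be calendar ordinals or day offsets — the algebra only
    needs integers.  ``covered_days`` is the union length of the member fills'
    supply, which can be smaller than ``end - start`` when graced gaps occur
    inside the episode.
    """

    person_id: str | None
    drug_name: str | None
    start: int
    end: int
    n_fills: int
    covered_days: int

    @property
    def span_days(self) -> int:
        return self.end - self.start


def build_episodes(
    fills: Sequence[tuple[int, int]],
    grace: int,
    person_id: str | None = None,
    drug_name: str | None = None,
) -> list[ExposureEpisode]:
    """Merge ``(fill_day, days_supply)`` pairs under a grace period.

    ``fills`` must belong to a single person and drug and be sorted by fill day.
    A fill joins the current episode iff ``fill_day <= episode_end + grace``;
    otherwise it opens a new episode, so retained inter-episode gaps strictly
    exceed the grace period.
    """
    if grace < 0:
        raise ValueError("grace period must be non-negative")
    eps: list[ExposureEpisode] = []
    prev_day = None
    start = end = cov_end = covered = n = 0
    for day, supply in fills:
        if supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {supply}")
        if prev_day is not None and day < prev_day:
            raise ValueError("fills must be sorted by fill date")
        prev_day = day
        if n and day <= end + grace:
            n += 1
            covered += max(0, day + supply - max(day, cov_end))
            cov_end = max(cov_end, day + supply)
            end = max(end, day + supply)
        else:
            if n:
                eps.append(ExposureEpisode(person_id, drug_name, start, end, n, covered))
            start, end, cov_end, covered, n = day, day + supply, day + supply, supply, 1
    if n:
        eps.append(ExposureEpisode(person_id, drug_name, start, end, n, covered))
    return eps


def chronic_medications(
    episodes_by_drug: Mapping[str, Iterable[ExposureEpisode]],
    chronic_days: int = 90,
) -> set[str]:
    """Drugs used continuously for at least ``chronic_days`` within one episode.

    "More than three consecutive months" is operationalised as a single
    grace-merged episode spanning >= 90 days; disjoint shorter episodes never
    qualify.
    """
    return {
        drug
        for drug, eps in episodes_by_drug.items()
        if any(e.span_days >= chronic_days for e in eps)
    }


def combination_csdmard(
    biologic_fills: Sequence[tuple[int, str]],
    csdmard_fills: Sequence[tuple[int, str]],
    index_start: int,
    followup_end: int | None = None,
    year_days: int = 365,
) -> tuple[bool, bool]:
    """csDMARD add-on use during biologic treatment, by same-visit dispensing.

    A period flag is true iff at least one csDMARD fill shares a ``visit_id``
    with a biologic fill whose fill day lies in the period.  Periods are the
    first treatment year ``[index_start, index_start + 365)`` and everything
    after it (optionally truncated at ``followup_end``).  Same-day fills at
    different visits do not count — the rule is visit-based.
    """
    cs_visits = {v for _, v in csdmard_fills}
    first_year = after = False
    for day, visit in biologic_fills:
        if followup_end is not None and day >= followup_end:
            continue
        if visit in cs_visits:
            if index_start <= day < index_start + year_days:
                first_year = True
            elif day >= index_start + year_days:
                after = True
    return first_year, after
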