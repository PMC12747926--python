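"""Independent brute-force oracles used by the test suite.

These deliberately use the dumbest correct algorithm (day bitmaps, exhaustive
window scans, event-by-event walks) so they stay independent of the package's
implementations.
"""

from __future__ import annotations


def coverage_episodes(fills: list[tuple[int, int]], grace: int) -> list[tuple[int, int, int]]:
    """Day-by-day bitmap oracle for exposure-episode merging.

    Marks every supplied day, then walks the timeline closing an episode when
    more than ``grace`` uncovered days elapse before the next covered day.
    Returns (start, end, covered_days) per episode, end half-open.
    """
    if not fills:
        return []
    covered: set[int] = set()
    for day, supply in fills:
        covered.update(range(day, day + supply))
    days = sorted(covered)
    episodes = []
    start = prev = days[0]
    n_cov = 1
    for d in days[1:]:
        if d - prev - 1 > grace:  # uncovered stretch strictly exceeds grace
            episodes.append((start, prev + 1, n_cov))
            start, n_cov = d, 0
        prev = d
        n_cov += 1
    episodes.append((start, prev + 1, n_cov))
    return episodes


def qualify_scan(events: list[tuple[int, str]], window: int = 365) -> int | None:
    """Exhaustive scan for the earliest case-qualification day.

    Considers the first inpatient code and every triple of distinct outpatient
    days (not only consecutive ones) whose span is within ``window``.
    """
    best = None
    for d, s in events:
        if s == "inpatient":
            best = d if best is None else min(best, d)
            break
    out = sorted({d for d, s in events if s == "outpatient"})
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            for k in range(j + 1, len(out)):
                if out[k] - out[i] <= window:
                    if best is None or out[k] < best:
                        best = out[k]
    return best


def classify_walk(
    fills: list[tuple[int, int, str]],
    followup_end: int,
    grace: int = 60,
    index_eligible=("etanercept", "adalimumab", "tocilizumab"),
) -> tuple[str, int, int] | None:
    """Event-by-event reference interpreter for the treatment-pattern states.

    Uses the day-bitmap episode oracle for the index episode, then walks every
    biologic fill after the index start in time order.  Returns
    (pattern, index_start, index_episode_end) or None when no eligible index
    biologic exists.
    """
    eligible = [(d, s, n) for d, s, n in fills if n in index_eligible]
    if not eligible:
        return None
    day0 = min(d for d, _, _ in eligible)
    same_day = [(d, s, n) for d, s, n in eligible if d == day0]
    same_day.sort(key=lambda f: (-f[1], f[2]))
    drug = same_day[0][2]

    own = sorted((d, s) for d, s, n in fills if n == drug)
    eps = coverage_episodes(own, grace)
    start = day0
    end = next(e for s_, e, _ in eps if s_ <= start < e)

    events = sorted((d, n) for d, s, n in fills if d > start)
    for d, n in events:
        if n != drug and d <= end + grace:
            return "switching", start, end
        if d > end + grace:
            return "restart", start, end
    if end + grace < followup_end:
        return "discontinuation", start, end
    return "continuation", start, end
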