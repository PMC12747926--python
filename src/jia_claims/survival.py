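"""Product-limit (Kaplan-Meier) estimation for drug survival.

Implements the standard estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i) with
Greenwood's variance and, by default, log(-log)-transformed 95% confidence
bounds (guaranteed inside [0, 1]); plain Greenwood bounds are available as a
config option.  Ties are handled by processing events before censorings at the
same time, the usual convention.  Years are days / 365.25 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DAYS_PER_YEAR = 365.25
_Z95 = 1.959963984540054


@dataclass
class KMCurve:
    """Survival curve evaluated at the distinct event times."""

    event_times: np.ndarray   # sorted distinct times with >=1 event
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray      # S at each event time
    var_log_s: np.ndarray     # Greenwood variance of log S
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int = 0
    max_time: float = 0.0     # largest observed time (event or censoring)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(t) = 1 before the first event."""
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def ci_at(self, t: float) -> tuple[float, float]:
        i = np.searchsorted(self.event_times, t, side="right") - 1
        if i < 0:
            return 1.0, 1.0
        return float(self.ci_low[i]), float(self.ci_high[i])


def km_fit(times, events, ci_method: str = "loglog") -> KMCurve:
    """Fit the product-limit estimator to (time, event) observations.

    ``events`` uses 1 for the event and 0 for right-censoring.  Events and
    censorings tied at the same time keep the censored subjects in the risk
    set for that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_fit requires at least one observation")
    if np.any(times < 1):
        raise ValueError("survival times must be >= 1 day")

    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n_total = t.size

    uniq = np.unique(t[e == 1])
    at_risk = np.empty(uniq.size, dtype=int)
    d = np.empty(uniq.size, dtype=int)
    for i, u in enumerate(uniq):
        at_risk[i] = int(np.sum(t >= u))
        d[i] = int(np.sum((t == u) & (e == 1)))

    with np.errstate(divide="ignore"):
        frac = 1.0 - d / at_risk
        surv = np.cumprod(frac)
        # Greenwood: var(log S) = sum d / (n (n - d))
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d).astype(float)), np.inf)
        var_log = np.cumsum(terms)

    lo = np.empty_like(surv)
    hi = np.empty_like(surv)
    for i, (s, v) in enumerate(zip(surv, var_log)):
        if s <= 0.0 or not math.isfinite(v):
            lo[i], hi[i] = 0.0, 0.0 if s <= 0 else 1.0
            continue
        if s >= 1.0:
            lo[i], hi[i] = 1.0, 1.0
            continue
        if ci_method == "loglog":
            se_theta = math.sqrt(v) / abs(math.log(s))
            lo[i] = s ** math.exp(_Z95 * se_theta)
            hi[i] = s ** math.exp(-_Z95 * se_theta)
        elif ci_method == "greenwood":
            se = s * math.sqrt(v)
            lo[i] = max(0.0, s - _Z95 * se)
            hi[i] = min(1.0, s + _Z95 * se)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")

    return KMCurve(uniq, at_risk, d, surv, var_log, lo, hi,
                   n=n_total, max_time=float(t[-1]))


def km_median(curve: KMCurve) -> float | None:
    """Smallest event time with S <= 0.5, or None if S never reaches 0.5."""
    hit = np.nonzero(curve.survival <= 0.5)[0]
    if hit.size == 0:
        return None
    return float(curve.event_times[hit[0]])


def cumulative_discontinuation(
    curve: KMCurve, horizon_years: float
) -> tuple[float, tuple[float, float]]:
    """1 - S at a horizon, with the transformed CI carried from the last event.

    Returns the cumulative event probability (0-1 scale) and its 95% CI.
    Before the first event the rate is 0 with a degenerate (0, 0) interval.
    """
    horizon = horizon_years * DAYS_PER_YEAR
    s = curve.survival_at(horizon)
    lo_s, hi_s = curve.ci_at(horizon)
    if s == 1.0:
        return 0.0, (0.0, 0.0)
    return 1.0 - s, (1.0 - hi_s, 1.0 - lo_s)


def time_to_restart_curve(courses) -> KMCurve:
    """KM curve of time from the index-episode end to the first later biologic fill.

    Only courses whose index episode ended in an interruption contribute:
    restarts are events at the restart fill; discontinuations are censored at
    the end of follow-up.  Switch-within-gap and continuation courses have no
    interruption and are excluded.
    """
    times, events = [], []
    for c in courses:
        if c.pattern == "restart":
            times.append(max(1, c.restart_day - c.index_episode_end))
            events.append(1)
        elif c.pattern == "discontinuation":
            times.append(max(1, c.followup_end - c.index_episode_end))
            events.append(0)
    if not times:
        raise ValueError("no interrupted courses to analyse")
    return km_fit(times, events)


def km_table(curve: KMCurve):
    """Curve as a plain table: time, at_risk, events, survival, ci bounds."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.event_times,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "survival": curve.survival,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
        }
    )
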