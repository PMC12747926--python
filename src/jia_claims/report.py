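"""Contingency statistics, small-count suppression, and report assembly.

The chi-squared test is the plain Pearson statistic without continuity
correction; Fisher's exact test is the full two-sided hypergeometric
enumeration (all tables with the observed margins whose probability does not
exceed the observed table's).  The conventional selection rule — Fisher when
any expected cell is below 5 in a 2x2 table, chi-squared otherwise — is
applied by :func:`select_test` and can be overridden.

Small-count suppression follows the data custodian's privacy rule: every
non-zero count below three is masked (rendered as "<=3"); zeros and counts of
three or more are shown.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGE_BANDS, AnalysisConfig
from .survival import cumulative_discontinuation, km_fit, km_median

log = logging.getLogger(__name__)

SUPPRESSED_DISPLAY = "≤3"


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence: (statistic, df, p).

    No continuity correction.  Raises on a zero row or column margin.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric probability is no greater than the observed one (with a
    small relative tolerance for floating-point ties).
    """
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    a, b = obs[0]
    c, d = obs[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p)


def odds_ratio(table) -> tuple[float, tuple[float, float]]:
    """Odds ratio (a*d)/(b*c) with a Woolf log-scale 95% CI.

    Zero cells trigger the Haldane-Anscombe 0.5 continuity correction (logged).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    if np.any(obs == 0):
        log.info("zero cell in 2x2 table; applying 0.5 continuity correction")
        obs = obs + 0.5
    a, b = obs[0]
    c, d = obs[1]
    ratio = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = 1.959963984540054
    ci = (ratio * np.exp(-z * se), ratio * np.exp(z * se))
    return float(ratio), (float(ci[0]), float(ci[1]))


def select_test(table) -> tuple[str, float]:
    """Apply Fisher's exact test when any expected 2x2 cell is < 5, else chi-squared."""
    obs = np.asarray(table, dtype=float)
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    expected = np.outer(rows, cols) / obs.sum()
    if obs.shape == (2, 2) and (expected < 5).any():
        return "fisher_exact", fisher_exact(obs.astype(int))
    return "chi_squared", chi_squared(obs)[2]


@dataclass
class SuppressedTable:
    """Counts with privacy mask flags: non-zero counts below three are masked."""

    counts: np.ndarray
    mask: np.ndarray

    def display(self) -> np.ndarray:
        out = self.counts.astype(object).copy()
        out[self.mask] = SUPPRESSED_DISPLAY
        return out


def suppress(table) -> SuppressedTable:
    """Mask exactly the counts in {1, 2}; zeros and counts >= 3 are shown.

    Idempotent: suppressing a :class:`SuppressedTable` never unmasks.
    """
    if isinstance(table, SuppressedTable):
        counts = table.counts
        mask = table.mask | ((counts > 0) & (counts < 3))
        return SuppressedTable(counts, mask)
    counts = np.asarray(table, dtype=int)
    mask = (counts > 0) & (counts < 3)
    return SuppressedTable(counts, mask)


def suppress_value(count: int) -> str:
    return SUPPRESSED_DISPLAY if 0 < count < 3 else str(int(count))


def _pct(n: int, d: int, digits: int = 1) -> float:
    return round(100.0 * n / d, digits) if d else float("nan")


def _median_iqr(values) -> tuple[float, float]:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return float("nan"), float("nan")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Characteristics of the incident cohort stratified by SpA subgroup.

    Sex percentages use the non-missing denominator; each row carries the test
    actually applied (chi-squared or Fisher's exact) and its p-value.
    """
    rows = []
    if not len(cohort):
        return pd.DataFrame(
            columns=["characteristic", "level", "total", "total_pct",
                     "SpA", "SpA_pct", "non_SpA", "non_SpA_pct", "test", "p_value"]
        )
    spa = cohort[cohort["subgroup"] == "SpA"]
    non = cohort[cohort["subgroup"] == "non_SpA"]

    def add(characteristic, level, n_spa, n_non, d_spa, d_non, test=None, p=None):
        rows.append({
            "characteristic": characteristic, "level": level,
            "total": n_spa + n_non, "total_pct": _pct(n_spa + n_non, d_spa + d_non),
            "SpA": n_spa, "SpA_pct": _pct(n_spa, d_spa),
            "non_SpA": n_non, "non_SpA_pct": _pct(n_non, d_non),
            "test": test, "p_value": p,
        })

    # age bands at diagnosis
    from .epi import age_band
    bands_spa = spa["age_at_index"].map(age_band)
    bands_non = non["age_at_index"].map(age_band)
    age_counts = [[int((bands_spa == b).sum()), int((bands_non == b).sum())]
                  for b in AGE_BANDS]
    tbl = np.array(age_counts)
    test, p = (None, None)
    if tbl.sum() and (tbl.sum(axis=1) > 0).all() and (tbl.sum(axis=0) > 0).all():
        test, p = select_test(tbl) if tbl.shape == (2, 2) else ("chi_squared", chi_squared(tbl)[2])
    for b, (ns, nn) in zip(AGE_BANDS, age_counts):
        add("age_group", b, ns, nn, len(spa), len(non), test, p)

    # sex, excluding missing from percentage denominators
    sex_tbl = np.array([
        [int((spa["sex"] == "male").sum()), int((non["sex"] == "male").sum())],
        [int((spa["sex"] == "female").sum()), int((non["sex"] == "female").sum())],
    ])
    d_spa, d_non = int(sex_tbl[:, 0].sum()), int(sex_tbl[:, 1].sum())
    test, p = select_test(sex_tbl.T) if sex_tbl.sum() else (None, None)
    add("sex", "male", sex_tbl[0, 0], sex_tbl[0, 1], d_spa, d_non, test, p)
    add("sex", "female", sex_tbl[1, 0], sex_tbl[1, 1], d_spa, d_non, test, p)
    n_miss_spa = int((spa["sex"] == "missing").sum())
    n_miss_non = int((non["sex"] == "missing").sum())
    add("sex", "missing", n_miss_spa, n_miss_non, len(spa), len(non))

    for comorb in ("uveitis", "psoriasis"):
        a, c = int(spa[comorb].sum()), int(non[comorb].sum())
        tbl = np.array([[a, len(spa) - a], [c, len(non) - c]])
        test, p = (None, None)
        if tbl.sum() and (tbl.sum(axis=1) > 0).all() and (tbl.sum(axis=0) > 0).all():
            test, p = select_test(tbl)
        add("comorbidity", comorb, a, c, len(spa), len(non), test, p)
    return pd.DataFrame(rows)


def treatment_table(courses) -> pd.DataFrame:
    """Per-index-drug treatment patterns with suppression applied last.

    Counts per pattern, median (IQR) of time-to-index and index duration, the
    csDMARD combination shares, and KM cumulative discontinuation at 1/3/5
    years with 95% CI.
    """
    from .patterns import PATTERNS

    rows = []
    drugs = sorted({c.index_drug for c in courses})
    for drug in drugs + (["all"] if courses else []):
        sub = [c for c in courses if drug == "all" or c.index_drug == drug]
        n = len(sub)
        row: dict = {"index_drug": drug, "n": n}
        med, iqr = _median_iqr([c.time_to_index_years for c in sub
                                if c.time_to_index_years is not None])
        row["time_to_index_median_years"] = round(med, 2)
        row["time_to_index_iqr_years"] = round(iqr, 2)
        med, iqr = _median_iqr([c.index_duration_years for c in sub])
        row["index_duration_median_years"] = round(med, 2)
        row["index_duration_iqr_years"] = round(iqr, 2)
        k1 = sum(c.combo_csdmard_first_year for c in sub)
        k2 = sum(c.combo_csdmard_after for c in sub)
        row["combo_csdmard_first_year"] = suppress_value(k1)
        row["combo_csdmard_first_year_pct"] = _pct(k1, n)
        row["combo_csdmard_after"] = suppress_value(k2)
        row["combo_csdmard_after_pct"] = _pct(k2, n)
        for p_name in PATTERNS:
            k = sum(1 for c in sub if c.pattern == p_name)
            row[p_name] = suppress_value(k)
            row[f"{p_name}_pct"] = _pct(k, n)
        curve = km_fit([c.event_time_days for c in sub], [c.event for c in sub])
        m = km_median(curve)
        row["km_median_discontinuation_years"] = (
            round(m / 365.25, 2) if m is not None else None
        )
        for h in (1, 3, 5):
            rate, ci = cumulative_discontinuation(curve, h)
            row[f"discontinuation_{h}y_pct"] = round(100 * rate, 1)
            row[f"discontinuation_{h}y_ci"] = (
                f"{100 * ci[0]:.1f}-{100 * ci[1]:.1f}"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def build_reports(
    cohort: pd.DataFrame,
    courses,
    rates: pd.DataFrame,
    config: AnalysisConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit the demographic table, the treatment-pattern table, the rate table
    and a JSON summary under ``out_dir``; suppression is applied last."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    t1 = demographics_table(cohort)
    paths["table1"] = out_dir / "table1_demographics.csv"
    t1.to_csv(paths["table1"], index=False)

    t2 = treatment_table(courses) if courses else pd.DataFrame(
        columns=["index_drug", "n"]
    )
    paths["table2"] = out_dir / "table2_treatment_patterns.csv"
    t2.to_csv(paths["table2"], index=False)

    paths["rates"] = out_dir / "rates.csv"
    rates.to_csv(paths["rates"], index=False)

    summary = {
        "n_cohort": int(len(cohort)),
        "n_biologic_users": len(courses),
        "n_spa": int((cohort["subgroup"] == "SpA").sum()) if len(cohort) else 0,
    }
    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths
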