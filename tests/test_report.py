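"""Contingency statistics, suppression, and report assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import jia_claims as jc
from jia_claims.report import suppress_value


def test_chi_squared_examples():
    stat, df, p = jc.chi_squared([[10, 10], [10, 10]])
    assert stat == 0 and p == pytest.approx(1.0)
    stat, df, p = jc.chi_squared([[20, 0], [0, 20]])
    assert stat == pytest.approx(40.0) and df == 1
    # Table-1-style sex x subgroup comparison is overwhelmingly significant
    _, _, p = jc.chi_squared([[586, 381], [243, 478]])
    assert p < 0.0001


def test_chi_squared_errors():
    with pytest.raises(ValueError, match="margin"):
        jc.chi_squared([[0, 0], [5, 5]])
    with pytest.raises(ValueError):
        jc.chi_squared([[1, 2, 3]])


def test_chi_squared_matches_scipy(rng):
    for _ in range(200):
        shape = (int(rng.integers(2, 4)), int(rng.integers(2, 4)))
        tbl = rng.integers(1, 50, size=shape)
        stat, df, p = jc.chi_squared(tbl)
        ref = st.chi2_contingency(tbl, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_fisher_exact_examples():
    assert jc.fisher_exact([[1, 9], [11, 3]]) == pytest.approx(0.0027594561852, rel=1e-9)
    assert jc.fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        jc.fisher_exact([[1, 2, 3], [4, 5, 6]])


def test_fisher_agrees_with_chi_squared_direction_on_large_tables():
    # strongly associated large table: both tests point the same way
    strong = [[80, 20], [20, 80]]
    null = [[50, 50], [50, 50]]
    assert jc.fisher_exact(strong) < 0.001 and jc.chi_squared(strong)[2] < 0.001
    assert jc.fisher_exact(null) > 0.9 and jc.chi_squared(null)[2] > 0.9


def test_odds_ratio_uveitis_worked_example():
    """SpA 61/774 vs non-SpA 26/835 uveitis: OR about 2.5."""
    ratio, (lo, hi) = jc.odds_ratio([[61, 774], [26, 835]])
    assert ratio == pytest.approx(2.53, abs=0.01)
    assert lo < 2.53 < hi and lo > 1.0


def test_odds_ratio_identities():
    ratio, _ = jc.odds_ratio([[10, 10], [10, 10]])
    assert ratio == pytest.approx(1.0)
    a, _ = jc.odds_ratio([[12, 5], [7, 9]])
    b, _ = jc.odds_ratio([[5, 12], [9, 7]])
    assert a == pytest.approx(1 / b)
    # zero cell falls back to the continuity correction instead of failing
    ratio, _ = jc.odds_ratio([[5, 0], [3, 8]])
    assert np.isfinite(ratio) and ratio > 1


def test_suppression_rules_and_idempotence():
    table = np.array([[0, 1], [2, 3]])
    sup = jc.suppress(table)
    assert sup.mask.tolist() == [[False, True], [True, False]]
    disp = sup.display()
    assert disp[0, 0] == 0 and disp[1, 1] == 3
    assert disp[0, 1] == disp[1, 0] == "≤3"
    again = jc.suppress(sup)
    assert (again.mask == sup.mask).all()
    assert suppress_value(2) == "≤3" and suppress_value(0) == "0" and suppress_value(3) == "3"


def test_select_test_threshold_rule():
    name, _ = jc.select_test([[2, 8], [3, 7]])       # small expected cells
    assert name == "fisher_exact"
    name, _ = jc.select_test([[50, 60], [40, 30]])
    assert name == "chi_squared"


def _table1_cohort():
    """A cohort frame with realistic sex-by-subgroup margins, including missing."""
    rows = []

    def add(n, subgroup, sex):
        for _ in range(n):
            rows.append({"person_id": f"x{len(rows)}", "subgroup": subgroup,
                         "sex": sex, "age_at_index": 13, "uveitis": False,
                         "psoriasis": False})
    add(586, "SpA", "male"); add(243, "SpA", "female"); add(6, "SpA", "missing")
    add(381, "non_SpA", "male"); add(478, "non_SpA", "female"); add(2, "non_SpA", "missing")
    df = pd.DataFrame(rows)
    df["index_date"] = pd.Timestamp("2015-06-01")
    df["birth_date"] = pd.Timestamp("2002-06-01")
    df["followup_end"] = pd.Timestamp("2020-12-31")
    df["incident"] = True
    return df


def test_demographics_percentages_use_nonmissing_denominator():
    t1 = jc.demographics_table(_table1_cohort()).set_index(["characteristic", "level"])
    male = t1.loc[("sex", "male")]
    assert male["SpA_pct"] == 70.7          # 586 / 829, not / 835
    assert male["non_SpA_pct"] == 44.4      # 381 / 859
    assert male["p_value"] < 0.0001
    missing = t1.loc[("sex", "missing")]
    assert missing["SpA"] == 6 and missing["non_SpA"] == 2


def test_build_reports_empty_cohort(tmp_path):
    empty = pd.DataFrame(columns=["person_id", "subgroup", "sex", "age_at_index",
                                  "uveitis", "psoriasis", "index_date",
                                  "birth_date", "followup_end", "incident"])
    paths = jc.build_reports(empty, [], pd.DataFrame(), jc.AnalysisConfig(), tmp_path)
    t1 = pd.read_csv(paths["table1"])
    assert len(t1) == 0 and "characteristic" in t1.columns


def test_reports_are_self_consistent(small_sim, small_cohorts, tmp_path):
    """Every emitted percentage recomputes from its own numerator and the
    relevant denominator."""
    _, bundle, _ = small_sim
    _, incident, _ = small_cohorts
    frame = jc.cohort_frame(incident)
    courses = jc.extract_courses(bundle, frame)
    rates = jc.rates_frame(
        jc.stratified_rates(frame, bundle.denominators, {"year"}, kind="incidence")
    )
    paths = jc.build_reports(frame, courses, rates, jc.AnalysisConfig(), tmp_path)

    t1 = pd.read_csv(paths["table1"])
    sex_rows = t1[t1["characteristic"] == "sex"]
    d_spa = sex_rows[sex_rows["level"].isin(["male", "female"])]["SpA"].sum()
    for _, row in sex_rows.iterrows():
        if row["level"] == "missing":
            continue
        assert row["SpA_pct"] == pytest.approx(100 * row["SpA"] / d_spa, abs=0.05)

    t2 = pd.read_csv(paths["table2"]).set_index("index_drug")
    from jia_claims.patterns import PATTERNS
    for drug, row in t2.iterrows():
        shown = [row[p] for p in PATTERNS if str(row[p]) not in ("≤3",)]
        pcts = [row[f"{p}_pct"] for p in PATTERNS]
        assert sum(pcts) == pytest.approx(100.0, abs=0.3)
        for p in PATTERNS:
            if str(row[p]) != "≤3":
                assert row[f"{p}_pct"] == pytest.approx(
                    100 * int(row[p]) / row["n"], abs=0.05)

    r = pd.read_csv(paths["rates"])
    assert np.allclose(r["rate_per_100k"],
                       1e5 * r["numerator"] / r["denominator"])
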