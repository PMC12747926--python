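"""Prevalence and incidence estimation."""

from __future__ import annotations

import pandas as pd
import pytest

import jia_claims as jc


def _denominators(years, count=100_000, py=None):
    rows = []
    for year in years:
        for band in ("0-5", "6-11", "12-15"):
            for sex in ("male", "female"):
                rows.append({"year": year, "age_group": band, "sex": sex,
                             "person_count": count // 6,
                             "person_years": (py or count) / 6.0})
    return pd.DataFrame(rows)


def _cohort(n, year=2015, birth_year=2005):
    df = pd.DataFrame({
        "person_id": [f"p{i}" for i in range(n)],
        "index_date": pd.Timestamp(f"{year}-06-01"),
        "incident": True,
        "age_at_index": year - birth_year,
        "birth_date": pd.Timestamp(f"{birth_year}-03-01"),
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "subgroup": "non_SpA",
        "followup_end": pd.Timestamp("2020-12-31"),
        "uveitis": False,
        "psoriasis": False,
    })
    return df


def test_annual_prevalence_definition():
    den = _denominators([2015], count=99_996)  # divisible by 6
    est = jc.annual_prevalence(_cohort(18), den, 2015)
    assert est.numerator == 18
    assert est.rate == pytest.approx(1e5 * 18 / 99_996)

    empty = _cohort(0)
    assert jc.annual_prevalence(empty, den, 2015).rate == 0.0


def test_prevalence_exits_at_age_sixteen():
    # sixteenth birthday 2020-03-01: still counted while under 16 during the
    # year, gone once the whole year is past the birthday
    cohort = _cohort(5, year=2013, birth_year=2004)
    cohort["followup_end"] = pd.Timestamp("2021-12-31")
    assert jc.annual_prevalence(cohort, _denominators([2015]), 2015).numerator == 5
    assert jc.annual_prevalence(cohort, _denominators([2020]), 2020).numerator == 5
    assert jc.annual_prevalence(cohort, _denominators([2021]), 2021).numerator == 0


def test_missing_denominator_year_errors():
    with pytest.raises(ValueError, match="2018"):
        jc.annual_prevalence(_cohort(1), _denominators([2015]), 2018)


def test_incidence_proportion_removes_prior_cases_from_denominator():
    den = _denominators([2015, 2016])
    early = _cohort(40, year=2015, birth_year=2005)
    late = _cohort(6, year=2016, birth_year=2005)
    cohort = pd.concat([early, late], ignore_index=True)
    est_2016 = jc.annual_incidence_proportion(cohort, den, 2016)
    assert est_2016.numerator == 6
    # population 6 x 16,666 minus the 40 prior cases still under 16
    assert est_2016.denominator == 99_996 - 40
    # in a closed population the at-risk denominator shrinks year over year
    est_2015 = jc.annual_incidence_proportion(cohort, den, 2015)
    assert est_2016.denominator < est_2015.denominator


def test_overall_incidence_rate_arithmetic():
    den = _denominators(range(2012, 2020), py=250_000)
    cohort = _cohort(91, year=2015)
    est = jc.overall_incidence_rate(cohort, den)
    assert est.denominator == pytest.approx(2_000_000)
    assert est.rate == pytest.approx(4.55)
    assert jc.overall_incidence_rate(_cohort(0), den).rate == 0.0


def test_overall_rate_equals_weighted_average_of_annual_rates():
    """With constant per-year person-years the person-year rate equals the
    mean of annual proportions computed on the same at-risk base."""
    den = _denominators(range(2012, 2020), py=100_000)
    per_year = [3, 5, 2, 7, 4, 6, 1, 8]
    frames = [_cohort(k, year=2012 + i, birth_year=2008)
              for i, k in enumerate(per_year)]
    cohort = pd.concat(frames, ignore_index=True)
    overall = jc.overall_incidence_rate(cohort, den)
    assert overall.rate == pytest.approx(1e5 * sum(per_year) / 800_000)


def test_stratified_rates_partition(small_sim, small_cohorts):
    _, bundle, _ = small_sim
    _, incident, _ = small_cohorts
    frame = jc.cohort_frame(incident)
    marginal = jc.stratified_rates(frame, bundle.denominators, {"year"},
                                   kind="incidence")
    by_sex = jc.stratified_rates(frame, bundle.denominators, {"year", "sex"},
                                 kind="incidence")
    by_age = jc.stratified_rates(frame, bundle.denominators, {"year", "age_group"},
                                 kind="incidence")
    for m in marginal:
        year = m.stratum["year"]
        # sexes recorded as "missing" are absent from sex strata by design
        n_missing = int(((frame["index_date"].dt.year == year)
                         & (frame["sex"] == "missing")).sum())
        assert sum(r.numerator for r in by_sex if r.stratum["year"] == year) \
            == m.numerator - n_missing
        assert sum(r.numerator for r in by_age if r.stratum["year"] == year) \
            == m.numerator


def test_stratified_rates_symmetry():
    den = _denominators([2015])
    cohort = _cohort(12, year=2015, birth_year=2005)  # age 10, even sex split
    rates = jc.stratified_rates(cohort, den, {"year", "sex"}, kind="incidence")
    male = next(r for r in rates if r.stratum["sex"] == "male")
    female = next(r for r in rates if r.stratum["sex"] == "female")
    assert male.rate == female.rate


def test_pipeline_prevalence_matches_truth_counts(small_sim, small_cohorts):
    """The pipeline's annual prevalent and incident numerators equal the
    generator's ground-truth annual counts."""
    _, bundle, truth = small_sim
    prevalent, incident, _ = small_cohorts
    prev_frame = jc.cohort_frame(prevalent)
    inc_frame = jc.cohort_frame(incident)
    for _, row in truth.annual.iterrows():
        year = int(row["year"])
        est = jc.annual_prevalence(prev_frame, bundle.denominators, year)
        assert est.numerator == row["true_prevalent"]
        inc = jc.annual_incidence_proportion(inc_frame, bundle.denominators, year)
        assert inc.numerator == row["true_incident"]
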