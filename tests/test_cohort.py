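"""Case definition, cohort assembly, and subgroup classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import jia_claims as jc
from jia_claims.core import empty_bundle
from oracles import qualify_scan


@pytest.mark.parametrize(
    "events, expected",
    [
        # three outpatient codes spanning 300 days -> qualifies at the third
        ([(0, "outpatient"), (100, "outpatient"), (300, "outpatient")], 300),
        # spread beyond any 365-day window -> never qualifies
        ([(0, "outpatient"), (200, "outpatient"), (400, "outpatient")], None),
        # a single inpatient code qualifies immediately
        ([(50, "inpatient")], 50),
        # inpatient beats a later outpatient triple
        ([(10, "outpatient"), (40, "inpatient"), (60, "outpatient"),
          (90, "outpatient")], 40),
        # duplicate same-day outpatient codes collapse to one visit day
        ([(0, "outpatient"), (0, "outpatient"), (30, "outpatient")], None),
        ([], None),
    ],
)
def test_qualify_case_examples(events, expected):
    assert jc.qualify_case(events) == expected


def test_qualify_case_rejects_unsorted():
    with pytest.raises(ValueError, match="sorted"):
        jc.qualify_case([(100, "outpatient"), (0, "outpatient")])


def test_qualify_case_matches_window_scan_oracle(rng):
    """Sliding-triple qualification equals an exhaustive all-triples scan on
    1,000 random small timelines."""
    for _ in range(1000):
        n = int(rng.integers(0, 8))
        days = sorted(rng.integers(0, 900, size=n))
        settings = rng.choice(["outpatient", "inpatient"], size=n, p=[0.9, 0.1])
        events = list(zip((int(d) for d in days), settings))
        assert jc.qualify_case(events) == qualify_scan(events)


@pytest.mark.parametrize(
    "fills, first_dx, expected",
    [
        ([(0, 30)], 0, True),            # 30 days > 14
        ([(0, 14)], 0, False),           # exactly 14 is not "more than 14"
        ([(0, 10), (12, 10)], 0, True),  # gap 2 <= grace, merged span 22
        ([(0, 10), (30, 10)], 0, False), # gap 20 > grace: two short episodes
        ([(400, 30)], 0, False),         # outside the 365-day window
        ([(-20, 30)], 0, True),          # episode started before dx but intersects
        ([], 0, False),
    ],
)
def test_nsaid_criterion(fills, first_dx, expected):
    assert jc.nsaid_criterion(sorted(fills), first_dx) is expected


def _mini_bundle():
    """Three hand-built persons: a clean incident case, a prevalent-only case
    with pre-window history, and a person aged 16 at index."""
    bundle = empty_bundle()
    ts = pd.Timestamp
    bundle.beneficiaries = pd.DataFrame({
        "person_id": ["A", "B", "C"],
        "sex": ["female", "male", "male"],
        "birth_date": [ts("2005-03-01"), ts("2004-06-01"), ts("1997-01-10")],
        "enroll_start": [ts("2011-01-01")] * 3,
        "enroll_end": [ts("2021-01-01")] * 3,
    })
    rows = []

    def dx(pid, when, setting="outpatient", code=None):
        d = ts(when)
        system = "ICD9CM" if d < ts("2016-01-01") else "ICD10CM"
        code = code or ("714.30" if system == "ICD9CM" else "M08.9")
        rows.append((pid, d, setting, code, system, "v"))

    # A: qualifies 2013 with outpatient triple, no prior history
    dx("A", "2013-05-01"); dx("A", "2013-07-01"); dx("A", "2013-10-01")
    # B: JIA codes in 2011 (washout) and qualifying codes in 2013
    dx("B", "2011-06-01")
    dx("B", "2013-02-01"); dx("B", "2013-04-01"); dx("B", "2013-06-01")
    # C: qualifies but is 16 at index (born 1997-01-10, index 2013-03-01)
    dx("C", "2013-03-01", setting="inpatient")
    df = pd.DataFrame(rows, columns=["person_id", "date", "setting", "code",
                                     "code_system", "visit_id"])
    cfg = jc.AnalysisConfig()
    df["dx_group"] = [cfg.code_group(c, s) for c, s in zip(df["code"], df["code_system"])]
    bundle.diagnoses = df[["person_id", "date", "setting", "code", "code_system",
                           "dx_group", "visit_id"]]
    bundle.prescriptions = pd.DataFrame({
        "person_id": ["A", "B", "C"],
        "fill_date": [ts("2013-05-02"), ts("2013-02-02"), ts("2013-03-02")],
        "days_supply": [30, 30, 30],
        "drug_class": ["NSAID"] * 3,
        "drug_name": ["naproxen"] * 3,
        "visit_id": ["vA", "vB", "vC"],
    })
    return bundle


def test_build_cohorts_inclusion_and_washout():
    prevalent, incident, flow = jc.build_cohorts(_mini_bundle())
    prev_ids = {m.person_id for m in prevalent}
    inc_ids = {m.person_id for m in incident}
    assert prev_ids == {"A", "B"}         # C excluded: 16 at index
    assert inc_ids == {"A"}               # B excluded by pre-2012 history
    assert flow["excluded_age"] == 1
    assert flow["excluded_prior_history"] == 1
    member_a = next(m for m in prevalent if m.person_id == "A")
    assert member_a.index_date.isoformat() == "2013-05-01"
    assert member_a.age_at_index == 8


def test_incident_subset_of_prevalent(small_cohorts):
    prevalent, incident, _ = small_cohorts
    prev_ids = {m.person_id for m in prevalent}
    assert all(m.person_id in prev_ids for m in incident)
    assert all(m.incident for m in incident)


def test_cohort_recovers_truth_labels_excluding_near_misses(small_sim, small_cohorts):
    """On tampering-free synthetic data the pipeline cohort equals the true
    case set, the incident subset equals the true incident set, and every
    configured near-miss is excluded."""
    _, _, truth = small_sim
    prevalent, incident, _ = small_cohorts
    t = truth.persons
    assert {m.person_id for m in prevalent} == set(t.loc[t["is_case"], "person_id"])
    assert {m.person_id for m in incident} == set(
        t.loc[t["is_case"] & t["incident"], "person_id"]
    )
    near = set(t.loc[t["near_miss_type"] != "", "person_id"])
    assert near and near.isdisjoint({m.person_id for m in prevalent})


def test_cohort_subgroup_and_comorbidities_match_truth(small_sim, small_cohorts):
    _, _, truth = small_sim
    prevalent, _, _ = small_cohorts
    frame = jc.cohort_frame(prevalent).set_index("person_id")
    t = truth.persons[truth.persons["is_case"]].set_index("person_id")
    assert (frame["subgroup"] == t.loc[frame.index, "subgroup"]).all()
    assert (frame["uveitis"] == t.loc[frame.index, "uveitis"]).all()
    assert (frame["psoriasis"] == t.loc[frame.index, "psoriasis"]).all()


def _dx_frame(rows):
    return pd.DataFrame(rows, columns=["person_id", "date", "setting", "code",
                                       "code_system", "dx_group", "visit_id"])


def test_classify_subgroup_rules():
    ts = pd.Timestamp
    jia = ("P", ts("2013-01-01"), "outpatient", "714.30", "ICD9CM", "JIA", "v1")
    sacro = ("P", ts("2014-01-01"), "outpatient", "720.2", "ICD9CM", "SpA_feature", "v2")
    psa_same_day = ("P", ts("2013-01-01"), "outpatient", "696.0", "ICD9CM",
                    "SpA_feature", "v3")
    assert jc.classify_subgroup(_dx_frame([jia, sacro])) == "SpA"
    assert jc.classify_subgroup(_dx_frame([jia])) == "non_SpA"
    assert jc.classify_subgroup(_dx_frame([jia, psa_same_day])) == "SpA"
    # strict same-day mode: a feature code on a different day no longer counts
    strict = jc.AnalysisConfig(spa_same_day_only=True)
    assert jc.classify_subgroup(_dx_frame([jia, sacro]), strict) == "non_SpA"
    assert jc.classify_subgroup(_dx_frame([jia, psa_same_day]), strict) == "SpA"
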