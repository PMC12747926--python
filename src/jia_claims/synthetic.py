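"""Synthetic claims generator with known ground truth.

Emulates the statistical structure of a pediatric administrative-claims cohort:
an under-16 population enrolled 2011-2020, juvenile-arthritis onsets arriving
at a configurable annual hazard (default 5.5 per 100,000), a SpA-feature
subgroup with its own sex and onset-age profile, diagnosis claims that satisfy
the claims case definition (one inpatient or three outpatient codes within 365
days plus the NSAID criterion), chronic NSAID/csDMARD/steroid therapy, and
biologic treatment courses driven by piecewise-exponential hazards per 30-day
interval (stop, switch-within-gap, restart).

Every run returns a :class:`GroundTruth` with per-person case labels, subgroup,
true index-biologic interval and true terminal pattern, computed from the
latent simulation events — independently of the downstream classifiers — so
every pipeline stage can be checked against known truth.  The same seed yields
byte-identical output; per-case randomness comes from sub-streams keyed by
(seed, person index) so the population draw and the case histories are stably
decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .config import INDEX_BIOLOGICS, AnalysisConfig
from .core import (
    BENEFICIARY_COLUMNS,
    DENOMINATOR_COLUMNS,
    DIAGNOSIS_COLUMNS,
    PRESCRIPTION_COLUMNS,
    ClaimsBundle,
    date_to_day,
    expected_code_system,
)

DAYS_PER_YEAR = 365.2425
SUBGROUPS = ("SpA", "non_SpA")
NEAR_MISS_TYPES = ("two_outpatient", "spread_codes", "short_nsaid", "no_nsaid")


@dataclass
class GeneratorConfig:
    """All calibration knobs of the simulator.

    Defaults reproduce the study conditions: onset hazard 5.5/100,000/year,
    SpA share 49.2% with 70.7% male (44.4% in non-SpA), adolescent-dominated
    onset ages, subgroup-specific biologic uptake (15.2% / 23.1%), and
    28-day biologic refill cadence.
    """

    seed: int = 0
    n_population: int = 300_000
    birth_start: date = date(1996, 1, 1)
    birth_end: date = date(2020, 1, 1)

    onset_hazard_per_100k: float = 5.5
    spa_fraction: float = 0.492
    male_fraction: dict = field(default_factory=lambda: {"SpA": 0.707, "non_SpA": 0.444})
    # onset-age shares over the bands 0-5 / 6-11 / 12-15, per subgroup
    onset_age_shares: dict = field(default_factory=lambda: {
        "SpA": (0.008, 0.146, 0.846),
        "non_SpA": (0.125, 0.357, 0.518),
    })
    uveitis_prob: dict = field(default_factory=lambda: {"SpA": 0.073, "non_SpA": 0.030})
    psoriasis_prob: dict = field(default_factory=lambda: {"SpA": 0.029, "non_SpA": 0.0})
    missing_sex_fraction: float = 0.005

    inpatient_qualify_prob: float = 0.15
    near_miss_fraction: float = 0.10
    background_noise_rate: float = 0.002

    chronic_use_prob: dict = field(default_factory=lambda: {
        "nsaid": {"SpA": 0.51, "non_SpA": 0.51},
        "methotrexate": {"SpA": 0.25, "non_SpA": 0.389},
        "sulfasalazine": {"SpA": 0.388, "non_SpA": 0.16},
        "steroid": {"SpA": 0.20, "non_SpA": 0.278},
    })
    biologic_uptake: dict = field(default_factory=lambda: {"SpA": 0.152, "non_SpA": 0.231})
    index_drug_shares: dict = field(default_factory=lambda: {
        "etanercept": 0.417, "adalimumab": 0.509, "tocilizumab": 0.074,
    })
    time_to_index_median_years: float = 0.73
    stop_hazard_per_30d: float = 0.016
    switch_given_stop: float = 0.24
    switch_to_abatacept_prob: float = 0.05
    restart_prob: float = 0.75              # interruptions that ever restart
    restart_gap_median_days: float = 58.0   # beyond the 60-day grace
    restart_same_drug_prob: float = 0.9
    combo_first_year_prob: float = 0.90
    combo_after_prob: float = 0.50

    biologic_cadence_days: int = 28
    biologic_supply_days: int = 28
    fill_jitter_days: int = 3

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    tamper: dict | None = None   # e.g. {"dialect": 2, "enroll_overlap": 1}

    def validate(self) -> None:
        if not 0 <= self.onset_hazard_per_100k <= 100_000:
            raise ValueError("onset hazard must be in [0, 100000] per 100,000")
        probs = [self.spa_fraction, self.missing_sex_fraction,
                 self.inpatient_qualify_prob, self.near_miss_fraction,
                 self.background_noise_rate, self.switch_given_stop,
                 self.restart_same_drug_prob, self.restart_prob,
                 self.combo_first_year_prob,
                 self.combo_after_prob, self.stop_hazard_per_30d,
                 *self.male_fraction.values(), *self.uveitis_prob.values(),
                 *self.psoriasis_prob.values(), *self.biologic_uptake.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.index_drug_shares.values()) - 1.0) > 1e-6:
            raise ValueError("index drug shares must sum to 1")
        if self.n_population < 1:
            raise ValueError("n_population must be positive")


@dataclass
class GroundTruth:
    """Per-person truth for cases/controls with claims, plus annual counts."""

    persons: pd.DataFrame
    annual: pd.DataFrame


class _Emitter:
    """Accumulates claim rows and hands out per-encounter visit ids."""

    def __init__(self, gen_cfg: GeneratorConfig):
        self.cfg = gen_cfg.analysis
        self.dx_rows: list[tuple] = []
        self.rx_rows: list[tuple] = []
        self._visit_seq: dict[tuple, int] = {}

    def visit_id(self, pid: str, day: int, new: bool = True) -> str:
        key = (pid, day)
        if new or key not in self._visit_seq:
            self._visit_seq[key] = self._visit_seq.get(key, -1) + 1
        return f"v-{pid}-{day}-{self._visit_seq[key]}"

    def dx(self, pid: str, day: int, setting: str, group: str, rng, visit: str | None = None):
        d = date.fromordinal(day + date(1970, 1, 1).toordinal())
        system = expected_code_system(d)
        codes = self.cfg.dx_codes[group][system]
        code = codes[int(rng.integers(len(codes)))]
        self.dx_rows.append(
            (pid, day, setting, code, system, group, visit or self.visit_id(pid, day))
        )

    def rx(self, pid: str, day: int, supply: int, drug: str, visit: str | None = None):
        cls = self.cfg.drug_class_of(drug)
        self.rx_rows.append(
            (pid, day, int(supply), cls, drug, visit or self.visit_id(pid, day))
        )


def _sixteenth_birthday_day(birth_day: int) -> int:
    """Exact day of the 16th birthday (calendar arithmetic)."""
    b = date.fromordinal(int(birth_day) + date(1970, 1, 1).toordinal())
    try:
        sixteenth = b.replace(year=b.year + 16)
    except ValueError:  # Feb 29
        sixteenth = b.replace(year=b.year + 16, month=3, day=1)
    return date_to_day(sixteenth)


def _assign_subgroup(cfg: GeneratorConfig, rng, sex: str, band: int) -> str:
    """Posterior subgroup draw given sex and onset-age band (naive-Bayes mixing)."""
    pi = cfg.spa_fraction
    like = {}
    for sub in SUBGROUPS:
        l_age = cfg.onset_age_shares[sub][band]
        if sex == "male":
            l_sex = cfg.male_fraction[sub]
        elif sex == "female":
            l_sex = 1.0 - cfg.male_fraction[sub]
        else:
            l_sex = 1.0
        like[sub] = l_age * l_sex
    w_spa = pi * like["SpA"]
    w_non = (1 - pi) * like["non_SpA"]
    total = w_spa + w_non
    p = 0.5 if total == 0 else w_spa / total
    return "SpA" if rng.random() < p else "non_SpA"


def _simulate_course(cfg: GeneratorConfig, rng, em: _Emitter, pid: str,
                     subgroup: str, onset_day: int, followup_end: int) -> dict | None:
    """Emit biologic (and combination csDMARD) fills; return latent course facts."""
    median_days = cfg.time_to_index_median_years * DAYS_PER_YEAR
    delay = rng.exponential(median_days / np.log(2))
    index_start = onset_day + 30 + int(delay)
    if index_start > followup_end - 120:
        return None
    drugs = list(cfg.index_drug_shares)
    shares = np.array([cfg.index_drug_shares[d] for d in drugs])
    index_drug = drugs[int(rng.choice(len(drugs), p=shares / shares.sum()))]

    cadence, supply, jit = (cfg.biologic_cadence_days, cfg.biologic_supply_days,
                            cfg.fill_jitter_days)

    def fill_days(start: int, n_max: int | None = None) -> list[int]:
        days, day, k = [], start, 0
        while day <= followup_end - 1 and (n_max is None or k < n_max):
            days.append(day)
            day += cadence + int(rng.integers(-jit, jit + 1))
            k += 1
        return days

    n_stop = int(rng.geometric(cfg.stop_hazard_per_30d)) if cfg.stop_hazard_per_30d > 0 else 10**9
    index_fills = fill_days(index_start, n_stop)
    episode_end = index_fills[-1] + supply

    switch_day = switch_drug = restart_day = restart_drug = None
    ran_to_end = len(index_fills) < n_stop  # cadence ran out of follow-up first
    if not ran_to_end:
        others = [d for d in INDEX_BIOLOGICS if d != index_drug]
        if rng.random() < cfg.switch_given_stop:
            day = episode_end + int(rng.integers(0, 61))
            if day <= followup_end - 1:
                switch_day = day
                switch_drug = ("abatacept" if rng.random() < cfg.switch_to_abatacept_prob
                               else others[int(rng.integers(len(others)))])
        elif rng.random() < cfg.restart_prob:
            gap = 61 + rng.exponential(cfg.restart_gap_median_days / np.log(2))
            day = episode_end + int(gap)
            if day <= followup_end - 1:
                restart_day = day
                restart_drug = (index_drug if rng.random() < cfg.restart_same_drug_prob
                                else others[int(rng.integers(len(others)))])

    # emit fills; csDMARD combination shares the dispensing visit
    combo_first = rng.random() < cfg.combo_first_year_prob
    combo_after = rng.random() < cfg.combo_after_prob
    combo_drug = "sulfasalazine" if subgroup == "SpA" else "methotrexate"
    for day in index_fills:
        visit = em.visit_id(pid, day)
        em.rx(pid, day, supply, index_drug, visit)
        in_first_year = day < index_start + 365
        if (in_first_year and combo_first) or (not in_first_year and combo_after):
            em.rx(pid, day, 28, combo_drug, visit)
    if switch_day is not None:
        for day in fill_days(switch_day, int(rng.integers(3, 20))):
            em.rx(pid, day, supply, switch_drug)
    if restart_day is not None:
        for day in fill_days(restart_day, int(rng.integers(3, 20))):
            em.rx(pid, day, supply, restart_drug)

    # truth label from the latent events, by the pattern definitions
    if switch_day is not None:
        pattern = "switching"
    elif restart_day is not None:
        pattern = "restart"
    elif episode_end + cfg.analysis.grace_biologic_days < followup_end:
        pattern = "discontinuation"
    else:
        pattern = "continuation"
    return {
        "index_drug": index_drug,
        "index_start": index_start,
        "index_episode_end": episode_end,
        "pattern": pattern,
        "restart_day": restart_day,
        "combo_first_year": combo_first and bool(index_fills),
    }


def _emit_case_claims(cfg: GeneratorConfig, rng, em: _Emitter, pid: str,
                      subgroup: str, onset_day: int, id_start: int,
                      flags: dict, id_end: int, followup_end: int) -> dict:
    """Diagnosis and standard-therapy claims for one true case.

    Cases with onset before the identification window (prevalent history) get
    their diagnostic work-up and NSAID course re-anchored at a re-presentation
    visit shortly after the window opens, mirroring continued care for an
    established diagnosis; the pre-window codes trigger the washout exclusion
    from the incident cohort.
    """
    prevalent_history = onset_day < id_start
    anchor = onset_day
    if prevalent_history:
        # pre-window onset codes (these alone never satisfy the in-window criterion)
        em.dx(pid, onset_day, "outpatient", "JIA", rng)
        if onset_day + 40 < id_start:
            em.dx(pid, onset_day + 40, "outpatient", "JIA", rng)
        anchor = id_start + int(rng.integers(0, 91))

    inpatient = (rng.random() < cfg.inpatient_qualify_prob
                 or anchor > id_end - 151)
    if inpatient:
        em.dx(pid, anchor, "inpatient", "JIA", rng)
    else:
        g1 = int(rng.integers(21, 61))
        g2 = int(rng.integers(30, 90))
        for d in (anchor, anchor + g1, anchor + g1 + g2):
            em.dx(pid, d, "outpatient", "JIA", rng)
    # ongoing care: quarterly-ish visits over the disease course
    duration = int(rng.uniform(1.0, 6.0) * 365)
    day = anchor + 180
    while day < min(anchor + duration, followup_end):
        em.dx(pid, day, "outpatient", "JIA", rng)
        day += 90 + int(rng.integers(0, 61))

    if subgroup == "SpA":
        for _ in range(int(rng.integers(1, 3))):
            d = min(anchor + int(rng.integers(0, 61)), followup_end)
            em.dx(pid, d, "outpatient", "SpA_feature", rng)
    if flags["psoriasis"]:
        d = min(anchor + int(rng.integers(0, 200)), followup_end)
        em.dx(pid, d, "outpatient", "psoriasis", rng)
    if flags["uveitis"]:
        d = min(anchor + int(rng.integers(30, 300)), followup_end)
        em.dx(pid, d, "outpatient", "uveitis", rng)

    chronic = cfg.chronic_use_prob
    nsaid_start = anchor + int(rng.integers(0, 11))
    if rng.random() < chronic["nsaid"][subgroup]:
        run = int(rng.uniform(120, 400))
    else:
        run = int(rng.uniform(30, 60))
    day, end = nsaid_start, min(nsaid_start + run, followup_end)
    nsaid = ["naproxen", "ibuprofen", "diclofenac", "celecoxib"][int(rng.integers(4))]
    while day < end:
        em.rx(pid, day, 30, nsaid)
        day += 28 + int(rng.integers(-3, 4))

    for drug, key in (("methotrexate", "methotrexate"),
                      ("sulfasalazine", "sulfasalazine"),
                      ("prednisolone", "steroid")):
        if rng.random() < chronic[key][subgroup]:
            start = anchor + int(rng.integers(14, 91))
            run = int(rng.uniform(120, 720)) if key != "steroid" else int(rng.uniform(90, 300))
            day, end = start, min(start + run, followup_end)
            while day < end:
                em.rx(pid, day, 30, drug)
                day += 28 + int(rng.integers(-2, 3))

    course = None
    if rng.random() < cfg.biologic_uptake[subgroup]:
        course = _simulate_course(cfg, rng, em, pid, subgroup, anchor, followup_end)
    return {"course": course}


def _emit_near_miss(cfg: GeneratorConfig, rng, em: _Emitter, pid: str,
                    onset_day: int, kind: str) -> None:
    """Claims for a control failing exactly one inclusion criterion."""
    if kind == "two_outpatient":
        for d in (onset_day, onset_day + 40):
            em.dx(pid, d, "outpatient", "JIA", rng)
        em.rx(pid, onset_day + 2, 30, "naproxen")
    elif kind == "spread_codes":
        for d in (onset_day, onset_day + 200, onset_day + 400):
            em.dx(pid, d, "outpatient", "JIA", rng)
        em.rx(pid, onset_day + 2, 30, "naproxen")
    elif kind == "short_nsaid":
        for d in (onset_day, onset_day + 40, onset_day + 90):
            em.dx(pid, d, "outpatient", "JIA", rng)
        em.rx(pid, onset_day + 2, 14, "naproxen")
    elif kind == "no_nsaid":
        for d in (onset_day, onset_day + 40, onset_day + 90):
            em.dx(pid, d, "outpatient", "JIA", rng)
    else:
        raise ValueError(f"unknown near-miss kind {kind!r}")


def generate_bundle(cfg: GeneratorConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Simulate a claims bundle and its ground truth.

    The output passes :func:`jia_claims.core.validate_bundle` unless the
    ``tamper`` option injects violations, and the same config (seed included)
    reproduces it exactly.
    """
    cfg.validate()
    ana = cfg.analysis
    rng_pop = np.random.default_rng([cfg.seed, 0])

    n = cfg.n_population
    b0, b1 = date_to_day(cfg.birth_start), date_to_day(cfg.birth_end)
    births = rng_pop.integers(b0, b1, size=n)
    true_sex = np.where(rng_pop.random(n) < 0.5, "male", "female")
    recorded_sex = true_sex.copy()
    recorded_sex[rng_pop.random(n) < cfg.missing_sex_fraction] = "missing"

    study_start = date_to_day(ana.study_start)
    study_end = date_to_day(ana.study_end)
    id_start = date_to_day(ana.identification_start)
    id_end = date_to_day(ana.identification_end)
    followup_end = date_to_day(ana.followup_cutoff)

    # onset mix over (age band x sex) cells implied by the subgroup mixture;
    # weighting the hazard by these targets makes the onset-age and sex-by-
    # subgroup profiles (and the SpA fraction) exactly recoverable
    target_cell = np.zeros((3, 2))  # [band, sex] with 0=male, 1=female
    for g in range(3):
        for s, sex_name in enumerate(("male", "female")):
            for sub, pi in (("SpA", cfg.spa_fraction),
                            ("non_SpA", 1 - cfg.spa_fraction)):
                m = cfg.male_fraction[sub]
                p_sex = m if sex_name == "male" else 1 - m
                target_cell[g, s] += pi * cfg.onset_age_shares[sub][g] * p_sex
    band_edges_days = (np.array([0, 6, 12, 16]) * DAYS_PER_YEAR).astype(int)
    sex01 = (true_sex == "female").astype(np.int8)

    onset_day = np.full(n, -1, dtype=np.int64)
    onset_band = np.full(n, -1, dtype=np.int8)
    hazard = cfg.onset_hazard_per_100k / 100_000.0
    years = range(ana.study_start.year, ana.identification_end.year)  # 2011..2019
    for year in years:
        jul1 = date_to_day(date(year, 7, 1))
        y0 = date_to_day(date(year, 1, 1))
        y1 = date_to_day(date(year + 1, 1, 1))
        age_days = jul1 - births
        band = np.searchsorted(band_edges_days, age_days, side="right") - 1
        at_risk = (age_days >= 0) & (band >= 0) & (band <= 2) & (onset_day < 0)
        if hazard > 0 and at_risk.any():
            n_at_risk = int(at_risk.sum())
            cell = np.clip(band, 0, 2) * 2 + sex01
            counts = np.bincount(cell[at_risk], minlength=6).astype(float)
            weights = np.zeros(6)
            nz = counts > 0
            weights[nz] = target_cell.ravel()[nz] * n_at_risk / counts[nz]
            p = np.zeros(n)
            p[at_risk] = hazard * weights[cell[at_risk]]
            hit = rng_pop.random(n) < p
            if hit.any():
                idx = np.nonzero(hit)[0]
                # onset anywhere in the year but safely before the 16th birthday
                hi = np.minimum(y1, births[idx] + int(16 * DAYS_PER_YEAR) - 6)
                lo = np.minimum(np.full(idx.size, y0), hi - 1)
                onset_day[idx] = (lo + (rng_pop.random(idx.size) * (hi - lo)).astype(np.int64))
                onset_band[idx] = band[idx]

    case_idx = np.nonzero(onset_day >= 0)[0]
    # drop 2011 onsets too old to re-qualify inside the identification window
    keep = []
    for i in case_idx:
        if onset_day[i] >= id_start:
            keep.append(i)
        elif _sixteenth_birthday_day(births[i]) > id_start + 200:
            keep.append(i)
        # else: too close to aging out — no claims emitted, not a case
    case_idx = np.array(keep, dtype=np.int64)

    # near-miss controls and background rule-out noise, drawn from non-cases
    non_case = np.nonzero(onset_day < 0)[0]
    eligible_nm = non_case[
        (births[non_case] + int(10 * DAYS_PER_YEAR) > id_start)
        & (births[non_case] < id_end - int(2 * DAYS_PER_YEAR))
    ]
    n_nm = int(round(cfg.near_miss_fraction * len(case_idx)))
    n_bg = int(round(cfg.background_noise_rate * n))
    picked = rng_pop.choice(eligible_nm, size=min(len(eligible_nm), n_nm + n_bg),
                            replace=False) if len(eligible_nm) else np.array([], dtype=int)
    nm_idx, bg_idx = picked[:n_nm], picked[n_nm:]

    em = _Emitter(cfg)
    truth_rows: list[dict] = []

    for k, i in enumerate(case_idx):
        rng = np.random.default_rng([cfg.seed, 1, int(i)])
        pid = f"p{int(i):07d}"
        o = int(onset_day[i])
        sex = str(true_sex[i])
        band = int(np.clip(onset_band[i], 0, 2))
        subgroup = _assign_subgroup(cfg, rng, sex, band)
        flags = {
            "uveitis": rng.random() < cfg.uveitis_prob[subgroup],
            "psoriasis": rng.random() < cfg.psoriasis_prob[subgroup],
        }
        out = _emit_case_claims(cfg, rng, em, pid, subgroup, o, id_start, flags,
                                id_end, followup_end)
        course = out["course"]
        truth_rows.append({
            "person_id": pid,
            "is_case": True,
            "near_miss_type": "",
            "onset_day": o,
            "incident": o >= id_start,
            "subgroup": subgroup,
            "sex": sex,
            "birth_day": int(births[i]),
            "uveitis": flags["uveitis"],
            "psoriasis": flags["psoriasis"],
            "biologic_user": course is not None,
            "index_drug": course["index_drug"] if course else "",
            "index_start_day": course["index_start"] if course else -1,
            "index_episode_end_day": course["index_episode_end"] if course else -1,
            "pattern": course["pattern"] if course else "",
            "restart_day": (course["restart_day"] if course and course["restart_day"]
                            else -1),
        })

    for k, i in enumerate(nm_idx):
        rng = np.random.default_rng([cfg.seed, 2, int(i)])
        pid = f"p{int(i):07d}"
        kind = NEAR_MISS_TYPES[k % len(NEAR_MISS_TYPES)]
        lo = max(id_start, int(births[i]))
        hi = min(id_end - 500, _sixteenth_birthday_day(int(births[i])) - 520)
        if hi <= lo:
            continue
        o = int(lo + rng.random() * (hi - lo))
        _emit_near_miss(cfg, rng, em, pid, o, kind)
        truth_rows.append({
            "person_id": pid, "is_case": False, "near_miss_type": kind,
            "onset_day": o, "incident": False, "subgroup": "", "sex": str(true_sex[i]),
            "birth_day": int(births[i]), "uveitis": False, "psoriasis": False,
            "biologic_user": False, "index_drug": "", "index_start_day": -1,
            "index_episode_end_day": -1, "pattern": "", "restart_day": -1,
        })

    for i in bg_idx:
        rng = np.random.default_rng([cfg.seed, 3, int(i)])
        pid = f"p{int(i):07d}"
        lo = max(id_start, int(births[i]) + 30)
        hi = min(id_end - 60, _sixteenth_birthday_day(int(births[i])) - 60)
        if hi <= lo:
            continue
        d = int(lo + rng.random() * (hi - lo))
        em.dx(pid, d, "outpatient", "JIA", rng)
        if rng.random() < 0.5:
            em.dx(pid, d + int(rng.integers(30, 200)), "outpatient", "JIA", rng)

    bundle = _assemble_bundle(cfg, births, recorded_sex, true_sex, em,
                              study_start, study_end)
    truth = _assemble_truth(cfg, truth_rows)
    if cfg.tamper:
        _apply_tamper(bundle, cfg)
    return bundle, truth


def _assemble_bundle(cfg: GeneratorConfig, births, recorded_sex, true_sex,
                     em: _Emitter, study_start: int, study_end: int) -> ClaimsBundle:
    ana = cfg.analysis
    n = cfg.n_population
    pids = np.array([f"p{i:07d}" for i in range(n)])
    enroll_start = np.maximum(births, study_start)
    epoch = np.datetime64("1970-01-01")

    ben = pd.DataFrame({
        "person_id": pids,
        "sex": recorded_sex,
        "birth_date": epoch + births.astype("timedelta64[D]"),
        "enroll_start": epoch + enroll_start.astype("timedelta64[D]"),
        "enroll_end": epoch + np.full(n, study_end).astype("timedelta64[D]"),
    })[BENEFICIARY_COLUMNS]

    if em.dx_rows:
        dx = pd.DataFrame(em.dx_rows, columns=["person_id", "day", "setting", "code",
                                               "code_system", "dx_group", "visit_id"])
        dx["date"] = epoch + dx.pop("day").values.astype("int64").astype("timedelta64[D]")
        dx = dx.sort_values(["person_id", "date", "setting"],
                            kind="stable").reset_index(drop=True)[DIAGNOSIS_COLUMNS]
    else:
        dx = pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "date" else object)
                           for c in DIAGNOSIS_COLUMNS})

    if em.rx_rows:
        rx = pd.DataFrame(em.rx_rows, columns=["person_id", "day", "days_supply",
                                               "drug_class", "drug_name", "visit_id"])
        rx["fill_date"] = epoch + rx.pop("day").values.astype("int64").astype("timedelta64[D]")
        rx = rx.sort_values(["person_id", "fill_date", "drug_name"],
                            kind="stable").reset_index(drop=True)[PRESCRIPTION_COLUMNS]
    else:
        rx = pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "fill_date"
                                        else (int if c == "days_supply" else object))
                           for c in PRESCRIPTION_COLUMNS})

    den = _analytic_denominators(cfg, births, true_sex)
    return ClaimsBundle(
        beneficiaries=ben,
        diagnoses=dx,
        prescriptions=rx,
        denominators=den,
        study_window=(ana.study_start, ana.study_end),
        identification_window=(ana.identification_start, ana.identification_end),
    )


def _analytic_denominators(cfg: GeneratorConfig, births, true_sex) -> pd.DataFrame:
    """Annual under-16 person counts and person-years by age band and sex.

    Computed analytically from the simulated population (every person is
    enrolled from birth or study start to study end); age-band boundaries use
    the mean calendar-year length.
    """
    ana = cfg.analysis
    rows = []
    band_lo = (np.array([0, 6, 12]) * DAYS_PER_YEAR).astype(int)
    band_hi = (np.array([6, 12, 16]) * DAYS_PER_YEAR).astype(int)
    enroll_start = np.maximum(births, date_to_day(ana.study_start))
    enroll_end = date_to_day(ana.study_end)
    for year in range(ana.identification_start.year, ana.identification_end.year):
        y0, y1 = date_to_day(date(year, 1, 1)), date_to_day(date(year + 1, 1, 1))
        ndays = y1 - y0
        for g, name in enumerate(("0-5", "6-11", "12-15")):
            lo = np.maximum.reduce([births + band_lo[g], enroll_start,
                                    np.full_like(births, y0)])
            hi = np.minimum.reduce([births + band_hi[g],
                                    np.full_like(births, enroll_end),
                                    np.full_like(births, y1)])
            overlap = np.maximum(0, hi - lo)
            for sex in ("male", "female"):
                m = (true_sex == sex) & (overlap > 0)
                rows.append({
                    "year": year, "age_group": name, "sex": sex,
                    "person_count": int(m.sum()),
                    "person_years": float(overlap[m].sum() / ndays),
                })
    return pd.DataFrame(rows, columns=DENOMINATOR_COLUMNS)


def _assemble_truth(cfg: GeneratorConfig, rows: list[dict]) -> GroundTruth:
    persons = pd.DataFrame(rows)
    epoch = pd.Timestamp("1970-01-01")
    if len(persons):
        for day_col, date_col in (("onset_day", "onset_date"),
                                  ("birth_day", "birth_date"),
                                  ("index_start_day", "index_start"),
                                  ("index_episode_end_day", "index_episode_end"),
                                  ("restart_day", "restart_date")):
            days = persons[day_col]
            persons[date_col] = epoch + pd.to_timedelta(days.where(days >= 0), unit="D")
        persons = persons.drop(columns=["onset_day", "birth_day", "index_start_day",
                                        "index_episode_end_day", "restart_day"])
    annual_rows = []
    ana = cfg.analysis
    cases = persons[persons["is_case"]] if len(persons) else persons
    for year in range(ana.identification_start.year, ana.identification_end.year):
        y0, y1 = pd.Timestamp(date(year, 1, 1)), pd.Timestamp(date(year, 12, 31))
        if len(cases):
            inc = int(((cases["onset_date"].dt.year == year) & cases["incident"]).sum())
            sixteenth = cases["birth_date"] + pd.DateOffset(years=16)
            prev = int(((cases["onset_date"] <= y1) & (sixteenth > y0)).sum())
        else:
            inc = prev = 0
        annual_rows.append({"year": year, "true_incident": inc, "true_prevalent": prev})
    return GroundTruth(persons=persons, annual=pd.DataFrame(annual_rows))


def _apply_tamper(bundle: ClaimsBundle, cfg: GeneratorConfig) -> None:
    """Inject invariant violations for validator testing."""
    t = cfg.tamper or {}
    k = int(t.get("dialect", 0))
    if k and len(bundle.diagnoses):
        idx = bundle.diagnoses.index[:k]
        flip = {"ICD9CM": "ICD10CM", "ICD10CM": "ICD9CM"}
        bundle.diagnoses.loc[idx, "code_system"] = [
            flip[s] for s in bundle.diagnoses.loc[idx, "code_system"]
        ]
    k = int(t.get("enroll_overlap", 0))
    if k and len(bundle.beneficiaries):
        extra = bundle.beneficiaries.iloc[:k].copy()
        extra["enroll_start"] = extra["enroll_start"] + pd.Timedelta(days=1)
        bundle.beneficiaries = pd.concat([bundle.beneficiaries, extra],
                                         ignore_index=True)


def generate_course_timeline(
    pattern: str,
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    followup_days: int = 2920,
) -> list[tuple[int, int, str]]:
    """Adversarial fill timeline whose true terminal pattern is ``pattern``.

    Returns ``(day, days_supply, drug_name)`` fills for one person, with
    boundary-hugging gaps (including exactly the 60-day grace) so the pattern
    classifier is exercised at its decision edges.  Day 0 is the start of
    follow-up; ``followup_days`` is its length.
    """
    if pattern not in ("continuation", "switching", "restart", "discontinuation"):
        raise ValueError(f"unknown pattern {pattern!r}")
    cfg = cfg or GeneratorConfig()
    grace = cfg.analysis.grace_biologic_days
    rng = np.random.default_rng([seed, 4,
                                 ("continuation", "switching", "restart",
                                  "discontinuation").index(pattern)])
    drugs = list(INDEX_BIOLOGICS)
    index_drug = drugs[int(rng.integers(len(drugs)))]
    others = [d for d in drugs if d != index_drug] + ["abatacept"]
    supply = cfg.biologic_supply_days
    start = int(rng.integers(0, 100))
    fills: list[tuple[int, int, str]] = []

    def index_run(max_end: int, n_max: int | None = None) -> int:
        """Fills of the index drug with gaps in [-7, grace]; returns episode end."""
        day, end, k = start, start, 0
        while day + supply <= max_end and (n_max is None or k < n_max):
            fills.append((day, supply, index_drug))
            end = max(end, day + supply)
            day = end + int(rng.integers(-7, grace + 1))
            k += 1
        return end

    if pattern == "continuation":
        end = index_run(followup_days)
        while end + grace < followup_days:  # top up to the end of follow-up
            fills.append((end, supply, index_drug))
            end += supply
    elif pattern == "switching":
        end = index_run(followup_days - grace - 200, n_max=int(rng.integers(1, 12)))
        gap = int(rng.integers(0, grace + 1))   # includes the boundary gap == grace
        sw = end + gap
        drug = others[int(rng.integers(len(others)))]
        for k in range(int(rng.integers(1, 6))):
            d = sw + k * supply
            if d < followup_days:
                fills.append((d, supply, drug))
    elif pattern == "restart":
        end = index_run(followup_days - grace - 400, n_max=int(rng.integers(1, 10)))
        gap = grace + 1 + int(rng.integers(0, 200))
        rs = min(end + gap, followup_days - 1)
        drug = index_drug if rng.random() < 0.5 else others[int(rng.integers(len(others)))]
        for k in range(int(rng.integers(1, 6))):
            d = rs + k * supply
            if d < followup_days:
                fills.append((d, supply, drug))
    else:  # discontinuation
        index_run(followup_days - grace - 100, n_max=int(rng.integers(1, 10)))

    return sorted(fills)


TRUTH_COLUMNS = ["person_id", "is_case", "near_miss_type", "incident", "subgroup",
                 "sex", "uveitis", "psoriasis", "biologic_user", "index_drug",
                 "pattern", "onset_date", "birth_date", "index_start",
                 "index_episode_end", "restart_date"]


def export_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the per-person truth table as CSV (round-trips via read_truth)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = truth.persons.reindex(columns=TRUTH_COLUMNS).copy()
    for c in ("onset_date", "birth_date", "index_start", "index_episode_end",
              "restart_date"):
        df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str}, keep_default_na=False)
    if not len(df):
        return df.reindex(columns=TRUTH_COLUMNS)
    for c in ("is_case", "incident", "uveitis", "psoriasis", "biologic_user"):
        df[c] = df[c].astype(str).str.lower().isin(["true", "1"])
    for c in ("onset_date", "birth_date", "index_start", "index_episode_end",
              "restart_date"):
        df[c] = pd.to_datetime(df[c].replace("", pd.NaT), format="%Y-%m-%d")
    return df[TRUTH_COLUMNS]
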