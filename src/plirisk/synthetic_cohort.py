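"""Synthetic veteran cohort generator with known ground-truth LTI risk.

The generator emulates the statistical shape of a national VA-style screening
cohort so that every downstream stage (timeline construction, covariates,
stratified models, tiering, evaluation) is testable without restricted data:

* a rare two-year long-term-institutionalization (LTI) outcome (~1.1% of the
  eligible cohort), with roughly five non-LTI deaths per LTI event;
* a latent elevated-frailty subpopulation (~9% of the cohort once run through
  the IAH-Q/HNHR stratifier) with much higher condition prevalence, prior
  utilization and cost than the rest;
* a race-differential age at LTI entry (earlier entry in the comparison
  group), implemented by letting latent risk depend on age relative to the
  group's mean plus a configurable shift;
* stay records engineered to exercise the spell detector's edge cases
  (hospital interludes, short community leaves, post-acute SNF stays that
  must not qualify), and a small fraction of persons constructed to trip
  each cohort-entry exclusion.

Outcome generation is a two-step draw — an LTI Bernoulli from the latent
per-class logistic, then death — rather than a full competing-risks model;
death censors nothing for realized LTI cases (their spells are placed before
death).  This is a documented simplification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .covariates import CONDITIONS, DEFAULT_FRAILTY_MAP, FrailtyMap
from .residential import SpellRule

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "write_cohort", "read_cohort"]

TABLES = ("persons", "diagnoses", "stays_baseline", "stays_outcome", "truth")

# Condition prevalence (common-risk rate, elevated-risk rate) patterned on the
# observed ER/CR contrast of the study population the generator emulates.
DEFAULT_CONDITION_PREVALENCE: dict[str, tuple[float, float]] = {
    "amputation": (0.004, 0.036),
    "cancer": (0.081, 0.257),
    "dementia": (0.025, 0.152),
    "diabetes": (0.248, 0.500),
    "fracture": (0.003, 0.040),
    "head_injury": (0.038, 0.051),
    "heart_failure": (0.048, 0.342),
    "malnutrition": (0.003, 0.073),
    "multiple_sclerosis": (0.003, 0.008),
    "obesity": (0.159, 0.283),
    "parkinsons": (0.009, 0.039),
    "pressure_ulcer": (0.011, 0.116),
    "schizophrenia": (0.015, 0.034),
    "spinal_cord_injury": (0.005, 0.041),
    "seizure": (0.014, 0.068),
    "sepsis": (0.0042, 0.126),
    "stroke": (0.019, 0.147),
    "substance_use_disorder": (0.089, 0.187),
}

# Latent per-class LTI logistic coefficients.  "age_rel" is
# (age - group mean - group shift) / 10 years.  Intercepts are calibrated so
# the eligible-cohort margins land near a 1.1% two-year LTI rate with the
# elevated class far above the common class.
DEFAULT_TRUE_COEFFICIENTS: dict[str, dict[str, float]] = {
    "common": {
        "intercept": -5.80, "age_rel": 0.55, "jfi": 0.30, "prior_hospitalization": 0.50,
        "prior_snf": 0.80, "prior_lti": 1.30, "dementia": 1.10, "stroke": 0.50,
        "pressure_ulcer": 0.50, "married": -0.30, "homeless": 0.40,
    },
    "elevated": {
        "intercept": -5.42, "age_rel": 0.35, "jfi": 0.10, "prior_hospitalization": 0.30,
        "prior_snf": 0.50, "prior_lti": 1.00, "dementia": 0.80, "stroke": 0.35,
        "pressure_ulcer": 0.35, "married": -0.20, "homeless": 0.30,
    },
}

# Two-year mortality logistic (applied on top of the realized LTI draw); the
# "lti" coefficient raises mortality among institutionalized persons.
DEFAULT_MORTALITY_MODEL: dict[str, float] = {
    "intercept": -3.41, "age_rel": 0.60, "jfi": 0.13, "lti": 1.40,
}

DEFAULT_EXCLUSION_FRACTIONS: dict[str, float] = {
    "baseline_hospice": 0.004,
    "baseline_lti": 0.004,
    "baseline_death": 0.006,
    "institutionalized_last_day": 0.006,
    "no_face_to_face": 0.005,
}


def _validate_proportions(name: str, d: Mapping[str, float]) -> None:
    vals = np.array(list(d.values()), dtype=float)
    if (vals < 0).any() or not np.isclose(vals.sum(), 1.0, atol=1e-8):
        raise ValueError(f"configuration error: {name} must be nonnegative and sum to 1")


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort; deterministic given ``seed``."""

    n_persons: int = 10_000
    seed: int = 0
    race_mix: dict[str, float] = field(default_factory=lambda: {"white": 0.7, "black": 0.3})
    age_dist_by_race: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"white": (64.0, 14.0), "black": (56.0, 14.0)}
    )
    lti_age_shift_by_race: dict[str, float] = field(
        default_factory=lambda: {"white": 0.0, "black": -4.0}
    )
    condition_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCE)
    )
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_COEFFICIENTS.items()}
    )
    mortality_model: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MORTALITY_MODEL)
    )
    p_elevated: float = 0.12
    elevated_group_count: tuple[float, float] = (7.5, 1.5)  # mean, sd of frailty groups
    n_facilities: int = 20
    facility_effect_sd: float = 0.15
    lag_months: int = 9
    index_date: date = date(2017, 10, 1)
    outcome_days: int = 730
    horizon_days: int = 180  # NH accumulation allowed past the window end
    exclusion_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_FRACTIONS)
    )

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("configuration error: n_persons must be >= 1")
        if self.lag_months < 0:
            raise ValueError("configuration error: lag_months must be >= 0")
        if self.n_facilities < 1:
            raise ValueError("configuration error: n_facilities must be >= 1")
        if len(self.race_mix) < 2:
            raise ValueError("configuration error: race_mix needs >= 2 groups")
        _validate_proportions("race_mix", self.race_mix)
        for c, (p_cr, p_er) in self.condition_prevalence.items():
            if not (0 <= p_cr <= 1 and 0 <= p_er <= 1):
                raise ValueError(f"configuration error: prevalence for {c} outside [0, 1]")
        for r in self.race_mix:
            if r not in self.age_dist_by_race:
                raise ValueError(f"configuration error: no age distribution for race {r!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["index_date"] = self.index_date.isoformat()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "index_date" in d and isinstance(d["index_date"], str):
            d["index_date"] = date.fromisoformat(d["index_date"])
        for key in ("age_dist_by_race", "condition_prevalence"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        if "elevated_group_count" in d:
            d["elevated_group_count"] = tuple(d["elevated_group_count"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Container for the generated tables; all person-level joins by person_id."""

    config: SimConfig
    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    stays_baseline: pd.DataFrame
    stays_outcome: pd.DataFrame
    truth: pd.DataFrame

    @property
    def index_date(self) -> date:
        return self.config.index_date

    @property
    def deaths(self) -> pd.Series:
        """person_id -> death date (NaT when alive through follow-up)."""
        s = self.truth.set_index("person_id")["death_date"]
        return pd.to_datetime(s)

    @property
    def eligible_ids(self) -> pd.Index:
        t = self.truth
        return pd.Index(t.loc[t["exclusion"] == "none", "person_id"], name="person_id")


def _lin(coefs: Mapping[str, float], cols: Mapping[str, np.ndarray]) -> np.ndarray:
    eta = np.full_like(next(iter(cols.values())), coefs.get("intercept", 0.0), dtype=float)
    for name, beta in coefs.items():
        if name == "intercept":
            continue
        if name not in cols:
            raise ValueError(f"configuration error: unknown coefficient {name!r}")
        eta += beta * cols[name]
    return eta


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a cohort under ``config``.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    idx = config.index_date
    pid = np.array([f"P{i:07d}" for i in range(n)])

    races = np.array(sorted(config.race_mix))
    race = rng.choice(races, size=n, p=[config.race_mix[r] for r in races])
    age_mean = np.array([config.age_dist_by_race[r][0] for r in race])
    age_sd = np.array([config.age_dist_by_race[r][1] for r in race])
    age = np.clip(rng.normal(age_mean, age_sd), 22.0, 100.0).round(1)
    shift = np.array([config.lti_age_shift_by_race.get(r, 0.0) for r in race])
    age_rel = (age - age_mean - shift) / 10.0

    elevated = rng.random(n) < config.p_elevated
    male = rng.random(n) < 0.92
    married = rng.random(n) < 0.68
    rural = rng.random(n) < 0.32
    pg1 = rng.random(n) < 0.44
    homeless = rng.random(n) < np.where(elevated, 0.048, 0.025)
    esrd = rng.random(n) < 0.02
    palliative = rng.random(n) < np.where(elevated, 0.03, 0.003)
    hbpc = rng.random(n) < np.where(elevated, 0.03, 0.002)
    clc = rng.random(n) < np.where(elevated, 0.01, 0.0005)

    # --- conditions -------------------------------------------------------
    conds = list(CONDITIONS)
    n_c = len(conds)
    cr_rate = np.array([config.condition_prevalence[c][0] for c in conds])
    er_rate = np.array([config.condition_prevalence[c][1] for c in conds])
    present = rng.random((n, n_c)) < cr_rate  # common-risk draw for everyone

    # Elevated class: draw a target number of frailty groups (high, so the
    # IAH-Q/HNHR thresholds are reachable), pick groups weighted by the
    # elevated-risk prevalence pattern, then add the non-frailty conditions
    # at their elevated rates.
    fmap = DEFAULT_FRAILTY_MAP
    gnames = sorted(fmap.groups)
    n_g = len(gnames)
    g_weight = np.array(
        [max(config.condition_prevalence[c][1] for c in fmap.groups[g]) for g in gnames]
    )
    e_idx = np.flatnonzero(elevated)
    if len(e_idx):
        mu, sd = config.elevated_group_count
        k = np.clip(np.rint(rng.normal(mu, sd, size=len(e_idx))), 2, n_g).astype(int)
        gumbel = rng.gumbel(size=(len(e_idx), n_g)) + np.log(g_weight)
        order = np.argsort(-gumbel, axis=1)
        chosen = np.zeros((len(e_idx), n_g), dtype=bool)
        rowpos = np.arange(n_g)[None, :] < k[:, None]
        np.put_along_axis(chosen, order, rowpos, axis=1)
        e_present = np.zeros((len(e_idx), n_c), dtype=bool)
        for gi, g in enumerate(gnames):
            members = fmap.groups[g]
            primary = max(members, key=lambda c: config.condition_prevalence[c][1])
            for c in members:
                ci = conds.index(c)
                if c == primary:
                    e_present[:, ci] |= chosen[:, gi]
                else:
                    extra = rng.random(len(e_idx)) < config.condition_prevalence[c][1]
                    e_present[:, ci] |= chosen[:, gi] & extra
        nonfrailty = [c for c in conds if c not in fmap.condition_to_group()]
        for c in nonfrailty:
            ci = conds.index(c)
            e_present[:, ci] = rng.random(len(e_idx)) < config.condition_prevalence[c][1]
        present[e_idx] = e_present

    c2g = fmap.condition_to_group()
    g_of_c = np.array([gnames.index(c2g[c]) if c in c2g else -1 for c in conds])
    group_present = np.zeros((n, n_g), dtype=bool)
    for ci in range(n_c):
        if g_of_c[ci] >= 0:
            group_present[:, g_of_c[ci]] |= present[:, ci]
    jfi_true = group_present.sum(axis=1)

    # --- prior utilization, facility, cost --------------------------------
    prior_hosp = rng.random(n) < np.where(elevated, 0.95, 0.047)
    prior_snf = rng.random(n) < np.where(elevated, 0.45, 0.006)
    prior_lti = rng.random(n) < np.where(elevated, 0.009, 0.0002)
    fac_share = rng.dirichlet(np.full(config.n_facilities, 3.0))
    facility = rng.choice(config.n_facilities, size=n, p=fac_share)
    fac_effect = rng.normal(0.0, config.facility_effect_sd, size=config.n_facilities)
    cost_meanlog = np.where(elevated, np.log(38_000), np.log(7_600)) - 0.32
    prior_cost = np.exp(rng.normal(cost_meanlog, 0.8)).round(2)

    # --- exclusions -------------------------------------------------------
    excl_names = list(config.exclusion_fractions)
    excl_p = np.array([config.exclusion_fractions[k] for k in excl_names])
    if excl_p.sum() >= 1:
        raise ValueError("configuration error: exclusion fractions sum to >= 1")
    u = rng.random(n)
    exclusion = np.full(n, "none", dtype=object)
    lo = 0.0
    for name, p in zip(excl_names, excl_p):
        exclusion[(u >= lo) & (u < lo + p)] = name
        lo += p
    eligible = exclusion == "none"

    # --- latent LTI and death draws ---------------------------------------
    cols = {
        "age_rel": age_rel, "jfi": jfi_true.astype(float),
        "prior_hospitalization": prior_hosp.astype(float),
        "prior_snf": prior_snf.astype(float), "prior_lti": prior_lti.astype(float),
        "married": married.astype(float), "homeless": homeless.astype(float),
    }
    for ci, c in enumerate(conds):
        cols[c] = present[:, ci].astype(float)
    eta = np.where(
        elevated,
        _lin(config.true_coefficients["elevated"], cols),
        _lin(config.true_coefficients["common"], cols),
    )
    p_lti = _sigmoid(eta + fac_effect[facility])
    lti = (rng.random(n) < p_lti) & eligible

    mort_cols = dict(cols)
    mort_cols["lti"] = lti.astype(float)
    p_death = _sigmoid(_lin(config.mortality_model, mort_cols))
    dies = rng.random(n) < p_death

    # --- stay records ------------------------------------------------------
    d0 = idx  # outcome window start
    window_end = idx + timedelta(days=config.outcome_days - 1)
    horizon = window_end + timedelta(days=config.horizon_days)
    base_rows: list[tuple] = []
    out_rows: list[tuple] = []
    _ALIVE = -10**6
    death_day = np.full(n, _ALIVE, dtype=int)  # day offset from index (may be pre-index)

    # baseline encounters (>=1 face-to-face for everyone except the
    # no-face-to-face exclusion arm); vectorized
    has_f2f = exclusion != "no_face_to_face"
    n_enc = np.where(has_f2f, 1 + rng.poisson(3, size=n), 0)
    enc_pid = np.repeat(pid, n_enc)
    enc_day = rng.integers(-365, 0, size=n_enc.sum())
    enc_first = np.concatenate([[True], np.diff(np.repeat(np.arange(n), n_enc)) != 0]) \
        if n_enc.sum() else np.array([], dtype=bool)
    enc_f2f = np.where(enc_first, True, rng.random(n_enc.sum()) < 0.9)
    for p_, d_, f_ in zip(enc_pid, enc_day, enc_f2f):
        day = idx + timedelta(days=int(d_))
        base_rows.append((p_, "encounter", day, day, "VA", bool(f_)))

    # baseline hospitalizations
    hosp_idx = np.flatnonzero(prior_hosp)
    n_h = 1 + rng.poisson(0.8, size=len(hosp_idx))
    for i, cnt in zip(hosp_idx, n_h):
        for _ in range(cnt):
            start = int(rng.integers(-360, -10))
            length = int(rng.integers(2, 11))
            payer = "VA" if rng.random() < 0.7 else "Medicare"
            base_rows.append((pid[i], "hospital", idx + timedelta(days=start),
                              idx + timedelta(days=start + length - 1), payer, False))

    # baseline short post-acute SNF stays (never qualifying)
    for i in np.flatnonzero(prior_snf):
        start = int(rng.integers(-350, -40))
        length = int(rng.integers(10, 46))
        payer = "Medicare" if rng.random() < 0.8 else "VA"
        base_rows.append((pid[i], "NH", idx + timedelta(days=start),
                          idx + timedelta(days=start + length - 1), payer, False))

    # prior-LTI spells: qualifying NH runs confined to months 13-24 pre-index
    for i in np.flatnonzero(prior_lti):
        end = int(rng.integers(-690, -380))
        length = int(rng.integers(95, 181))
        payer = "Medicare" if rng.random() < 0.6 else "VA"
        base_rows.append((pid[i], "NH", idx + timedelta(days=end - length + 1),
                          idx + timedelta(days=end), payer, False))

    # exclusion-arm baseline records
    for i in np.flatnonzero(exclusion == "baseline_hospice"):
        start = int(rng.integers(-200, -20))
        base_rows.append((pid[i], "hospice", idx + timedelta(days=start),
                          idx + timedelta(days=start + int(rng.integers(5, 60))), "VA", False))
    for i in np.flatnonzero(exclusion == "baseline_lti"):
        start = int(rng.integers(-360, -160))
        base_rows.append((pid[i], "NH", idx + timedelta(days=start),
                          idx + timedelta(days=start + int(rng.integers(95, 150))), "VA", False))
    for i in np.flatnonzero(exclusion == "baseline_death"):
        death_day[i] = int(rng.integers(-360, -1))
    for i in np.flatnonzero(exclusion == "institutionalized_last_day"):
        setting = "hospital" if rng.random() < 0.5 else "NH"
        start = int(rng.integers(-20, -2))
        base_rows.append((pid[i], setting, idx + timedelta(days=start),
                          idx + timedelta(days=-1), "VA", False))

    # --- outcome-period trajectories --------------------------------------
    horizon_off = (horizon - idx).days
    qualify_off = np.full(n, -1, dtype=int)
    for i in np.flatnonzero(lti):
        entry = int(rng.integers(0, config.outcome_days - 30))
        avail = horizon_off - entry
        total_nh = int(min(91 + rng.integers(0, 120), max(91, avail - 45)))
        # split into runs with interruptions that must not break the spell
        runs = [total_nh]
        if rng.random() < 0.6:
            n_runs = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(1, total_nh), size=n_runs - 1, replace=False))
            runs = np.diff(np.concatenate([[0], cuts, [total_nh]])).tolist()
        day = entry
        for j, r in enumerate(runs):
            out_rows.append((pid[i], "NH", idx + timedelta(days=day),
                             idx + timedelta(days=day + r - 1),
                             "VA" if rng.random() < 0.5 else "Medicare", False))
            day += r
            if j < len(runs) - 1:
                if rng.random() < 0.5:  # acute interlude (any length)
                    gap = int(rng.integers(1, 16))
                    out_rows.append((pid[i], "hospital", idx + timedelta(days=day),
                                     idx + timedelta(days=day + gap - 1), "VA", False))
                else:  # short home leave, never more than the allowed gap
                    gap = int(rng.integers(1, 8))
                day += gap
        qualify_off[i] = day - 1
        if dies[i]:
            death_day[i] = day + int(rng.integers(1, 150))

    # non-LTI deaths: uniform over the outcome window
    for i in np.flatnonzero(dies & ~lti & eligible):
        death_day[i] = int(rng.integers(0, config.outcome_days))

    # non-LTI short post-acute stays and hospitalizations in the outcome window
    p_out_snf = np.where(elevated, 0.25, 0.03)
    out_snf = (rng.random(n) < p_out_snf) & ~lti & eligible
    for i in np.flatnonzero(out_snf):
        start = int(rng.integers(0, config.outcome_days - 120))
        length = int(rng.integers(5, 46))
        out_rows.append((pid[i], "NH", idx + timedelta(days=start),
                         idx + timedelta(days=start + length - 1),
                         "Medicare" if rng.random() < 0.7 else "VA", False))
        if rng.random() < 0.3:  # a second stay, far enough away to stay separate
            s2 = start + length + 30 + int(rng.integers(0, 60))
            l2 = int(rng.integers(5, 40))
            out_rows.append((pid[i], "NH", idx + timedelta(days=s2),
                             idx + timedelta(days=s2 + l2 - 1), "Medicare", False))

    p_out_hosp = np.where(elevated, 0.45, 0.08)
    out_hosp = (rng.random(n) < p_out_hosp) & eligible & ~lti
    for i in np.flatnonzero(out_hosp):
        start = int(rng.integers(0, config.outcome_days - 12))
        out_rows.append((pid[i], "hospital", idx + timedelta(days=start),
                         idx + timedelta(days=start + int(rng.integers(2, 11))),
                         "VA" if rng.random() < 0.7 else "Medicare", False))

    # clip or drop outcome events at death
    death_date = {
        pid[i]: idx + timedelta(days=int(death_day[i]))
        for i in np.flatnonzero(death_day != _ALIVE)
    }
    clipped = []
    for row in out_rows:
        p_, setting, s_, e_, payer, f2f = row
        dd = death_date.get(p_)
        if dd is not None:
            if s_ > dd:
                continue
            if e_ > dd:
                e_ = dd
        clipped.append((p_, setting, s_, e_, payer, f2f))
    out_rows = clipped

    # --- diagnosis events --------------------------------------------------
    pe_idx, ce_idx = np.nonzero(present)
    onset = rng.integers(-24, 0, size=len(pe_idx))
    dx_rows = {"person_id": [], "condition": [], "month": [], "source": []}
    for k in range(len(pe_idx)):
        i, ci, o = pe_idx[k], ce_idx[k], int(onset[k])
        months = [o]
        for m in range(o + 1, 0):
            if rng.random() < 0.35:
                months.append(m)
        recent = int(rng.integers(max(o, -6), 0))  # guaranteed recent contact
        if recent not in months:
            months.append(recent)
        for m in months:
            dx_rows["person_id"].append(pid[i])
            dx_rows["condition"].append(conds[ci])
            dx_rows["month"].append(m)
            dx_rows["source"].append("VA" if rng.random() < 0.75 else "medicare")
    diagnoses = pd.DataFrame(dx_rows)
    if len(diagnoses):
        diagnoses = diagnoses.sort_values(["person_id", "condition", "month"], kind="stable")
    diagnoses = diagnoses.reset_index(drop=True)

    stay_cols = ["person_id", "setting", "start", "end", "payer", "face_to_face"]
    stays_baseline = pd.DataFrame(base_rows, columns=stay_cols)
    stays_outcome = pd.DataFrame(out_rows, columns=stay_cols)
    for df in (stays_baseline, stays_outcome):
        df.sort_values(["person_id", "start", "setting"], kind="stable", inplace=True)
        df.reset_index(drop=True, inplace=True)

    persons = pd.DataFrame({
        "person_id": pid,
        "facility_id": np.char.add("F", np.char.zfill(facility.astype(str), 3)),
        "race": race, "age": age,
        "male": male.astype(int), "married": married.astype(int),
        "rural": rural.astype(int), "priority_group_1": pg1.astype(int),
        "homeless": homeless.astype(int), "esrd": esrd.astype(int),
        "palliative": palliative.astype(int), "hbpc": hbpc.astype(int),
        "clc": clc.astype(int), "prior_cost": prior_cost,
    })
    truth = pd.DataFrame({
        "person_id": pid,
        "elevated": elevated.astype(int),
        "p_lti": np.where(eligible, p_lti, 0.0).round(8),
        "lti": lti.astype(int),
        "death_date": [death_date.get(p_, pd.NaT) for p_ in pid],
        "exclusion": exclusion,
    })
    return SyntheticCohort(
        config=config, persons=persons, diagnoses=diagnoses,
        stays_baseline=stays_baseline, stays_outcome=stays_outcome, truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the five cohort tables plus config as CSV/YAML; return a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name in TABLES:
        df: pd.DataFrame = getattr(cohort, name)
        path = directory / f"{name}.csv"
        try:
            df.to_csv(path, index=False)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing table {name!r} to {path}: {exc}") from exc
        manifest[name] = {"path": str(path), "rows": int(len(df))}
    cohort.config.to_yaml(directory / "config.yaml")
    return manifest


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    directory = Path(directory)
    config = SimConfig.from_yaml(directory / "config.yaml")
    tables = {}
    for name in TABLES:
        path = directory / f"{name}.csv"
        try:
            df = pd.read_csv(path)
        except OSError as exc:
            raise OSError(f"failed reading table {name!r} from {path}: {exc}") from exc
        tables[name] = df
    for name in ("stays_baseline", "stays_outcome"):
        df = tables[name]
        if len(df):
            df["start"] = pd.to_datetime(df["start"]).dt.date
            df["end"] = pd.to_datetime(df["end"]).dt.date
            df["face_to_face"] = df["face_to_face"].astype(bool)
    t = tables["truth"]
    if len(t):
        t["death_date"] = pd.to_datetime(t["death_date"]).dt.date
    return SyntheticCohort(config=config, **tables)
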