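"""Model covariates derived from claims-style tables.

Everything the stratified risk models consume is built here: a transparent
diagnosis-group frailty count standing in for the JEN Frailty Index (JFI), an
auxiliary one-year death-or-hospitalization score standing in for the CAN
score (with configurable missingness), the monthly Independence-at-Home
qualification (IAH-Q) and High-Need/High-Risk (HNHR) indicators that define
the elevated-risk (ER) vs common-risk (CR) strata, race-centered age, and
prior-utilization flags — in a *complete-data* mode and a *production* mode
that suppresses the most recent months of non-VA records (claims lag) and
compensates with an extended look-back.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .residential import SpellRule, detect_spells_table

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "CHRONIC_CONDITIONS",
    "FrailtyMap",
    "DEFAULT_FRAILTY_MAP",
    "compute_jfi_proxy",
    "CanProxyModel",
    "race_centered_age",
    "monthly_iahq",
    "monthly_hnhr",
    "assign_stratum",
    "build_feature_rows",
]

#: The 18 prior-year diagnosis flags used as model covariates.
CONDITIONS = (
    "amputation", "cancer", "dementia", "diabetes", "fracture", "head_injury",
    "heart_failure", "malnutrition", "multiple_sclerosis", "obesity",
    "parkinsons", "pressure_ulcer", "schizophrenia", "spinal_cord_injury",
    "seizure", "sepsis", "stroke", "substance_use_disorder",
)

#: Chronic-condition subset used for the IAH-Q two-chronic-conditions
#: criterion: all conditions except the acute events (sepsis, fracture).
CHRONIC_CONDITIONS = tuple(c for c in CONDITIONS if c not in ("sepsis", "fracture"))


@dataclass(frozen=True)
class FrailtyMap:
    """Disjoint condition groups; each group with >=1 qualifying diagnosis adds 1."""

    groups: Mapping[str, tuple[str, ...]]

    @property
    def max_score(self) -> int:
        return len(self.groups)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g, conds in self.groups.items():
            overlap = seen & set(conds)
            if overlap:
                raise ValueError(f"frailty group {g!r} reuses conditions {sorted(overlap)}")
            seen |= set(conds)

    def condition_to_group(self) -> dict[str, str]:
        return {c: g for g, conds in self.groups.items() for c in conds}


#: Default 13-group frailty map over the 18 conditions.  This is a proxy: the
#: published claims frailty index it emulates is calibrated on functional
#: data we do not model; here frailty is a plain count of affected groups.
DEFAULT_FRAILTY_MAP = FrailtyMap(
    groups={
        "dementia": ("dementia",),
        "stroke": ("stroke",),
        "parkinsonism": ("parkinsons",),
        "malnutrition": ("malnutrition",),
        "pressure_ulcer": ("pressure_ulcer",),
        "fracture": ("fracture",),
        "amputation": ("amputation",),
        "neuromuscular": ("multiple_sclerosis", "spinal_cord_injury"),
        "heart_failure": ("heart_failure",),
        "diabetes": ("diabetes",),
        "seizure": ("seizure",),
        "psychiatric": ("schizophrenia", "substance_use_disorder"),
        "sepsis": ("sepsis",),
    }
)


def compute_jfi_proxy(
    diagnoses: Iterable[str], frailty_map: FrailtyMap = DEFAULT_FRAILTY_MAP
) -> int:
    """Frailty score for one person: number of groups with >=1 qualifying diagnosis.

    ``diagnoses`` is the collection of condition names recorded within the
    look-back window.  Unknown condition names are ignored with a warning.
    """
    c2g = frailty_map.condition_to_group()
    hit: set[str] = set()
    for c in diagnoses:
        g = c2g.get(c)
        if g is None:
            if c not in CONDITIONS:
                logger.warning("ignoring unknown condition code %r", c)
            continue
        hit.add(g)
    return len(hit)


def _events_in_window(diagnoses: pd.DataFrame, lo: int, hi: int, sources=None) -> pd.DataFrame:
    """Diagnosis event rows with month in [lo, hi], optionally restricted by source."""
    m = diagnoses["month"].to_numpy()
    mask = (m >= lo) & (m <= hi)
    if sources is not None:
        mask &= diagnoses["source"].isin(sources).to_numpy()
    return diagnoses.loc[mask]


def jfi_scores(
    diagnoses: pd.DataFrame,
    person_ids: Sequence[str],
    month_lo: int = -12,
    month_hi: int = -1,
    frailty_map: FrailtyMap = DEFAULT_FRAILTY_MAP,
    sources: Sequence[str] | None = None,
) -> pd.Series:
    """Vectorized frailty scores for a cohort from a diagnosis-event table.

    ``diagnoses`` has columns person_id, condition, month (integer offset,
    -1 = last month before the index date), source.
    """
    ev = _events_in_window(diagnoses, month_lo, month_hi, sources)
    c2g = frailty_map.condition_to_group()
    ev = ev[ev["condition"].isin(c2g)]
    grp = ev["condition"].map(c2g)
    pairs = pd.DataFrame({"person_id": ev["person_id"], "group": grp}).drop_duplicates()
    counts = pairs.groupby("person_id").size()
    return counts.reindex(person_ids, fill_value=0).astype(int).rename("jfi")


class CanProxyModel:
    """Auxiliary one-year death-or-hospitalization risk score (CAN stand-in).

    A logistic model fit on a held-out synthetic slice; `predict` returns a
    probability in [0, 1].  The production CAN score this emulates is a
    proprietary weekly VA model; only its role (an auxiliary risk input with
    missingness) is reproduced.
    """

    FEATURES = ("age", "jfi", "prior_hospitalization", "dementia", "heart_failure", "cancer")

    def __init__(self) -> None:
        self.params_: pd.Series | None = None

    def fit(self, features: pd.DataFrame, target: pd.Series) -> "CanProxyModel":
        import statsmodels.api as sm

        X = sm.add_constant(features[list(self.FEATURES)].astype(float), has_constant="add")
        y = np.asarray(target, dtype=float)
        if y.min() == y.max():  # degenerate slice: fall back to intercept-only
            p = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
            self.params_ = pd.Series({"const": np.log(p / (1 - p))})
            return self
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        self.params_ = res.params
        return self

    @classmethod
    def intercept_only(cls, prevalence: float) -> "CanProxyModel":
        m = cls()
        p = float(np.clip(prevalence, 1e-9, 1 - 1e-9))
        m.params_ = pd.Series({"const": np.log(p / (1 - p))})
        return m

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("CanProxyModel not fitted")
        eta = np.full(len(features), self.params_.get("const", 0.0), dtype=float)
        for name, beta in self.params_.items():
            if name != "const":
                eta += beta * features[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def compute_can_proxy(
    features: pd.DataFrame,
    aux_model: CanProxyModel,
    missing_fraction: float = 0.045,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """CAN-proxy score with missingness.

    A configurable fraction of persons is flagged missing; missing scores are
    imputed with the cohort median of the non-missing scores (indicator kept).
    """
    rng = rng or np.random.default_rng(0)
    p = aux_model.predict(features)
    missing = rng.random(len(p)) < missing_fraction
    fill = float(np.median(p[~missing])) if (~missing).any() else 0.0
    p = np.where(missing, fill, p)
    return pd.DataFrame(
        {"can": p, "can_missing": missing.astype(int)}, index=features.index
    )


def race_centered_age(
    age: pd.Series | Sequence[float],
    race_group: pd.Series | Sequence[str],
    group_means: Mapping[str, float] | None = None,
) -> pd.Series:
    """Residual of age from the mean age of the person's racial-ethnic group.

    With ``group_means=None`` the means are computed over the given cohort
    (the analysis-cohort convention); a precomputed mapping may be supplied
    to score new persons, in which case an unknown group raises a KeyError
    naming the group.
    """
    age = pd.Series(np.asarray(age, dtype=float))
    race = pd.Series(np.asarray(race_group, dtype=object), index=age.index)
    if group_means is None:
        means = race.map(age.groupby(race).mean())
    else:
        unknown = set(race.unique()) - set(group_means)
        if unknown:
            raise KeyError(f"unknown race group(s): {sorted(unknown)}")
        means = race.map(group_means)
    return (age - means).rename("race_centered_age")


def monthly_iahq(
    hosp_in_window: bool,
    snf_in_window: bool,
    n_chronic_conditions: int,
    jfi: int,
    jfi_threshold: int = 6,
) -> bool:
    """IAH-Q for one person-month: hospitalization AND post-acute SNF AND
    >=2 chronic conditions AND frailty score >= 6, all within the 12-month
    look-back ending at that month."""
    return bool(hosp_in_window and snf_in_window and n_chronic_conditions >= 2
                and jfi >= jfi_threshold)


def monthly_hnhr(
    hosp_in_window: bool,
    jfi_va: int,
    hospice_or_palliative: bool,
    hbpc_or_clc: bool,
    esrd: bool,
    jfi_threshold: int = 5,
) -> bool:
    """HNHR for one person-month: hospitalization AND VA-data frailty score
    >= 5, excluding hospice/palliative care (or referral), home-based primary
    care / community-living-center enrollment, and end-stage renal disease."""
    return bool(hosp_in_window and jfi_va >= jfi_threshold
                and not hospice_or_palliative and not hbpc_or_clc and not esrd)


def assign_stratum(iahq_months: Sequence[bool], hnhr_months: Sequence[bool]) -> str:
    """ER if either indicator is true in any baseline month, else CR."""
    return "ER" if (any(iahq_months) or any(hnhr_months)) else "CR"


# ---------------------------------------------------------------------------
# Cohort-level feature construction


def _month_start(index_date: date, m: int) -> date:
    """First day of month offset ``m`` (m = -1 is the last baseline month)."""
    ts = pd.Timestamp(index_date) + pd.DateOffset(months=m)
    return ts.date()


def _stay_overlap_flags(
    stays: pd.DataFrame, ids: pd.Index, lo: date, hi: date, mask: np.ndarray | None = None
) -> pd.Series:
    """Per-person indicator of any stay overlapping [lo, hi] (inclusive).

    ``_start``/``_end`` must be datetime64 columns (vectorized comparisons).
    """
    sel = ((stays["_end"] >= pd.Timestamp(lo)) & (stays["_start"] <= pd.Timestamp(hi))).to_numpy()
    if mask is not None:
        sel &= mask
    hit = stays.loc[sel, "person_id"].unique()
    return pd.Series(ids.isin(hit), index=ids)


def _monthly_group_presence(
    diagnoses: pd.DataFrame,
    ids: pd.Index,
    frailty_map: FrailtyMap,
    months: Sequence[int],
    lookback: int = 12,
    sources: Sequence[str] | None = None,
) -> np.ndarray:
    """(n_persons, len(months)) frailty scores, one per look-back month."""
    c2g = frailty_map.condition_to_group()
    ev = diagnoses[diagnoses["condition"].isin(c2g)]
    if sources is not None:
        ev = ev[ev["source"].isin(sources)]
    id_pos = pd.Series(np.arange(len(ids)), index=ids)
    ev = ev[ev["person_id"].isin(id_pos.index)]
    rows = id_pos.loc[ev["person_id"]].to_numpy()
    gnames = sorted(frailty_map.groups)
    g_pos = {g: i for i, g in enumerate(gnames)}
    gcol = ev["condition"].map(c2g).map(g_pos).to_numpy()
    month = ev["month"].to_numpy()

    lo, hi = int(min(months)) - lookback + 1, int(max(months))
    n_m = hi - lo + 1
    present = np.zeros((len(ids), len(gnames), n_m), dtype=np.int8)
    ok = (month >= lo) & (month <= hi)
    present[rows[ok], gcol[ok], month[ok] - lo] = 1
    csum = np.cumsum(present, axis=2)

    out = np.zeros((len(ids), len(months)), dtype=np.int16)
    for j, m in enumerate(months):
        hi_i = m - lo
        lo_i = m - lookback - lo  # exclusive
        win = csum[:, :, hi_i] - (csum[:, :, lo_i] if lo_i >= 0 else 0)
        out[:, j] = (win > 0).sum(axis=1)
    return out


def stratum_assignments(
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    stays_baseline: pd.DataFrame,
    index_date: date,
    months: Sequence[int] = tuple(range(-12, 0)),
    frailty_map: FrailtyMap = DEFAULT_FRAILTY_MAP,
    chronic_conditions: Sequence[str] = CHRONIC_CONDITIONS,
    visible_sources: Sequence[str] | None = None,
    iahq_jfi_threshold: int = 6,
    hnhr_jfi_threshold: int = 5,
) -> pd.Series:
    """ER/CR stratum per person from monthly IAH-Q and HNHR over ``months``.

    Both criteria require a hospitalization in the 12 months before the month
    under consideration, so only hospitalized persons are evaluated in depth.
    """
    ids = pd.Index(persons["person_id"])
    st = stays_baseline.copy()
    st["_start"] = pd.to_datetime(st["start"])
    st["_end"] = pd.to_datetime(st["end"])
    if visible_sources is not None:
        pass  # visibility filtering is applied by the caller for stays

    is_hosp = (st["setting"] == "hospital").to_numpy()
    is_snf = (st["setting"] == "NH").to_numpy()
    not_medicare = (st["payer"] != "Medicare").to_numpy()
    is_hospice = (st["setting"] == "hospice").to_numpy()

    any_hosp_ever = st.loc[is_hosp, "person_id"].unique()
    cand = ids[ids.isin(any_hosp_ever)]
    if len(cand) == 0:
        return pd.Series("CR", index=ids, name="stratum")

    pm = persons.set_index("person_id").loc[cand]
    esrd = pm["esrd"].astype(bool).to_numpy() if "esrd" in pm else np.zeros(len(cand), bool)
    palliative = pm["palliative"].astype(bool).to_numpy() if "palliative" in pm else np.zeros(len(cand), bool)
    hbpc_clc = np.zeros(len(cand), bool)
    for c in ("hbpc", "clc"):
        if c in pm:
            hbpc_clc |= pm[c].astype(bool).to_numpy()

    jfi_all = _monthly_group_presence(diagnoses, cand, frailty_map, months)
    jfi_va = _monthly_group_presence(diagnoses, cand, frailty_map, months, sources=["VA"])

    # chronic-condition counts per month window
    chron = diagnoses[diagnoses["condition"].isin(chronic_conditions)]
    chron = chron[chron["person_id"].isin(cand)]
    id_pos = pd.Series(np.arange(len(cand)), index=cand)

    er = np.zeros(len(cand), dtype=bool)
    for j, m in enumerate(months):
        lo = _month_start(index_date, m - 11)
        hi = _month_start(index_date, m + 1) - timedelta(days=1)
        hosp_any = _stay_overlap_flags(st, cand, lo, hi, mask=is_hosp).to_numpy()
        hosp_nonmedicare = _stay_overlap_flags(st, cand, lo, hi, mask=is_hosp & not_medicare).to_numpy()
        snf = _stay_overlap_flags(st, cand, lo, hi, mask=is_snf).to_numpy()
        hospice_stay = _stay_overlap_flags(st, cand, lo, hi, mask=is_hospice).to_numpy()

        cw = chron[(chron["month"] >= m - 11) & (chron["month"] <= m)]
        nchron = (
            cw.drop_duplicates(["person_id", "condition"]).groupby("person_id").size()
            .reindex(cand, fill_value=0).to_numpy()
        )
        iahq = hosp_any & snf & (nchron >= 2) & (jfi_all[:, j] >= iahq_jfi_threshold)
        hnhr = (
            hosp_nonmedicare
            & (jfi_va[:, j] >= hnhr_jfi_threshold)
            & ~(hospice_stay | palliative)
            & ~hbpc_clc
            & ~esrd
        )
        er |= iahq | hnhr

    out = pd.Series("CR", index=ids, name="stratum")
    out.loc[cand[er]] = "ER"
    return out


def build_feature_rows(
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    stays_baseline: pd.DataFrame,
    index_date: date,
    mode: str = "complete",
    lag_months: int = 9,
    frailty_map: FrailtyMap = DEFAULT_FRAILTY_MAP,
    can_model: CanProxyModel | None = None,
    can_missing_fraction: float = 0.045,
    spell_rule: SpellRule = SpellRule(),
    cost_scale: float = 10_000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One covariate row per person (exclusions assumed already applied).

    complete mode
        12-month look-back for diagnoses, frailty and utilization flags
        (prior LTI, which requires complete non-VA data, is ascertained in
        months 13-24 before the index date in both modes).
    production mode
        The most recent ``lag_months`` of non-VA records are invisible;
        non-VA look-back windows shift back by the lag (extending the total
        look-back to up to 24 months), the frailty score is the maximum of
        the monthly scores over the baseline year, and stratum qualification
        may occur in any of the 24 pre-index months.
    """
    if mode not in ("complete", "production"):
        raise ValueError(f"mode must be 'complete' or 'production', got {mode!r}")
    lag = 0 if mode == "complete" else int(lag_months)
    rng = np.random.default_rng(seed)
    ids = pd.Index(persons["person_id"], name="person_id")
    pm = persons.set_index("person_id").loc[ids]

    st = stays_baseline.copy()
    st["_start"] = pd.to_datetime(st["start"])
    st["_end"] = pd.to_datetime(st["end"])
    lag_cut = pd.Timestamp(_month_start(index_date, -lag))
    va_stay = (st["payer"] == "VA").to_numpy()
    if lag:
        # Suppress non-VA stay records from the lag period (claims not yet
        # received); non-VA diagnosis events likewise.
        vis_st = st[va_stay | (st["_end"] < lag_cut).to_numpy()].copy()
        dx_va = (diagnoses["source"] == "VA").to_numpy()
        vis_dx = diagnoses[dx_va | (diagnoses["month"].to_numpy() < -lag)]
    else:
        vis_st, vis_dx = st, diagnoses

    months12 = tuple(range(-12, 0))

    def window_flag(setting_mask_col: str, payer_split: bool) -> pd.Series:
        """Any-stay flag over the 12-month look-back; with a lag, the non-VA
        part of the window shifts back by the lag."""
        m = (vis_st["setting"] == setting_mask_col).to_numpy()
        lo = _month_start(index_date, -12)
        hi = index_date - timedelta(days=1)
        va = (vis_st["payer"] == "VA").to_numpy()
        base = _stay_overlap_flags(vis_st, ids, lo, hi, mask=m & va)
        if lag == 0:
            other = _stay_overlap_flags(vis_st, ids, lo, hi, mask=m & ~va)
        else:
            lo2 = _month_start(index_date, -12 - lag)
            hi2 = _month_start(index_date, -lag) - timedelta(days=1)
            other = _stay_overlap_flags(vis_st, ids, lo2, hi2, mask=m & ~va)
        return base | other

    prior_hosp = window_flag("hospital", True)
    prior_snf = window_flag("NH", True)

    # Prior LTI: qualifying spell in months 13-24 before the index date
    # (the window for which non-VA nursing-home data are complete).
    lti_lo = _month_start(index_date, -24)
    lti_hi = _month_start(index_date, -12) - timedelta(days=1)
    nh_st = vis_st[vis_st["setting"] == "NH"]
    spells = detect_spells_table(nh_st, spell_rule, range_start=lti_lo, range_end=lti_hi)
    prior_lti_ids = (
        set(spells.loc[spells["qualifying"] & (spells["spell_start"] >= lti_lo)
                       & (spells["spell_start"] <= lti_hi), "person_id"])
        if len(spells) else set()
    )
    prior_lti = pd.Series(ids.isin(prior_lti_ids), index=ids)

    # Frailty score
    if mode == "complete":
        jfi = jfi_scores(vis_dx, ids, -12, -1, frailty_map)
    else:
        monthly = _monthly_group_presence(vis_dx, ids, frailty_map, months12)
        jfi = pd.Series(monthly.max(axis=1).astype(int), index=ids, name="jfi")

    # Condition flags: any event in the (visible) look-back
    dx_lo = -12 - lag  # non-VA part of the window reaches further back
    cond_ev = vis_dx[(vis_dx["month"] >= -12) | ((vis_dx["month"] >= dx_lo)
                     & (vis_dx["source"] != "VA"))]
    cond_flags = pd.crosstab(cond_ev["person_id"], cond_ev["condition"])
    cond_flags = (cond_flags > 0).astype(int).reindex(index=ids, fill_value=0)
    for c in CONDITIONS:
        if c not in cond_flags:
            cond_flags[c] = 0
    cond_flags = cond_flags[list(CONDITIONS)]

    stratum_months = months12 if mode == "complete" else tuple(range(-24, 0))
    stratum = stratum_assignments(
        persons, vis_dx, vis_st, index_date, months=stratum_months, frailty_map=frailty_map
    )

    feats = pd.DataFrame(index=ids)
    feats["age"] = pm["age"].astype(float)
    feats["race"] = pm["race"]
    feats["race_centered_age"] = race_centered_age(feats["age"], feats["race"]).to_numpy()
    for c in ("male", "married", "rural", "priority_group_1", "homeless"):
        feats[c] = pm[c].astype(int)
    feats["jfi"] = jfi
    feats["prior_hospitalization"] = prior_hosp.astype(int)
    feats["prior_snf"] = prior_snf.astype(int)
    feats["prior_lti"] = prior_lti.astype(int)
    feats["prior_cost"] = pm["prior_cost"].astype(float) / cost_scale
    for c in CONDITIONS:
        feats[c] = cond_flags[c].to_numpy()
    feats["facility_id"] = pm["facility_id"]
    feats["stratum"] = stratum

    if can_model is None:
        can_model = CanProxyModel.intercept_only(0.1)
    can_feats = feats.rename(columns={})[["age", "jfi", "prior_hospitalization",
                                          "dementia", "heart_failure", "cancer"]]
    can = compute_can_proxy(can_feats, can_model, can_missing_fraction, rng)
    feats["can"] = can["can"]
    feats["can_missing"] = can["can_missing"]
    return feats
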