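"""End-to-end screening pipeline: cohort tables -> risk tiers -> report.

Glue for the common path: apply cohort exclusions, detect the two-year LTI
outcome, build covariates, fit the stratified model, tune the dual
thresholds, assign tiers and evaluate.  Each step is the public function or
estimator from its own module; this wrapper only sequences them and is fully
deterministic given its seed.
"""

from __future__ import annotations

from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import CanProxyModel, build_feature_rows
from .evaluation import (
    c_statistic,
    calibration_by_decile,
    confusion_metrics,
    facility_nns_distribution,
    fnr_equity_audit,
    tier_outcome_table,
)
from .model import StratifiedRiskModel
from .residential import SpellRule, apply_cohort_exclusions, lti_outcome_flags
from .synthetic_cohort import SyntheticCohort
from .tiering import TierAssigner

__all__ = ["run_pipeline"]


def _outcome_tables(cohort: SyntheticCohort, ids: pd.Index) -> dict[str, pd.Series]:
    """Death/hospitalization/cost summaries over the outcome window."""
    idx = cohort.index_date
    window_end = idx + timedelta(days=cohort.config.outcome_days - 1)
    deaths = cohort.deaths
    died = deaths.notna() & (deaths.dt.date <= window_end)
    died = died.reindex(ids, fill_value=False)

    st = cohort.stays_outcome
    hosp_ids = st.loc[st["setting"] == "hospital", "person_id"].unique()
    hosp = pd.Series(ids.isin(hosp_ids), index=ids)

    one_year = idx + timedelta(days=365)
    starts = pd.to_datetime(st["start"]).dt.date
    h1 = st.loc[(st["setting"] == "hospital") & (starts < one_year), "person_id"].unique()
    d1 = deaths.notna() & (deaths.dt.date < one_year)
    death_or_hosp_1y = (pd.Series(ids.isin(h1), index=ids)
                        | d1.reindex(ids, fill_value=False))
    return {"died_2y": died, "hospitalized_2y": hosp, "death_or_hosp_1y": death_or_hosp_1y}


def run_pipeline(
    cohort: SyntheticCohort,
    mode: str = "complete",
    link: str = "logit",
    nns_high: float = 8.0,
    nns_moderate: float = 25.0,
    with_facility_effects: bool = False,
    retention_alpha: float | None = None,
    use_race_centered_age: bool = True,
    spell_rule: SpellRule = SpellRule(),
    can_holdout_fraction: float = 0.25,
    seed: int = 0,
) -> dict:
    """Run the full screening pipeline on a synthetic cohort.

    Returns a dict with eligible ids, exclusion tally, features, outcome,
    fitted model, scores, tier assigner, tiers and the evaluation report.
    """
    idx = cohort.index_date
    eligible, tally = apply_cohort_exclusions(
        cohort.persons, cohort.stays_baseline, cohort.deaths, idx, spell_rule
    )

    window_end = idx + timedelta(days=cohort.config.outcome_days - 1)
    lti = lti_outcome_flags(
        cohort.stays_outcome, eligible, idx, window_end,
        horizon=window_end + timedelta(days=cohort.config.horizon_days),
        rule=spell_rule, deaths=cohort.deaths,
    )

    persons = cohort.persons[cohort.persons["person_id"].isin(eligible)]
    out_tabs = _outcome_tables(cohort, eligible)

    # CAN proxy: fit the auxiliary model on a held-out slice of the cohort
    rng = np.random.default_rng(seed)
    feats_nocan = build_feature_rows(
        persons, cohort.diagnoses, cohort.stays_baseline, idx, mode=mode,
        lag_months=cohort.config.lag_months, can_model=CanProxyModel.intercept_only(0.1),
        can_missing_fraction=0.0, spell_rule=spell_rule, seed=seed,
    )
    hold = rng.random(len(eligible)) < can_holdout_fraction
    can_model = CanProxyModel().fit(
        feats_nocan.loc[hold], out_tabs["death_or_hosp_1y"].loc[hold].astype(int)
    )
    from .covariates import compute_can_proxy

    can = compute_can_proxy(
        feats_nocan[list(CanProxyModel.FEATURES)], can_model,
        missing_fraction=0.045, rng=np.random.default_rng(seed + 1),
    )
    features = feats_nocan.copy()
    features["can"] = can["can"]
    features["can_missing"] = can["can_missing"]
    if not use_race_centered_age:
        features = features.drop(columns=["race_centered_age"])
        features.insert(0, "centered_age", features["age"] - features["age"].mean())

    y = lti.loc[features.index].astype(int).to_numpy()
    model = StratifiedRiskModel(
        link=link, with_facility_effects=with_facility_effects,
        retention_alpha=retention_alpha,
    ).fit(features, y)
    p = model.predict_risk(features)

    scores = pd.DataFrame({
        "p_lti": p.to_numpy(), "stratum": features["stratum"].to_numpy(),
    }, index=features.index)
    assigner = TierAssigner(nns_high=nns_high, nns_moderate=nns_moderate).fit(scores, y)
    tiers = scores.copy()
    tiers["tier"] = assigner.predict(scores)

    high = (tiers["tier"] == "high").to_numpy()
    report = {
        "exclusions": tally,
        "n_eligible": int(len(eligible)),
        "lti_rate": float(y.mean()),
        "er_share": float((features["stratum"] == "ER").mean()),
        "confusion": confusion_metrics(high, y),
        "c_statistic": {
            s: c_statistic(p[features["stratum"] == s], y[(features["stratum"] == s).to_numpy()])
            for s in sorted(features["stratum"].unique())
        },
        "pseudo_r2": {s: m.pseudo_r2 for s, m in model.models_.items()},
        "thresholds": {"high": assigner.high_.as_dict(),
                       "moderate": assigner.moderate_.as_dict()},
        "tier_table": tier_outcome_table(
            tiers, y, out_tabs["died_2y"].to_numpy(),
            persons.set_index("person_id").loc[features.index, "prior_cost"].to_numpy(),
            service_flags=pd.DataFrame({
                "hospitalized": out_tabs["hospitalized_2y"].to_numpy()
            }, index=features.index),
        ),
        "calibration": {
            s: calibration_by_decile(
                p[(features["stratum"] == s).to_numpy()],
                y[(features["stratum"] == s).to_numpy()],
                person_ids=features.index[(features["stratum"] == s).to_numpy()],
            )
            for s in sorted(features["stratum"].unique())
        },
        "fnr_audit": fnr_equity_audit(
            tiers, y, features["race"].to_numpy()
        ),
        "facility_nns": facility_nns_distribution(
            tiers, y, features["facility_id"].to_numpy()
        ),
    }
    return {
        "eligible": eligible, "exclusion_tally": tally, "features": features,
        "outcome": pd.Series(y, index=features.index, name="lti"),
        "model": model, "scores": scores, "assigner": assigner,
        "tiers": tiers, "report": report,
    }
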