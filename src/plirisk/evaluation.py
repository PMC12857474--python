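"""Accuracy, calibration, fairness and descriptive outputs.

Implements the full reporting surface of the screening pipeline: confusion
metrics and number needed to screen (NNS), the c-statistic (concordance
probability, rank-sum form), decile calibration tables, the false-negative-
rate (FNR) equity audit across race groups and strata, stratified k-fold
cross-validation of the whole fit-tune-evaluate pipeline, per-facility NNS,
and tier-level outcome tables.

Undefined quantities (e.g. sensitivity with zero positives) are reported as
NaN together with an explanatory message, never silently dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .model import StratifiedRiskModel
from .tiering import ThresholdPair, TierAssigner, optimize_thresholds, assign_tiers

logger = logging.getLogger(__name__)

__all__ = [
    "confusion_metrics",
    "c_statistic",
    "calibration_by_decile",
    "fnr_equity_audit",
    "kfold_cv",
    "tier_outcome_table",
    "facility_nns_distribution",
    "plot_calibration",
    "plot_facility_nns",
]


def confusion_metrics(flags, outcomes) -> dict:
    """Sensitivity, specificity, PPV and NNS of a high-tier indicator.

    ``nns = flagged / true positives`` (the reciprocal of PPV).  With zero
    outcome positives, sensitivity is undefined and reported as NaN with a
    message; likewise PPV/NNS with nobody flagged.
    """
    f = np.asarray(flags, dtype=bool)
    y = np.asarray(outcomes, dtype=bool)
    if len(f) != len(y):
        raise ValueError("flags and outcomes must be aligned, same length")
    tp = int((f & y).sum())
    fp = int((f & ~y).sum())
    fn = int((~f & y).sum())
    tn = int((~f & ~y).sum())
    out: dict = {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "n_flagged": tp + fp}
    messages = []
    if tp + fn > 0:
        out["sensitivity"] = tp / (tp + fn)
    else:
        out["sensitivity"] = float("nan")
        messages.append("sensitivity undefined: no outcome positives")
    if tn + fp > 0:
        out["specificity"] = tn / (tn + fp)
    else:
        out["specificity"] = float("nan")
        messages.append("specificity undefined: no outcome negatives")
    if tp + fp > 0:
        out["ppv"] = tp / (tp + fp)
        out["nns"] = (tp + fp) / tp if tp > 0 else float("inf")
    else:
        out["ppv"] = float("nan")
        out["nns"] = float("nan")
        messages.append("ppv/nns undefined: nobody flagged")
    if messages:
        out["messages"] = messages
    for k in ("sensitivity", "specificity", "ppv", "nns"):
        logger.debug("confusion_metrics %s = %s", k, out[k])
    return out


def c_statistic(scores, outcomes) -> float:
    """Concordance: P(random positive outscores random negative), ties half.

    Computed in the Mann-Whitney rank-sum form; equal to the area under the
    ROC curve and invariant to strictly monotone transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic undefined: need >=1 positive and >=1 negative")
    ranks = stats.rankdata(s)  # midranks handle ties at half credit
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def calibration_by_decile(scores, outcomes, person_ids=None, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count risk-decile calibration table.

    Persons are ranked by score (stable sort; ties keep person_id order) and
    split into ``n_bins`` equal-count bins; each bin reports the mean
    predicted risk and the observed outcome rate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(s) < n_bins:
        raise ValueError(f"need at least {n_bins} observations")
    if person_ids is None:
        person_ids = np.arange(len(s))
    order = np.lexsort((np.asarray(person_ids), s))  # stable within ties
    rows = []
    for d, chunk in enumerate(np.array_split(order, n_bins), start=1):
        rows.append({
            "decile": d,
            "mean_predicted": float(s[chunk].mean()),
            "observed_rate": float(y[chunk].mean()),
            "n": len(chunk),
        })
    return pd.DataFrame(rows)


def fnr_equity_audit(
    tiers: pd.DataFrame,
    outcomes,
    race_group,
    stratum=None,
) -> pd.DataFrame:
    """False-negative rate of the high tier per race group per stratum.

    FNR = LTI cases not flagged high / all LTI cases in the cell.  Groups
    with no LTI cases report NaN.  The result includes, per stratum, the
    absolute between-group gap (max - min over groups with defined FNR).
    """
    df = pd.DataFrame({
        "high": (tiers["tier"] == "high").to_numpy(),
        "lti": np.asarray(outcomes, dtype=bool),
        "race": np.asarray(race_group, dtype=object),
        "stratum": np.asarray(stratum if stratum is not None else tiers["stratum"],
                              dtype=object),
    })
    rows = []
    for (st, race), grp in df.groupby(["stratum", "race"]):
        cases = grp["lti"].sum()
        if cases == 0:
            fnr = float("nan")
            logger.warning("FNR undefined for stratum=%s race=%s: no LTI cases", st, race)
        else:
            fnr = float((grp["lti"] & ~grp["high"]).sum() / cases)
        rows.append({"stratum": st, "race": race, "n_cases": int(cases), "fnr": fnr})
    out = pd.DataFrame(rows)
    gaps = (
        out.dropna(subset=["fnr"]).groupby("stratum")["fnr"]
        .agg(lambda v: float(v.max() - v.min()))
        .rename("fnr_gap")
    )
    return out.merge(gaps, on="stratum", how="left")


def tier_outcome_table(
    tiers: pd.DataFrame,
    outcomes,
    deaths,
    costs,
    service_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-tier counts/rates of LTI and death, mean cost, and service use."""
    df = pd.DataFrame({
        "tier": tiers["tier"].to_numpy(),
        "lti": np.asarray(outcomes, dtype=bool),
        "death": np.asarray(deaths, dtype=bool),
        "cost": np.asarray(costs, dtype=float),
    })
    if service_flags is not None:
        for c in service_flags.columns:
            df[c] = service_flags[c].to_numpy(dtype=bool)
    rows = []
    for tier in ("high", "moderate", "low"):
        grp = df[df["tier"] == tier]
        n = len(grp)
        row = {
            "tier": tier, "n": n,
            "lti_n": int(grp["lti"].sum()),
            "lti_pct": 100 * grp["lti"].mean() if n else 0.0,
            "death_n": int(grp["death"].sum()),
            "death_pct": 100 * grp["death"].mean() if n else 0.0,
            "mean_cost": float(grp["cost"].mean()) if n else 0.0,
        }
        if service_flags is not None:
            for c in service_flags.columns:
                row[f"{c}_n"] = int(grp[c].sum())
                row[f"{c}_pct"] = 100 * grp[c].mean() if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def facility_nns_distribution(
    tiers: pd.DataFrame,
    outcomes,
    facility_id,
) -> pd.Series:
    """NNS among flagged persons, per facility (NaN when no flagged LTI case)."""
    df = pd.DataFrame({
        "high": (tiers["tier"] == "high").to_numpy(),
        "lti": np.asarray(outcomes, dtype=bool),
        "facility": np.asarray(facility_id, dtype=object),
    })
    out = {}
    for fac, grp in df.groupby("facility"):
        flagged = int(grp["high"].sum())
        tp = int((grp["high"] & grp["lti"]).sum())
        out[fac] = flagged / tp if tp > 0 else float("nan")
        if tp == 0:
            logger.warning("facility %s: NNS undefined (no flagged LTI case)", fac)
    return pd.Series(out, name="nns").sort_index()


def kfold_cv(
    features: pd.DataFrame,
    outcomes,
    k: int = 10,
    seed: int = 0,
    link: str = "logit",
    nns_max: float = 8.0,
    with_facility_effects: bool = False,
    model_features: Sequence[str] | None = None,
) -> dict:
    """Cross-validate the whole fit -> tune-thresholds -> evaluate pipeline.

    Folds are stratified on (stratum, outcome) so every training fold keeps
    positives in both strata; thresholds are re-optimized inside each
    training fold (no leakage into the held-out fold).  Folds whose test
    split has no positive are skipped with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(outcomes, dtype=int)
    combo = features["stratum"].astype(str) + "_" + pd.Series(y, index=features.index).astype(str)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(features, combo)):
        if y[te].sum() == 0:
            warnings.warn(f"fold {fold}: no positives in test split; skipped")
            continue
        Xtr, Xte = features.iloc[tr], features.iloc[te]
        mdl = StratifiedRiskModel(link=link, with_facility_effects=with_facility_effects,
                                  features=model_features).fit(Xtr, y[tr])
        tr_scores = pd.DataFrame({
            "p_lti": mdl.predict_risk(Xtr).to_numpy(),
            "stratum": Xtr["stratum"].to_numpy(), "lti": y[tr],
        })
        pair = optimize_thresholds(tr_scores, nns_max)
        p_te = mdl.predict_risk(Xte).to_numpy()
        er = (Xte["stratum"] == "ER").to_numpy()
        flags = np.where(er, p_te >= pair.tau_er, p_te >= pair.tau_cr)
        m = confusion_metrics(flags, y[te])
        m["fold"] = fold
        m["c_statistic"] = c_statistic(p_te, y[te])
        per_fold.append(m)
    folds = pd.DataFrame(per_fold)
    rng = {
        "nns": (float(folds["nns"].min()), float(folds["nns"].max())),
        "sensitivity": (float(folds["sensitivity"].min()), float(folds["sensitivity"].max())),
        "c_statistic": (float(folds["c_statistic"].min()), float(folds["c_statistic"].max())),
    }
    return {"folds": folds, "ranges": rng}


def plot_calibration(table: pd.DataFrame, path, title: str = "Calibration by risk decile"):
    """Observed vs predicted rate per decile (one point per decile)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(table["mean_predicted"], table["observed_rate"], "o-", label="deciles")
    lim = max(table["mean_predicted"].max(), table["observed_rate"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="ideal")
    ax.set_xlabel("mean predicted risk")
    ax.set_ylabel("observed rate")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_facility_nns(nns: pd.Series, path, bins: int = 15):
    """Histogram of per-facility NNS."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(nns.dropna().to_numpy(), bins=bins)
    ax.set_xlabel("number needed to screen")
    ax.set_ylabel("facilities")
    ax.set_title("Per-facility NNS")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
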