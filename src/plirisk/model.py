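"""Stratum-specific binary-outcome regression for LTI risk.

One model is fit per risk stratum (elevated risk, ER; common risk, CR) by
maximum likelihood with a logit (default) or probit link, optionally with
facility (station) fixed effects.  The estimator follows scikit-learn
conventions (``fit`` / ``predict_proba`` / ``get_params``) so it composes
with sklearn model selection; the likelihood maximization itself is
delegated to statsmodels (Newton, score-norm tolerance 1e-8).

Also here: average marginal effects (AME) on the outcome probability — the
counterfactual difference for binary covariates, the mean derivative for
continuous ones, with delta-method confidence intervals — and the
variable-retention rule (keep a covariate if Wald p < alpha in at least one
stratum model, then refit both strata on the retained set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

import statsmodels.api as sm

STRATA = ("ER", "CR")

__all__ = [
    "StratumModel",
    "StratifiedRiskModel",
    "PerfectSeparationError",
    "average_marginal_effect",
    "variable_retention",
]


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded because a covariate separates the outcome."""


@dataclass
class StratumModel:
    """Fitted coefficients and fit statistics for one stratum."""

    stratum: str
    link: str
    coefficients: pd.Series          # named slopes (no intercept)
    intercept: float
    facility_effects: pd.Series      # reference-coded station effects (may be empty)
    n_obs: int
    converged: bool
    loglik: float
    loglik_null: float
    bse: pd.Series                   # standard errors, same naming as params
    cov_params: pd.DataFrame
    dropped: tuple[str, ...] = ()

    @property
    def pseudo_r2(self) -> float:
        """McFadden pseudo-r2, 1 - loglik/loglik_null."""
        if self.loglik_null == 0:
            return 0.0
        return 1.0 - self.loglik / self.loglik_null

    @property
    def params(self) -> pd.Series:
        out = pd.Series({"const": self.intercept})
        return pd.concat([out, self.coefficients, self.facility_effects])

    def wald_pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "link": self.link,
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "facility_effects": {k: float(v) for k, v in self.facility_effects.items()},
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "loglik": float(self.loglik),
            "loglik_null": float(self.loglik_null),
            "pseudo_r2": float(self.pseudo_r2),
        }


def _link_funcs(link: str):
    if link == "logit":
        return stats.logistic.cdf, stats.logistic.pdf
    if link == "probit":
        return stats.norm.cdf, stats.norm.pdf
    raise ValueError(f"link must be 'logit' or 'probit', got {link!r}")


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> str | None:
    """Name a perfectly separating covariate, if any (binary covariates only)."""
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        uniq = np.unique(v)
        v1, v0 = v[y == 1], v[y == 0]
        if not len(v1) or not len(v0):
            continue
        if len(uniq) == 2:
            y0, y1 = y[v == uniq[0]], y[v == uniq[1]]
            if len(y0) and len(y1) and (
                (y0.max() < y1.min()) or (y1.max() < y0.min())
            ):
                return col
        elif v1.min() > v0.max() or v0.min() > v1.max():
            return col
    return None


def _fit_one_stratum(
    X: pd.DataFrame,
    y: np.ndarray,
    link: str,
    stratum: str,
    facility: pd.Series | None,
    facility_levels: list[str] | None,
    maxiter: int = 100,
) -> StratumModel:
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            f"stratum {stratum}: need at least one positive and one negative outcome"
        )

    dropped = []
    keep = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        uniq = np.unique(v)
        if len(uniq) <= 1:
            dropped.append(col)
            warnings.warn(f"stratum {stratum}: dropping constant covariate {col!r}")
            continue
        if len(uniq) == 2:
            # Quasi-separated dummies (an outcome-pure level) push the MLE to
            # infinity; two-sided purity is full separation and is an error.
            pure = [y[v == u].min() == y[v == u].max() for u in uniq]
            if all(pure):
                raise PerfectSeparationError(
                    f"stratum {stratum}: covariate {col!r} perfectly separates the outcome"
                )
            if any(pure) and min((v == u).sum() for u in uniq) < len(v):
                side = uniq[pure.index(True)]
                if (v == side).sum() < len(v) / 2:
                    dropped.append(col)
                    warnings.warn(
                        f"stratum {stratum}: dropping quasi-separated covariate {col!r} "
                        f"(outcome constant where {col} == {side:g})"
                    )
                    continue
        keep.append(col)
    X = X[keep].astype(float)

    fac_cols: list[str] = []
    if facility is not None:
        # Reference-coded station dummies; the largest station is reference.
        dummies = pd.get_dummies(facility, prefix="facility", dtype=float)
        ref = "facility_" + str(facility.value_counts().idxmax())
        fac_cols = [c for c in dummies.columns if c != ref]
        X = pd.concat([X, dummies[fac_cols]], axis=1)

    design = sm.add_constant(X, has_constant="add")
    cls = sm.Logit if link == "logit" else sm.Probit
    model = cls(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-8, disp=0)
        except Exception as exc:
            sep = _check_separation(X, y)
            if sep is not None:
                raise PerfectSeparationError(
                    f"stratum {stratum}: covariate {sep!r} perfectly separates the outcome"
                ) from exc
            raise RuntimeError(
                f"stratum {stratum}: fit failed after {maxiter} Newton iterations: {exc}"
            ) from exc
    score_norm = float(np.abs(model.score(res.params)).max())
    converged = bool(res.mle_retvals.get("converged", False)) or score_norm < 1e-6
    if not converged:
        sep = _check_separation(X, y)
        if sep is not None:
            raise PerfectSeparationError(
                f"stratum {stratum}: covariate {sep!r} perfectly separates the outcome"
            )
        raise RuntimeError(
            f"stratum {stratum}: no convergence in {maxiter} iterations "
            f"(|score| = {np.abs(model.score(res.params)).max():.3g})"
        )

    params = pd.Series(res.params, index=design.columns)
    bse = pd.Series(res.bse, index=design.columns)
    slope_names = [c for c in keep]
    return StratumModel(
        stratum=stratum,
        link=link,
        coefficients=params[slope_names],
        intercept=float(params["const"]),
        facility_effects=params[fac_cols],
        n_obs=len(y),
        converged=True,
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        bse=bse,
        cov_params=pd.DataFrame(res.cov_params(), index=design.columns,
                                columns=design.columns),
        dropped=tuple(dropped),
    )


#: Default model covariates (the CovariateRow fields that enter the linear
#: predictor; stratum and facility are handled structurally).
DEFAULT_FEATURES = None  # resolved at fit time: everything numeric except identifiers

_NON_FEATURES = {"person_id", "age", "race", "facility_id", "stratum"}


class StratifiedRiskModel(BaseEstimator):
    """Per-stratum binary-outcome GLM with a shared interface.

    Parameters
    ----------
    link : 'logit' or 'probit'
    with_facility_effects : include reference-coded station fixed effects.
    features : explicit covariate list; default: every numeric column except
        identifiers, raw age, race, facility and stratum.
    retention_alpha : if set, fit twice: a full model per stratum, then a
        refit on the union of covariates with Wald p < alpha in at least one
        stratum (facility effects, if requested, are always retained).

    Fitted attributes: ``models_`` (stratum -> StratumModel),
    ``feature_names_``, ``retained_``.
    """

    def __init__(self, link: str = "logit", with_facility_effects: bool = False,
                 features: Sequence[str] | None = None,
                 retention_alpha: float | None = None):
        self.link = link
        self.with_facility_effects = with_facility_effects
        self.features = features
        self.retention_alpha = retention_alpha

    def _resolve_features(self, X: pd.DataFrame) -> list[str]:
        if self.features is not None:
            missing = [f for f in self.features if f not in X.columns]
            if missing:
                raise ValueError(f"missing covariate(s): {missing}")
            return list(self.features)
        return [c for c in X.columns
                if c not in _NON_FEATURES and pd.api.types.is_numeric_dtype(X[c])]

    def fit(self, X: pd.DataFrame, y) -> "StratifiedRiskModel":
        _link_funcs(self.link)  # validate early
        if "stratum" not in X.columns:
            raise ValueError("X must carry a 'stratum' column with values ER/CR")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        feats = self._resolve_features(X)

        # Deterministic given input ordering: sort by person_id when present.
        order = np.argsort(X.index.to_numpy(), kind="stable") \
            if X.index.name == "person_id" else np.arange(len(X))
        Xs, ys = X.iloc[order], y[order]

        models: dict[str, StratumModel] = {}
        for stratum in sorted(Xs["stratum"].unique()):
            mask = (Xs["stratum"] == stratum).to_numpy()
            fac = Xs.loc[mask, "facility_id"] if (
                self.with_facility_effects and "facility_id" in Xs
            ) else None
            models[stratum] = _fit_one_stratum(
                Xs.loc[mask, feats], ys[mask], self.link, stratum, fac, None
            )

        if self.retention_alpha is not None:
            retained = variable_retention(models.values(), self.retention_alpha)
            refit_feats = [f for f in feats if f in retained]
            if not refit_feats:
                warnings.warn("no covariate significant; refitting intercept-only models")
            refit: dict[str, StratumModel] = {}
            for stratum, m in models.items():
                mask = (Xs["stratum"] == stratum).to_numpy()
                fac = Xs.loc[mask, "facility_id"] if (
                    self.with_facility_effects and "facility_id" in Xs
                ) else None
                refit[stratum] = _fit_one_stratum(
                    Xs.loc[mask, refit_feats], ys[mask], self.link, stratum, fac, None
                )
            self.full_models_ = models
            models = refit
            self.retained_ = sorted(refit_feats)
        else:
            self.retained_ = sorted(feats)

        self.models_ = models
        self.feature_names_ = feats
        return self

    def _eta(self, m: StratumModel, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in m.coefficients.index if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariate(s): {missing}")
        eta = np.full(len(X), m.intercept)
        for name, beta in m.coefficients.items():
            eta += beta * X[name].to_numpy(dtype=float)
        if len(m.facility_effects) and "facility_id" in X.columns:
            eff = ("facility_" + X["facility_id"].astype(str)).map(
                m.facility_effects
            ).fillna(0.0)  # unseen stations get effect 0
            eta += eff.to_numpy()
        return eta

    def predict_risk(self, X: pd.DataFrame) -> pd.Series:
        """Predicted LTI probability per row, using each row's stratum model."""
        cdf, _ = _link_funcs(self.link)
        if not hasattr(self, "models_"):
            raise RuntimeError("model not fitted")
        p = np.empty(len(X))
        for stratum, m in self.models_.items():
            mask = (X["stratum"] == stratum).to_numpy()
            if mask.any():
                p[mask] = cdf(self._eta(m, X.loc[mask]))
        unknown = ~X["stratum"].isin(self.models_).to_numpy()
        if unknown.any():
            raise ValueError(
                f"rows with unknown stratum: {sorted(X.loc[unknown, 'stratum'].unique())}"
            )
        return pd.Series(p, index=X.index, name="p_lti")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_risk(X).to_numpy()
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_risk(X).to_numpy() >= 0.5).astype(int)


def average_marginal_effect(
    model: StratumModel,
    X: pd.DataFrame,
    covariate: str,
    ci_level: float = 0.95,
    kind: str = "auto",
) -> dict:
    """AME of one covariate on the outcome probability, with a delta-method CI.

    Binary covariates: mean over rows of p(x; covariate=1) - p(x; covariate=0).
    Continuous covariates: mean of dp/dx = f(eta) * beta.  ``kind`` may force
    'binary' or 'continuous' when the observed values are ambiguous (default:
    binary iff the column only takes values 0 and 1).
    """
    if covariate not in model.coefficients.index:
        raise ValueError(f"covariate {covariate!r} not in model")
    cdf, pdf = _link_funcs(model.link)
    names = list(model.params.index)  # const + slopes + facility effects

    def design(df: pd.DataFrame) -> np.ndarray:
        M = np.ones((len(df), len(names)))
        for j, nm in enumerate(names):
            if nm == "const":
                continue
            if nm.startswith("facility_") and nm not in df.columns:
                lvl = nm[len("facility_"):]
                M[:, j] = (df["facility_id"].astype(str) == lvl).astype(float) \
                    if "facility_id" in df.columns else 0.0
            else:
                M[:, j] = df[nm].to_numpy(dtype=float)
        return M

    beta = model.params.to_numpy()
    vals = X[covariate].to_numpy(dtype=float)
    if kind not in ("auto", "binary", "continuous"):
        raise ValueError("kind must be 'auto', 'binary' or 'continuous'")
    if kind == "auto":
        is_binary = set(np.unique(vals)) <= {0.0, 1.0}
    else:
        is_binary = kind == "binary"

    if is_binary:
        X1, X0 = X.copy(), X.copy()
        X1[covariate] = 1.0
        X0[covariate] = 0.0
        M1, M0 = design(X1), design(X0)
        ame = float(np.mean(cdf(M1 @ beta) - cdf(M0 @ beta)))
        grad = (pdf(M1 @ beta)[:, None] * M1 - pdf(M0 @ beta)[:, None] * M0).mean(axis=0)
    else:
        M = design(X)
        eta = M @ beta
        j = names.index(covariate)
        ame = float(np.mean(pdf(eta)) * beta[j])
        if model.link == "logit":
            fprime = pdf(eta) * (1 - 2 * cdf(eta))
        else:
            fprime = -eta * pdf(eta)
        grad = (fprime[:, None] * M).mean(axis=0) * beta[j]
        grad[j] += float(np.mean(pdf(eta)))

    V = model.cov_params.loc[names, names].to_numpy()
    se = float(np.sqrt(grad @ V @ grad))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return {"ame": ame, "se": se, "ci": (ame - z * se, ame + z * se)}


def variable_retention(
    models: Sequence[StratumModel] | Mapping[str, StratumModel],
    alpha: float = 0.05,
) -> set[str]:
    """Covariates with Wald p < alpha in at least one stratum model.

    Facility effects and the intercept are structural and not subject to the
    filter.  An empty result means an intercept-only refit.
    """
    if isinstance(models, Mapping):
        models = list(models.values())
    retained: set[str] = set()
    for m in models:
        p = m.wald_pvalues()
        for name in m.coefficients.index:
            if p[name] < alpha:
                retained.add(name)
    if not retained:
        warnings.warn(f"no covariate significant at alpha={alpha}")
    return retained
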