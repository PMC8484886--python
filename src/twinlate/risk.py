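"""Continuous dementia-risk proxy from logistic-regression Pearson residuals.

The binary dementia diagnosis cannot enter a multigroup Gaussian twin model
directly, so diagnosis is regressed (logistic) on demographic and clinical
covariates and each person's Pearson residual

    resid_i = (y_i - p_i) / sqrt(p_i (1 - p_i))

serves as a continuous risk score: the part of the diagnosis not explained
by measured covariates, on a standardised scale.  The distribution is
bimodal (cases vs non-cases), not Gaussian, but the score is nearly
perfectly correlated with diagnosis when the covariates are informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import TwinCohort
from .errors import EstimationError

DEFAULT_COVARIATES = (
    "cohort",  # birth-year decade bands
    "sex",
    "study",
    "age_first",  # age at first loneliness assessment
    "education",
    "isei",
    "illness",
    "apoe_e4",  # allele count; missing handled via indicator + zero fill
)

#: ridge penalty (on the standardised design) applied under quasi-separation
RIDGE_ALPHA = 1e-4


@dataclass
class LogisticFit:
    """ML (or ridge-penalised) logistic regression of dementia on covariates."""

    params: pd.Series
    fitted: pd.Series  # person_id -> predicted probability
    outcomes: pd.Series  # person_id -> observed 0/1
    loglik: float
    converged: bool
    penalized: bool
    covariates: tuple


def _design(cohort: TwinCohort, covariates) -> tuple[pd.DataFrame, pd.Series]:
    base = cohort.baseline_table().set_index("person_id")
    cols = {}
    cov = tuple(covariates)
    if "cohort" in cov:
        decade = (base["birth_year"].astype(float) // 10 * 10).astype(int)
        for d in sorted(decade.unique())[1:]:  # earliest decade = reference
            cols[f"cohort_{d}s"] = (decade == d).astype(float)
    if "sex" in cov:
        cols["sex_f"] = (base["sex"] == "F").astype(float)
    if "study" in cov:
        for s in sorted(base["study"].unique())[1:]:
            cols[f"study_{s}"] = (base["study"] == s).astype(float)
    if "age_first" in cov:
        cols["age_first"] = base["baseline_age"].astype(float)
    if "education" in cov:
        cols["education"] = base["education"].astype(float)
    if "isei" in cov:
        cols["isei"] = base["isei"].astype(float)
    if "illness" in cov:
        cols["illness"] = base["illness"].astype(float)
    if "apoe_e4" in cov:
        apoe = base["apoe_e4"]
        cols["apoe_e4"] = apoe.fillna(0).astype(float)
        if apoe.isna().any():
            cols["apoe_missing"] = apoe.isna().astype(float)
    X = pd.DataFrame(cols, index=base.index)
    X = X.loc[:, X.nunique() > 1]  # drop no-contrast columns
    X.insert(0, "const", 1.0)
    y = base["dementia"].astype(int)
    return X, y


def fit_dementia_logistic(
    cohort: TwinCohort,
    covariates=DEFAULT_COVARIATES,
    penalize_on_separation: bool = True,
) -> LogisticFit:
    """Fit the dementia logistic model used to build the risk proxy.

    On quasi-separation (non-convergence or exploding coefficients) the fit
    falls back, when allowed, to a small ridge penalty on the standardised
    design and flags itself ``penalized``.
    """
    X, y = _design(cohort, covariates)
    if y.nunique() < 2:
        raise EstimationError("dementia outcome is constant; logistic model undefined")

    separated = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0, maxiter=200)
        params = pd.Series(res.params, index=X.columns)
        converged = bool(res.mle_retvals.get("converged", False))
        if (
            not converged
            or not np.all(np.isfinite(params))
            or np.abs(params).max() > 30
        ):
            separated = True
    except Exception:
        separated, converged = True, False
        params = pd.Series(np.zeros(X.shape[1]), index=X.columns)

    if separated and penalize_on_separation:
        # ridge on the standardised design keeps coefficients finite
        from sklearn.linear_model import LogisticRegression

        Z = X.drop(columns="const")
        mu, sd = Z.mean(), Z.std(ddof=0).replace(0, 1.0)
        Zs = (Z - mu) / sd
        clf = LogisticRegression(  # default penalty is the L2 ridge
            C=1.0 / RIDGE_ALPHA, solver="lbfgs", max_iter=2000
        )
        clf.fit(Zs.to_numpy(), y.to_numpy())
        beta_std = pd.Series(clf.coef_[0], index=Zs.columns)
        beta = beta_std / sd
        intercept = float(clf.intercept_[0] - (beta * mu).sum())
        params = pd.concat([pd.Series({"const": intercept}), beta])
        converged, penalized = True, True
    elif separated:
        converged, penalized = False, False
    else:
        penalized = False

    eta = X.to_numpy() @ params.reindex(X.columns).to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    loglik = float(
        np.sum(y * np.log(np.clip(p, 1e-300, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-300, 1)))
    )
    return LogisticFit(
        params=params,
        fitted=pd.Series(p, index=X.index),
        outcomes=y,
        loglik=loglik,
        converged=converged,
        penalized=penalized,
        covariates=tuple(covariates),
    )


def pearson_residuals(fit: LogisticFit, outcomes: pd.Series | None = None) -> pd.DataFrame:
    """Pearson residuals of a logistic fit: the dementia-risk scores.

    Returns a (person_id, resid) table.  Fitted probabilities at 0 or 1
    (machine precision) raise, since the residual is undefined there.
    """
    if not (fit.converged or fit.penalized):
        raise EstimationError("logistic fit did not converge; residuals unreliable")
    p = fit.fitted.to_numpy(dtype=float)
    if np.any(p <= 1e-12) or np.any(p >= 1 - 1e-12):
        raise EstimationError("fitted probabilities at 0/1; Pearson residual undefined")
    y = (fit.outcomes if outcomes is None else outcomes.reindex(fit.fitted.index)).to_numpy(
        dtype=float
    )
    resid = (y - p) / np.sqrt(p * (1 - p))
    return pd.DataFrame({"person_id": fit.fitted.index, "resid": resid}).reset_index(
        drop=True
    )
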