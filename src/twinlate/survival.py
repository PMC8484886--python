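"""Phenotypic Cox regression of dementia on baseline loneliness.

Time is measured from study intake (the first loneliness assessment) to
dementia diagnosis or censoring.  Baseline loneliness enters as categorical
levels (0 = reference), each interacting with intake age centred at 60, so
the main effects are hazard ratios at age 60 and the interactions describe
how they move with intake age.  Ties are handled with the Efron
approximation and, because co-twins are not independent, the pooled fits
use a cluster-robust (by family) variance by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines import exceptions as lifelines_exceptions

from .cohort import TwinCohort
from .errors import ConvergenceError, EstimationError, InestimableTermError

DEFAULT_CENTER_AGE = 60.0
Z95 = 1.959963984540054


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    coefficients: pd.Series
    se: pd.Series
    covariance: pd.DataFrame
    loglik: float
    n_events: int
    n_subjects: int
    ties_method: str
    center_age: float
    levels: tuple  # non-reference loneliness levels present

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


@dataclass
class HazardProfile:
    """HR of one loneliness level vs level 0 across intake ages."""

    loneliness_level: int
    table: pd.DataFrame  # columns: age, hr, ci_low, ci_high


def _person_frame(cohort: TwinCohort, center_age: float) -> pd.DataFrame:
    base = cohort.baseline_table()
    df = pd.DataFrame(
        {
            "family_id": base["family_id"],
            "duration": np.maximum(
                base["event_age"].to_numpy(dtype=float)
                - base["baseline_age"].to_numpy(dtype=float),
                1.0 / 365.25,
            ),
            "event": base["dementia"].to_numpy(dtype=int),
            "level": base["baseline_score"].to_numpy(dtype=float).astype(int),
            "age_c": base["baseline_age"].to_numpy(dtype=float) - center_age,
        }
    )
    return df


def _check_events(df: pd.DataFrame, label: str = "") -> None:
    n_events = int(df["event"].sum())
    where = f" in {label}" if label else ""
    if n_events == 0:
        raise EstimationError(f"all observations are censored{where}")
    if n_events < 2:
        raise EstimationError(f"fewer than 2 events{where}; model inestimable")


def _fit_lifelines(df, columns, robust, strata=None):
    cph = CoxPHFitter()
    kwargs = {}
    cols = list(columns)
    if strata:
        kwargs["strata"] = strata
        cols += [strata]
    elif robust:
        kwargs = {"cluster_col": "family_id", "robust": True}
        cols += ["family_id"]
    try:
        cph.fit(df[["duration", "event"] + cols], duration_col="duration",
                event_col="event", **kwargs)
    except (lifelines_exceptions.ConvergenceError, ValueError) as exc:
        raise ConvergenceError(f"Cox partial-likelihood fit failed: {exc}") from exc
    return cph


def fit_cox_model(
    cohort: TwinCohort,
    center_age: float = DEFAULT_CENTER_AGE,
    include_age: bool = True,
    robust: bool = True,
) -> CoxFit:
    """Cox regression of dementia on baseline loneliness levels.

    With ``include_age`` (default) the design is level dummies + centred
    intake age + level-by-age interactions, so ``exp(lon_k)`` is the hazard
    ratio of level k vs level 0 at the centring age.  Constant design
    columns raise :class:`InestimableTermError`.
    """
    df = _person_frame(cohort, center_age)
    _check_events(df)

    levels = tuple(sorted(set(df["level"]) - {0}))
    if not levels:
        raise InestimableTermError(
            "baseline loneliness is identical for all subjects; no contrast"
        )
    columns = []
    for lv in levels:
        df[f"lon{lv}"] = (df["level"] == lv).astype(float)
        columns.append(f"lon{lv}")
    if include_age:
        df["age_c"] = df["age_c"].astype(float)
        columns.append("age_c")
        for lv in levels:
            df[f"lon{lv}_x_age"] = df[f"lon{lv}"] * df["age_c"]
            columns.append(f"lon{lv}_x_age")

    for col in columns:
        if df[col].nunique() <= 1:
            raise InestimableTermError(f"covariate {col!r} is constant; no contrast")

    cph = _fit_lifelines(df, columns, robust)
    return CoxFit(
        coefficients=cph.params_.copy(),
        se=cph.standard_errors_.copy(),
        covariance=pd.DataFrame(
            cph.variance_matrix_, index=cph.params_.index, columns=cph.params_.index
        ),
        loglik=float(cph.log_likelihood_),
        n_events=int(df["event"].sum()),
        n_subjects=len(df),
        ties_method="efron",
        center_age=center_age,
        levels=levels,
    )


def hazard_ratio_profile(fit: CoxFit, level: int, ages) -> HazardProfile:
    """HR(age) = exp(b_level + b_interaction * (age - center)), with 95% CI.

    Level 0 is its own reference: the profile is identically 1.  The CI uses
    the delta method on the linear predictor.
    """
    ages = np.asarray(ages, dtype=float)
    if level == 0:
        ones = np.ones_like(ages)
        return HazardProfile(0, pd.DataFrame(
            {"age": ages, "hr": ones, "ci_low": ones, "ci_high": ones}))
    main = f"lon{level}"
    if main not in fit.coefficients.index:
        raise EstimationError(f"loneliness level {level} absent from the fit")
    b = float(fit.coefficients[main])
    inter = f"{main}_x_age"
    d = ages - fit.center_age
    if inter in fit.coefficients.index:
        bi = float(fit.coefficients[inter])
        lin = b + bi * d
        var = (
            fit.covariance.loc[main, main]
            + d**2 * fit.covariance.loc[inter, inter]
            + 2 * d * fit.covariance.loc[main, inter]
        )
    else:
        lin = np.full_like(ages, b)
        var = np.full_like(ages, fit.covariance.loc[main, main])
    sd = np.sqrt(np.clip(var, 0, None))
    return HazardProfile(
        level,
        pd.DataFrame(
            {
                "age": ages,
                "hr": np.exp(lin),
                "ci_low": np.exp(lin - Z95 * sd),
                "ci_high": np.exp(lin + Z95 * sd),
            }
        ),
    )


def fit_zygosity_stratified_cox(
    cohort: TwinCohort,
    low_max: int = 0,
    high_min: int = 2,
    center_age: float = DEFAULT_CENTER_AGE,
    include_age: bool = True,
    within_pair: bool = False,
) -> dict:
    """Separate Cox fits for MZ and DZ twins, low vs high baseline loneliness.

    Subjects are grouped into low (score <= ``low_max``) and high
    (score >= ``high_min``) baseline loneliness; intermediate scores are set
    aside.  Within each zygosity stratum the model regresses dementia on the
    high-group indicator (plus centred age and its interaction).

    With ``within_pair=True`` the partial likelihood is additionally
    stratified by family (the co-twin control design): only pairs discordant
    on the loneliness group inform the estimate, so genetic confounding is
    removed entirely in the MZ stratum and halved in the DZ stratum.
    Attenuation of the MZ within-pair association relative to the pooled
    phenotypic estimate signals familial confounding.
    """
    fits = {}
    for zyg in ("MZ", "DZ"):
        ids = cohort.individuals.loc[
            cohort.individuals["zygosity"] == zyg, "person_id"
        ]
        if ids.empty:
            raise EstimationError(f"zygosity stratum {zyg} is empty")
        sub = cohort.subset(ids)
        df = _person_frame(sub, center_age)
        df = df[(df["level"] <= low_max) | (df["level"] >= high_min)].copy()
        if df.empty:
            raise EstimationError(f"zygosity stratum {zyg} has no low/high subjects")
        _check_events(df, label=f"stratum {zyg}")
        df["high"] = (df["level"] >= high_min).astype(float)
        if df["high"].nunique() <= 1:
            raise InestimableTermError(
                f"stratum {zyg}: loneliness group indicator is constant"
            )
        columns = ["high"]
        if include_age and not within_pair:
            df["high_x_age"] = df["high"] * df["age_c"]
            columns += ["age_c", "high_x_age"]
        cph = _fit_lifelines(
            df, columns, robust=not within_pair,
            strata="family_id" if within_pair else None,
        )
        fits[zyg] = CoxFit(
            coefficients=cph.params_.copy(),
            se=cph.standard_errors_.copy(),
            covariance=pd.DataFrame(
                cph.variance_matrix_, index=cph.params_.index,
                columns=cph.params_.index,
            ),
            loglik=float(cph.log_likelihood_),
            n_events=int(df["event"].sum()),
            n_subjects=len(df),
            ties_method="efron",
            center_age=center_age,
            levels=("high",),
        )
    return fits
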