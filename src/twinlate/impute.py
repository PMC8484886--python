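"""Multiple imputation of loneliness scores by predictive mean matching.

Missing ordinal scores are imputed within each study stratum: a linear
prediction model is fitted on the complete person-waves, regression
coefficients are perturbed per imputation (drawn from their sampling
distribution), and each missing score receives the observed value of a
donor drawn at random from the k complete cases with the closest predicted
values.  Donor-based imputation guarantees every imputed value is a valid
0-3 category.  A delta-adjustment wrapper shifts imputed values by a fixed
offset to probe departures from the missing-at-random assumption, and
Rubin's rules pool per-imputation estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TwinCohort
from .errors import DomainError, EstimationError

DEFAULT_M = 50  # imputed data sets
DEFAULT_K_DONORS = 5
DF_CAP = 1e8  # reported df when between-imputation variance is 0

DEFAULT_PREDICTORS = (
    "time_in_study",
    "zygosity",
    "sex",
    "cohort",
    "education",
    "apoe_e4",
    "illness",
    "person_mean_score",
)


@dataclass
class ImputationSet:
    """m completed cohorts plus the imputation metadata."""

    m: int
    completed: list
    predictors: tuple
    seed: int
    delta: float = 0.0

    def score_means(self) -> list:
        """Mean loneliness score of each completed data set."""
        return [float(c.observations["score"].astype(float).mean())
                for c in self.completed]


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation estimates."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def _imputation_design(cohort: TwinCohort) -> pd.DataFrame:
    pw = cohort.person_waves()
    first_age = pw.groupby("person_id")["age_at_wave"].transform("min")
    pw["time_in_study"] = pw["age_at_wave"] - first_age
    pw["zyg_mz"] = (pw["zygosity"] == "MZ").astype(float)
    pw["sex_f"] = (pw["sex"] == "F").astype(float)
    pw["cohort_decade"] = (pw["birth_year"].astype(float) // 10).astype(float)
    pw["apoe_fill"] = pw["apoe_e4"].astype("Float64").fillna(0).astype(float)
    pw["apoe_miss"] = pw["apoe_e4"].isna().astype(float)
    score_num = pw["score"].astype(float)
    pmean = score_num.groupby(pw["person_id"]).transform("mean")
    pw["person_mean_score"] = pmean.fillna(score_num.mean())
    return pw


_PREDICTOR_COLUMNS = {
    "time_in_study": ["time_in_study"],
    "zygosity": ["zyg_mz"],
    "sex": ["sex_f"],
    "cohort": ["cohort_decade"],
    "education": ["education"],
    "apoe_e4": ["apoe_fill", "apoe_miss"],
    "illness": ["illness"],
    "person_mean_score": ["person_mean_score"],
}


def impute_pmm(
    cohort: TwinCohort,
    m: int = DEFAULT_M,
    predictors=DEFAULT_PREDICTORS,
    k_donors: int = DEFAULT_K_DONORS,
    seed: int = 0,
) -> ImputationSet:
    """Predictive-mean-matching multiple imputation of missing scores.

    Imputation runs within each study stratum.  Per imputation, the linear
    prediction coefficients are redrawn from their estimated sampling
    distribution (proper MI); each missing score takes the observed value of
    one of its ``k_donors`` nearest donors by predicted value.  A cohort
    without missing scores yields ``m`` identical copies.
    """
    if m < 2:
        raise DomainError("at least 2 imputations are required for pooling")
    rng = np.random.default_rng(seed)
    pw = _imputation_design(cohort)
    cols = [c for p in predictors for c in _PREDICTOR_COLUMNS[p]]

    missing_any = pw["score"].isna().to_numpy()
    completed = []
    base_obs = cohort.observations.copy().reset_index(drop=True)

    if not missing_any.any():
        for _ in range(m):
            completed.append(TwinCohort(cohort.individuals.copy(), base_obs.copy()))
        return ImputationSet(m, completed, tuple(predictors), seed)

    # per-stratum model pieces, computed once
    strata = []
    for study, g in pw.groupby("study", sort=False):
        obs_mask = g["score"].notna().to_numpy()
        X = np.column_stack(
            [np.ones(len(g))] + [g[c].to_numpy(dtype=float) for c in cols]
        )
        y = g["score"].to_numpy(dtype=float)
        n_obs = int(obs_mask.sum())
        if n_obs == 0:
            raise EstimationError(f"study {study}: no complete cases to impute from")
        if n_obs < k_donors:
            raise EstimationError(
                f"study {study}: fewer complete cases ({n_obs}) than donors requested"
            )
        Xo, yo = X[obs_mask], y[obs_mask]
        beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
        resid = yo - Xo @ beta
        dof = max(len(yo) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(Xo.T @ Xo)
        cov_beta = sigma2 * XtX_inv
        L = np.linalg.cholesky(cov_beta + 1e-12 * np.eye(len(beta)))
        strata.append(
            {
                "index": g.index.to_numpy(),
                "obs_mask": obs_mask,
                "X": X,
                "y": y,
                "beta": beta,
                "L": L,
            }
        )

    for _ in range(m):
        score = pw["score"].astype(float).to_numpy().copy()
        for st in strata:
            beta_star = st["beta"] + st["L"] @ rng.standard_normal(len(st["beta"]))
            pred_obs = st["X"][st["obs_mask"]] @ st["beta"]
            pred_mis = st["X"][~st["obs_mask"]] @ beta_star
            if len(pred_mis) == 0:
                continue
            donors_y = st["y"][st["obs_mask"]]
            dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
            k = min(k_donors, len(donors_y))
            nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
            pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, len(pred_mis))]
            score[st["index"][~st["obs_mask"]]] = donors_y[pick]
        obs_new = base_obs.copy()
        obs_new["score"] = pd.array(score, dtype="Float64")
        completed.append(TwinCohort(cohort.individuals.copy(), obs_new))

    return ImputationSet(m, completed, tuple(predictors), seed)


def delta_adjust(
    cohort: TwinCohort,
    deltas,
    m: int = DEFAULT_M,
    predictors=DEFAULT_PREDICTORS,
    k_donors: int = DEFAULT_K_DONORS,
    seed: int = 0,
) -> dict:
    """MNAR sensitivity analysis: shift imputed values by each delta.

    Each imputed (never observed) value is shifted by delta, clamped to
    [0, 3] and re-rounded to the ordinal scale.  All deltas reuse the same
    PMM draws under the shared seed, so delta = 0 reproduces the standard
    imputation bit for bit.  Returns mapping delta -> :class:`ImputationSet`.
    """
    deltas = list(deltas)
    if not deltas:
        raise DomainError("delta list must not be empty")
    if 0 not in deltas and 0.0 not in deltas:
        raise DomainError("delta grid must include 0 (the MAR reference)")

    base = impute_pmm(cohort, m=m, predictors=predictors, k_donors=k_donors, seed=seed)
    was_missing = cohort.observations["score"].isna().to_numpy()
    out = {}
    for delta in deltas:
        completed = []
        for comp in base.completed:
            obs = comp.observations.copy()
            vals = obs["score"].astype(float).to_numpy()
            shifted = np.clip(np.round(vals[was_missing] + delta), 0, 3)
            vals[was_missing] = shifted
            obs["score"] = pd.array(vals, dtype="Float64")
            completed.append(TwinCohort(comp.individuals.copy(), obs))
        out[delta] = ImputationSet(
            base.m, completed, base.predictors, seed, delta=float(delta)
        )
    return out


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Rubin's rules: combine per-imputation estimates and squared SEs.

    total variance T = W + (1 + 1/m) B and
    df = (m - 1) (1 + W / ((1 + 1/m) B))^2, capped when B = 0.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise DomainError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise DomainError("pooling requires at least 2 imputations")
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1))
    total = wbar + (1 + 1 / m) * b
    if b > 0:
        df = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
        df = float(min(df, DF_CAP))
    else:
        df = DF_CAP
    return PooledEstimate(
        estimate=qbar, within_var=wbar, between_var=b, total_var=float(total),
        df=df, m=m,
    )
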