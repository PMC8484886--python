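"""Latent growth curves of loneliness on centred age.

Age enters as t = (age - 60) / 10 (decades, centred at 60), so the intercept
is the expected loneliness level at age 60 and the quadratic term captures
the late-life upswing.  The model for person i is

    y_it = (b0 + u0_i) + (b1 + u1_i) t + (b2 + u2_i) t^2 + e_it,

with random growth parameters u_i ~ N(0, G) (intercept-slope covariance
free, quadratic variance independent) and level-1 residual e ~ N(0, s^2).
Estimation is straight maximum likelihood over per-person marginal Gaussian
contributions, which makes linear-vs-quadratic likelihood-ratio tests valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._mlcore import MarginalData, MarginalModel, chol_to_cov
from .cohort import TwinCohort
from .errors import EstimationError

AGE_CENTER = 60.0
AGE_SCALE = 10.0
ALPHA = 0.05


def age_to_t(age):
    """Centred, decade-scaled age transform used throughout the package."""
    return (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE


@dataclass
class GrowthFit:
    """ML fit of a linear or quadratic latent growth curve."""

    order: str
    fixed: np.ndarray  # (b0, b1[, b2])
    fixed_se: np.ndarray
    random_variances: dict  # var_intercept, var_linear[, var_quadratic], cov_is
    resid_var: float
    loglik: float
    n_params: int
    n_persons: int
    n_obs: int
    converged: bool
    boundary: list = field(default_factory=list)
    _fit: object = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_persons) * self.n_params


@dataclass
class ModelComparison:
    """LRT / AIC / BIC comparison of two nested ML fits."""

    lrt_stat: float
    delta_df: int
    p_value: float
    aic_each: dict
    bic_each: dict
    preferred: str
    labels: tuple

    def __str__(self):
        return (
            f"LRT = {self.lrt_stat:.3f}, ddf = {self.delta_df}, "
            f"p = {self.p_value:.4g}; preferred: {self.preferred}"
        )


# ---------------------------------------------------------------------------


def _person_arrays(cohort: TwinCohort, q: int):
    """Padded (Y, X, B, obs, pad) arrays, one cluster per person."""
    obs = cohort.observations.dropna(subset=["score"]).sort_values(
        ["person_id", "wave"]
    )
    if obs.empty:
        raise EstimationError("no non-missing loneliness scores")
    groups = list(obs.groupby("person_id", sort=False))
    sizes = [len(g) for _, g in groups]
    if max(sizes) < 2:
        raise EstimationError("all persons have a single wave; random slopes inestimable")
    if q == 3 and max(sizes) < 3:
        raise EstimationError("quadratic order needs at least one person with 3 waves")
    P, M = len(groups), max(sizes)
    Y = np.zeros((P, M))
    X = np.zeros((P, M, q))
    obs_ind = np.zeros((P, M))
    pad = np.ones((P, M))
    for p, (_, g) in enumerate(groups):
        n = len(g)
        t = age_to_t(g["age_at_wave"].to_numpy())
        Y[p, :n] = g["score"].to_numpy(dtype=float)
        X[p, :n, 0] = 1.0
        X[p, :n, 1] = t
        if q == 3:
            X[p, :n, 2] = t**2
        obs_ind[p, :n] = 1.0
        pad[p, :n] = 0.0
    return Y, X, obs_ind, pad, P, int(sum(sizes))


def _growth_assemble(q):
    if q == 2:
        def assemble(kp):
            return [chol_to_cov(kp[0], kp[1], kp[2])]
        return assemble, 3

    def assemble(kp):
        return [chol_to_cov(kp[0], kp[1], kp[2], kp[3])]
    return assemble, 4


def fit_growth_curve(cohort: TwinCohort, order: str = "quadratic") -> GrowthFit:
    """Fit the latent growth curve by marginal ML.

    ``order`` is ``"linear"`` (random intercept + slope) or ``"quadratic"``
    (adds fixed and random quadratic terms).  Variance estimates that hit the
    0 boundary are reported as 0 and listed in ``boundary``.  The quadratic
    fit is warm-started from the linear solution, so its log-likelihood can
    never fall below the linear one.
    """
    if order not in ("linear", "quadratic"):
        raise ValueError(f"unknown growth order {order!r}")
    q = 2 if order == "linear" else 3
    Y, X, obs_ind, pad, P, n_obs = _person_arrays(cohort, q)
    data = MarginalData(Y, X, X.copy(), obs_ind, pad, np.zeros(P, dtype=int), 1)
    assemble, n_k = _growth_assemble(q)
    model = MarginalModel(data, assemble, n_k)

    # start: pooled OLS for the mean, modest random variances
    Xf = X[obs_ind.astype(bool)]
    yf = Y[obs_ind.astype(bool)]
    beta0, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
    resid = yf - Xf @ beta0
    s0 = max(float(np.std(resid)), 1e-3)
    k0 = [0.5 * s0, 0.0, 0.25 * s0] + ([0.05 * s0] if q == 3 else [])
    theta0 = np.concatenate([beta0, [np.log(s0 / np.sqrt(2))], k0])

    bounds = {q: (np.log(1e-5), np.log(1e3))}  # keep sigma off exact zero
    fit = model.fit(theta0, bounds=bounds)

    if order == "quadratic":
        # warm start embedding the linear solution guarantees nesting
        lin = fit_growth_curve(cohort, "linear")
        theta_lin = np.concatenate(
            [
                [*lin.fixed, 0.0],
                [0.5 * np.log(max(lin.resid_var, 1e-10))],
                lin._fit.theta[3:6],
                [1e-3],
            ]
        )
        fit2 = model.fit(theta_lin, bounds=bounds)
        if fit2.loglik > fit.loglik:
            fit = fit2

    beta = fit.theta[:q]
    sigma2 = float(np.exp(2 * fit.theta[q]))
    kp = fit.theta[q + 1 :]
    G = assemble(kp)[0]
    rv = {
        "var_intercept": float(G[0, 0]),
        "var_linear": float(G[1, 1]),
        "cov_is": float(G[0, 1]),
    }
    if q == 3:
        rv["var_quadratic"] = float(G[2, 2])
    boundary = [k for k, v in rv.items() if k.startswith("var") and v < 1e-6]

    se_all = np.sqrt(np.clip(np.diag(fit.beta_cov), 0.0, None))
    return GrowthFit(
        order=order,
        fixed=beta.copy(),
        fixed_se=se_all,
        random_variances=rv,
        resid_var=sigma2,
        loglik=float(fit.loglik),
        n_params=model.n_params,
        n_persons=P,
        n_obs=n_obs,
        converged=fit.converged,
        boundary=boundary,
        _fit=fit,
    )


def compare_growth_models(fit_small: GrowthFit, fit_big: GrowthFit,
                          alpha: float = ALPHA) -> ModelComparison:
    """Likelihood-ratio comparison of nested growth fits.

    Follows the parsimony rule: the smaller model is preferred unless the
    LRT is significant at ``alpha``.  AIC/BIC for both fits are reported
    alongside.
    """
    if fit_small.n_params >= fit_big.n_params:
        raise EstimationError("fits are not nested (parameter counts do not increase)")
    if (fit_small.n_persons, fit_small.n_obs) != (fit_big.n_persons, fit_big.n_obs):
        raise EstimationError("fits were not computed on the same data")
    ddf = fit_big.n_params - fit_small.n_params
    lrt = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    p = float(stats.chi2.sf(lrt, ddf))
    preferred = fit_big.order if p < alpha else fit_small.order
    return ModelComparison(
        lrt_stat=float(lrt),
        delta_df=int(ddf),
        p_value=p,
        aic_each={fit_small.order: fit_small.aic, fit_big.order: fit_big.aic},
        bic_each={fit_small.order: fit_small.bic, fit_big.order: fit_big.bic},
        preferred=preferred,
        labels=(fit_small.order, fit_big.order),
    )
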