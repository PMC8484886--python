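"""Twin ACE decomposition of loneliness growth and biometric regression.

The growth parameters (intercept, linear, quadratic on centred age) of the
loneliness trajectory decompose, per twin i in family j, into additive
genetic (A), shared environmental (C) and nonshared environmental (E)
component scores.  Monozygotic pairs share A entirely (within-family genetic
variance 0); dizygotic pairs split the genetic variance equally between a
shared and an individual part, so the cross-twin covariance of a growth
parameter is sigma2_A + sigma2_C in MZ pairs and 0.5 sigma2_A + sigma2_C in
DZ pairs.  Shared environment is wholly between-family, nonshared
environment wholly within-family.

Estimation is direct maximum likelihood on per-pair joint Gaussian
likelihoods: each pair contributes its stacked repeated measures (and, in
the biometric regression, its continuous dementia-risk scores), with the
implied covariance assembled from the component matrices.  This is the
multigroup (MZ/DZ) equivalent of a three-level formulation and of the usual
SEM path models.

The biometric regression then regresses the dementia-risk score on the
latent components,

    risk_ij = mu + sum_k (areg_k A_kij + creg_k C_kj + ereg_k Ew_kij) + e_ij,

with the residual e split into zygosity-specific within- and between-family
variances.  A significant ereg (nonshared-environmental path) is the
quasi-causal signal; areg/creg capture genetic and shared-environmental
selection.  Components whose variance estimate sits on the 0 boundary are
dropped from the regression (their paths are unidentified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mlcore import MarginalData, MarginalModel, chol_to_cov, delta_method
from .cohort import TwinCohort
from .errors import DomainError, EstimationError, InestimableTermError
from .growth import ALPHA, ModelComparison, age_to_t, fit_growth_curve

PARAMS = ("intercept", "linear", "quadratic")
COMPONENTS = ("A", "C", "E")

#: a component variance below this fraction of its parameter's total
#: variance is treated as sitting on the 0 boundary
DROP_FRACTION = 0.005


@dataclass
class ICCEstimate:
    """Intraclass correlation from within/between variance components."""

    within: float
    between: float
    icc: float


@dataclass
class UnivariateACE:
    """Method-of-moments (Falconer) ACE proportions from twin correlations."""

    h2: float
    c2: float
    e2: float

    def as_tuple(self):
        return (self.h2, self.c2, self.e2)


def intraclass_correlation(within: float, between: float) -> ICCEstimate:
    """ICC = between / (between + within); twin-pair similarity."""
    if within + between <= 0:
        raise DomainError("within + between variance must be positive")
    return ICCEstimate(within=float(within), between=float(between),
                       icc=float(between / (between + within)))


def falconer_estimates(r_mz: float, r_dz: float) -> UnivariateACE:
    """Falconer formulas: h2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ.

    The three proportions sum to 1 identically.  Negative values (e.g. c2
    when rMZ > 2 rDZ) are passed through untouched - they are a meaningful
    moment-based diagnostic, not an error.
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise DomainError(f"twin correlations must lie in [-1, 1], got {r}")
    return UnivariateACE(
        h2=2.0 * (r_mz - r_dz), c2=2.0 * r_dz - r_mz, e2=1.0 - r_mz
    )


# ---------------------------------------------------------------------------
# pair-level data assembly


def _pair_arrays(cohort: TwinCohort, risk: pd.DataFrame | None):
    """Padded per-pair arrays: stacked twin observations (+ risk rows)."""
    obs = cohort.observations.dropna(subset=["score"]).sort_values(
        ["person_id", "wave"]
    )
    by_person = {pid: g for pid, g in obs.groupby("person_id", sort=False)}
    risk_map = (
        dict(zip(risk["person_id"], risk["resid"].astype(float)))
        if risk is not None
        else {}
    )
    ind = cohort.individuals
    zyg_by_fam = dict(zip(ind["family_id"], ind["zygosity"]))

    clusters = []  # (zygosity, [(t_array, y_array, risk_or_None), ...])
    for fam, g in ind.groupby("family_id", sort=False):
        members = []
        for pid in g["person_id"]:
            if pid not in by_person:
                continue
            gg = by_person[pid]
            t = age_to_t(gg["age_at_wave"].to_numpy())
            y = gg["score"].to_numpy(dtype=float)
            r = risk_map.get(pid) if risk is not None else None
            members.append((t, y, r))
        if members:
            clusters.append((zyg_by_fam[fam], members))

    zygs = {z for z, _ in clusters}
    for z in ("MZ", "DZ"):
        if z not in zygs:
            raise EstimationError(f"no usable families in the {z} stratum")

    q = 3
    with_risk = risk is not None
    L = 2 * q + (2 if with_risk else 0)
    p = q + (1 if with_risk else 0)
    sizes = [
        sum(len(t) for t, _, _ in mem) + (sum(r is not None for _, _, r in mem)
                                          if with_risk else 0)
        for _, mem in clusters
    ]
    P, M = len(clusters), max(sizes)
    Y = np.zeros((P, M))
    X = np.zeros((P, M, p))
    B = np.zeros((P, M, L))
    obs_ind = np.zeros((P, M))
    pad = np.ones((P, M))
    group = np.zeros(P, dtype=int)

    for j, (zyg, mem) in enumerate(clusters):
        group[j] = 0 if zyg == "MZ" else 1
        row = 0
        for i, (t, y, r) in enumerate(mem):
            n = len(t)
            Z = np.column_stack([np.ones(n), t, t**2])
            Y[j, row : row + n] = y
            X[j, row : row + n, :q] = Z
            B[j, row : row + n, i * q : (i + 1) * q] = Z
            obs_ind[j, row : row + n] = 1.0
            pad[j, row : row + n] = 0.0
            row += n
        if with_risk:
            for i, (_, _, r) in enumerate(mem):
                if r is None:
                    continue
                Y[j, row] = r
                X[j, row, q] = 1.0  # mu
                B[j, row, 2 * q + i] = 1.0
                pad[j, row] = 0.0
                row += 1
    n_complete = sum(1 for _, mem in clusters if len(mem) == 2)
    return MarginalData(Y, X, B, obs_ind, pad, group, 2), n_complete


def _chol_params(cov):
    l11 = np.sqrt(max(cov[0, 0], 1e-10))
    l21 = cov[0, 1] / l11
    l22 = np.sqrt(max(cov[1, 1] - l21**2, 1e-10))
    l33 = np.sqrt(max(cov[2, 2], 1e-10))
    return [l11, l21, l22, l33]


def _component_covs(kp):
    return (
        chol_to_cov(*kp[0:4]),
        chol_to_cov(*kp[4:8]),
        chol_to_cov(*kp[8:12]),
    )


def _assemble_decomposition(kp):
    SA, SC, SE = _component_covs(kp)
    G = SA + SC + SE
    out = []
    for w in (1.0, 0.5):  # MZ, DZ genetic cross-twin weight
        cross = w * SA + SC
        out.append(np.block([[G, cross], [cross, G]]))
    return out


def _assemble_biometric(kp):
    SA, SC, SE = _component_covs(kp[0:12])
    a, c, e = kp[12:15], kp[15:18], kp[18:21]
    s = kp[21:25]  # (MZ within, MZ between, DZ within, DZ between) sds
    va, vc, ve = SA @ a, SC @ c, SE @ e
    qa, qc, qe = a @ va, c @ vc, e @ ve
    G = SA + SC + SE
    out = []
    for gi, w in ((0, 1.0), (1, 0.5)):
        sw2, sb2 = s[2 * gi] ** 2, s[2 * gi + 1] ** 2
        cross = w * SA + SC
        K = np.zeros((8, 8))
        K[0:3, 0:3] = K[3:6, 3:6] = G
        K[0:3, 3:6] = K[3:6, 0:3] = cross
        ur_own = va + vc + ve
        ur_other = w * va + vc
        for i, other in ((0, 1), (1, 0)):
            K[3 * i : 3 * i + 3, 6 + i] = ur_own
            K[6 + i, 3 * i : 3 * i + 3] = ur_own
            K[3 * i : 3 * i + 3, 6 + other] = ur_other
            K[6 + other, 3 * i : 3 * i + 3] = ur_other
        K[6, 6] = K[7, 7] = qa + qc + qe + sw2 + sb2
        K[6, 7] = K[7, 6] = w * qa + qc + sb2
        out.append(K)
    return out


def _chol_chain(M, l):
    """Gradient of sum(M * Sigma) w.r.t. the 4 Cholesky factors of Sigma."""
    l11, l21, l22, l33 = l
    s01 = M[0, 1] + M[1, 0]
    return np.array(
        [
            2.0 * l11 * M[0, 0] + l21 * s01,
            l11 * s01 + 2.0 * l21 * M[1, 1],
            2.0 * l22 * M[1, 1],
            2.0 * l33 * M[2, 2],
        ]
    )


def _decomposition_k_grad(kp, W):
    """Analytic gradient of 1/2 sum_g tr(K_g W_g) for the ACE assembly."""
    MA = np.zeros((3, 3))
    MC = np.zeros((3, 3))
    ME = np.zeros((3, 3))
    for gi, w in ((0, 1.0), (1, 0.5)):
        Wg = W[gi]
        Wu = Wg[0:3, 0:3] + Wg[3:6, 3:6]
        Wx = Wg[0:3, 3:6] + Wg[3:6, 0:3].T
        MA += Wu + w * Wx
        MC += Wu + Wx
        ME += Wu
    g = np.concatenate(
        [
            _chol_chain(MA, kp[0:4]),
            _chol_chain(MC, kp[4:8]),
            _chol_chain(ME, kp[8:12]),
        ]
    )
    return 0.5 * g


def _biometric_k_grad(kp, W):
    """Analytic gradient of 1/2 sum_g tr(K_g W_g) for the joint assembly."""
    SA, SC, SE = _component_covs(kp[0:12])
    a, c, e = kp[12:15], kp[15:18], kp[18:21]
    s = kp[21:25]
    MA = np.zeros((3, 3)); MC = np.zeros((3, 3)); ME = np.zeros((3, 3))
    ga = np.zeros(3); gc = np.zeros(3); ge = np.zeros(3)
    gs = np.zeros(4)
    for gi, w in ((0, 1.0), (1, 0.5)):
        Wg = W[gi]
        Wu = Wg[0:3, 0:3] + Wg[3:6, 3:6]
        Wx = Wg[0:3, 3:6] + Wg[3:6, 0:3].T
        v_own = 2.0 * (Wg[0:3, 6] + Wg[3:6, 7])
        v_oth = 2.0 * (Wg[0:3, 7] + Wg[3:6, 6])
        q_diag = Wg[6, 6] + Wg[7, 7]
        q_off = 2.0 * Wg[6, 7]

        MA += Wu + w * Wx + np.outer(v_own + w * v_oth, a) \
            + (q_diag + w * q_off) * np.outer(a, a)
        MC += Wu + Wx + np.outer(v_own + v_oth, c) \
            + (q_diag + q_off) * np.outer(c, c)
        ME += Wu + np.outer(v_own, e) + q_diag * np.outer(e, e)

        ga += SA @ (v_own + w * v_oth) + 2.0 * (q_diag + w * q_off) * (SA @ a)
        gc += SC @ (v_own + v_oth) + 2.0 * (q_diag + q_off) * (SC @ c)
        ge += SE @ v_own + 2.0 * q_diag * (SE @ e)
        gs[2 * gi] += 2.0 * s[2 * gi] * q_diag
        gs[2 * gi + 1] += 2.0 * s[2 * gi + 1] * (q_diag + q_off)
    g = np.concatenate(
        [
            _chol_chain(MA, kp[0:4]),
            _chol_chain(MC, kp[4:8]),
            _chol_chain(ME, kp[8:12]),
            ga, gc, ge, gs,
        ]
    )
    return 0.5 * g


# ---------------------------------------------------------------------------
# variance decomposition


@dataclass
class VarianceComponents:
    """ML estimates of ACE variances for each loneliness growth parameter."""

    variances: pd.DataFrame  # index PARAMS, columns var_a/var_c/var_e + SEs
    cov_is: dict  # component -> intercept-slope covariance
    fixed: np.ndarray
    resid_var: float
    loglik: float
    n_params: int
    n_pairs: int
    dropped: list = field(default_factory=list)
    _fit: object = None

    def group_moments(self) -> pd.DataFrame:
        """Model-implied within/between variances per zygosity group.

        MZ_B = s2A + s2C, MZ_W = s2E, DZ_B = 0.5 s2A + s2C,
        DZ_W = 0.5 s2A + s2E - exact algebraic images of the components.
        """
        rows = []
        for param in PARAMS:
            va, vc, ve = (self.variances.loc[param, f"var_{x}"] for x in "ace")
            rows.append(
                {
                    "parameter": param,
                    "MZ_W": ve,
                    "MZ_B": va + vc,
                    "DZ_W": 0.5 * va + ve,
                    "DZ_B": 0.5 * va + vc,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def iccs(self) -> pd.DataFrame:
        """Model-implied twin ICCs per zygosity (NaN where total variance 0)."""
        m = self.group_moments()
        out = {}
        for z in ("MZ", "DZ"):
            tot = m[f"{z}_B"] + m[f"{z}_W"]
            out[f"icc_{z.lower()}"] = np.where(tot > 0, m[f"{z}_B"] / tot, np.nan)
        return pd.DataFrame(out, index=m.index)

    def ace_proportions(self) -> pd.DataFrame:
        """Standardised (h2, c2, e2) per growth parameter."""
        v = self.variances
        tot = v["var_a"] + v["var_c"] + v["var_e"]
        return pd.DataFrame(
            {
                "h2": v["var_a"] / tot,
                "c2": v["var_c"] / tot,
                "e2": v["var_e"] / tot,
            }
        )


def _decomposition_theta0(cohort):
    # start at the phenotypic growth fit with the person-level variance
    # split evenly across A, C and E
    growth = fit_growth_curve(cohort, "quadratic")
    rv = growth.random_variances
    third = np.array(
        [
            [max(rv["var_intercept"], 1e-5) / 3.0, rv["cov_is"] / 3.0, 0.0],
            [rv["cov_is"] / 3.0, max(rv["var_linear"], 1e-5) / 3.0, 0.0],
            [0.0, 0.0, max(rv.get("var_quadratic", 1e-4), 1e-5) / 3.0],
        ]
    )
    kp0 = _chol_params(third) * 3
    return np.concatenate(
        [growth.fixed, [0.5 * np.log(max(growth.resid_var, 1e-8))], kp0]
    )


def _detect_dropped(kp):
    SA, SC, SE = _component_covs(kp)
    total = np.diag(SA) + np.diag(SC) + np.diag(SE)
    dropped = []
    for ci, S in (("A", SA), ("C", SC), ("E", SE)):
        for k, param in enumerate(PARAMS):
            if total[k] <= 0 or S[k, k] < DROP_FRACTION * total[k]:
                dropped.append((ci, param))
    return dropped


#: chol-parameter offsets (within a component's 4-block) tied to each growth
#: parameter's variance
_CHOL_OF_PARAM = {"intercept": [0], "linear": [1, 2], "quadratic": [3]}


def fit_twin_decomposition(
    cohort: TwinCohort, growth_order: str = "quadratic", compute_se: bool = True
) -> VarianceComponents:
    """Multigroup ML ACE decomposition of the growth parameters.

    Both zygosity groups must be present; complete pairs contribute joint
    bivariate terms, singletons their marginals.  Component variances whose
    estimate sits on the 0 boundary are reported as dropped (the emulated
    study found no between-pair variance in the quadratic slope, which
    surfaces here as A and C quadratic components on the boundary).
    """
    if growth_order != "quadratic":
        raise EstimationError("the decomposition is defined for the quadratic model")
    data, n_complete = _pair_arrays(cohort, risk=None)
    model = MarginalModel(data, _assemble_decomposition, 12,
                          k_grad=_decomposition_k_grad)
    theta0 = _decomposition_theta0(cohort)
    bounds = {3: (np.log(1e-5), np.log(1e3))}
    fit = model.fit(theta0, bounds=bounds)

    kp = fit.theta[4:16]
    SA, SC, SE = _component_covs(kp)
    dropped = _detect_dropped(kp)

    def nat(th):
        A, C, E = _component_covs(th[4:16])
        return np.concatenate([np.diag(A), np.diag(C), np.diag(E)])

    if compute_se:
        vals, ses = delta_method(fit, nat)
    else:
        vals = np.asarray(nat(fit.theta))
        ses = np.full_like(vals, np.nan)
    variances = pd.DataFrame(
        {
            "var_a": vals[0:3], "se_var_a": ses[0:3],
            "var_c": vals[3:6], "se_var_c": ses[3:6],
            "var_e": vals[6:9], "se_var_e": ses[6:9],
        },
        index=list(PARAMS),
    )
    return VarianceComponents(
        variances=variances,
        cov_is={"A": float(SA[0, 1]), "C": float(SC[0, 1]), "E": float(SE[0, 1])},
        fixed=fit.theta[:3].copy(),
        resid_var=float(np.exp(2 * fit.theta[3])),
        loglik=float(fit.loglik),
        n_params=model.n_params,
        n_pairs=n_complete,
        dropped=dropped,
        _fit=fit,
    )


# ---------------------------------------------------------------------------
# biometric regression


_REG_NAMES = [f"{c}reg{k}" for c in "ace" for k in (1, 2, 3)]


def _biom_param_names():
    names = ["beta0", "beta1", "beta2", "mu", "log_sigma"]
    for comp in COMPONENTS:
        names += [f"{comp}_l11", f"{comp}_l21", f"{comp}_l22", f"{comp}_l33"]
    names += _REG_NAMES
    names += ["s_MZW", "s_MZB", "s_DZW", "s_DZB"]
    return names


@dataclass
class BiometricRegressionFit:
    """Joint ML fit of the ACE decomposition and the risk regression."""

    mu: float
    regressions: pd.DataFrame  # index (component, parameter): estimate, se, p
    resid_var_by_group: pd.DataFrame  # zygosity x (within, between) + SEs
    components: VarianceComponents
    dropped_terms: list
    loglik: float
    n_params: int
    n_free: int
    converged: bool
    param_names: list = field(default_factory=_biom_param_names)
    _fit: object = None
    _cohort_key: tuple = None

    def regression(self, component: str, parameter: str) -> pd.Series:
        return self.regressions.loc[(component, parameter)]

    def risk_moments(self) -> pd.DataFrame:
        """Implied within/between variance of the risk score per zygosity."""
        th = self._fit.theta
        kp = th[5:]
        SA, SC, SE = _component_covs(kp[0:12])
        a, c, e = kp[12:15], kp[15:18], kp[18:21]
        s = kp[21:25]
        qa, qc, qe = a @ SA @ a, c @ SC @ c, e @ SE @ e
        rows = {}
        for gi, (z, w) in enumerate((("MZ", 1.0), ("DZ", 0.5))):
            sw2, sb2 = s[2 * gi] ** 2, s[2 * gi + 1] ** 2
            between = w * qa + qc + sb2
            total = qa + qc + qe + sw2 + sb2
            rows[z] = {"within": total - between, "between": between}
        return pd.DataFrame(rows).T


def _reg_index(kind, k):
    # position of a regression coefficient inside the theta vector
    base = 5 + 12
    return base + {"a": 0, "c": 3, "e": 6}[kind] + k


def fit_biometric_regression(
    cohort: TwinCohort,
    risk: pd.DataFrame,
    two_stage: bool = False,
    stage1: bool = True,
) -> BiometricRegressionFit:
    """Regress the continuous dementia-risk score on latent ACE components.

    ``risk`` is a (person_id, resid) table such as the output of
    :func:`twinlate.risk.pearson_residuals`.  By default the decomposition
    and the regression are estimated jointly; ``two_stage=True`` freezes the
    growth/ACE parameters at their decomposition estimates and estimates the
    regression conditionally (faster, slightly less efficient).
    ``stage1=False`` skips the warm-start decomposition fit and starts from
    pooled moments instead (used by large simulation studies; boundary
    components are still detected and dropped after the joint fit).

    Wald standard errors and p-values are reported for every free parameter;
    for variance parameters near the 0 boundary they are approximations and
    should be read as descriptive.
    """
    risk = risk.dropna(subset=["resid"])
    if risk["resid"].nunique() <= 1:
        raise InestimableTermError("risk score is constant; regression inestimable")

    data, n_complete = _pair_arrays(cohort, risk=risk)
    model = MarginalModel(data, _assemble_biometric, 25, k_grad=_biometric_k_grad)

    r = risk["resid"].to_numpy(dtype=float)
    s0 = float(np.std(r))
    if stage1 or two_stage:
        decomp = fit_twin_decomposition(cohort, compute_se=False)
        th1 = decomp._fit.theta
        chol0 = th1[4:16]
        log_sig0 = th1[3]
        dropped = list(decomp.dropped)
    else:
        # pooled-moment start: half the score variance to the person level,
        # split evenly across A, C and E intercepts
        y = cohort.observations["score"].astype(float)
        vy = max(float(y.var(ddof=1)), 1e-3)
        l0 = np.sqrt(vy / 6.0)
        chol0 = [l0, 0.0, 0.3 * l0, 0.2 * l0] * 3
        log_sig0 = 0.5 * np.log(vy / 2.0)
        dropped = []
    theta0 = np.concatenate(
        [
            np.zeros(3), [float(np.mean(r))], [log_sig0], chol0,
            np.zeros(9),
            [0.7 * s0, 0.5 * s0, 0.7 * s0, 0.5 * s0],
        ]
    )

    def fixed_for(dropped):
        fixed = {}
        for comp, param in dropped:
            block = 5 + 4 * COMPONENTS.index(comp)
            for off in _CHOL_OF_PARAM[param]:
                fixed[block + off] = 0.0
            fixed[_reg_index(comp.lower(), PARAMS.index(param))] = 0.0
        return fixed

    bounds = {4: (np.log(1e-5), np.log(1e3))}
    if two_stage:
        # freeze the growth/ACE covariance structure at stage-1 estimates
        # (the mean parameters re-profile automatically)
        frozen = {i: theta0[i] for i in (4, *range(5, 17))}
    else:
        frozen = {}

    for _ in range(2):
        fixed = {**fixed_for(dropped), **frozen}
        fit = model.fit(theta0, fixed=fixed, bounds=bounds)
        new_dropped = [
            d for d in _detect_dropped(fit.theta[5:17]) if d not in dropped
        ]
        if not new_dropped:
            break
        for d in new_dropped:
            warnings.warn(
                f"component {d[0]} variance of the {d[1]} hit the 0 boundary; "
                "its regression path is dropped"
            )
        dropped += new_dropped

    # regressions whose likelihood information vanished at the solution are
    # unidentified: report them as dropped rather than with arbitrary SEs
    cov = fit.covariance()
    flat = fit.flat_coordinates()
    pos_of = {idx: a for a, idx in enumerate(fit.free)}
    for comp in COMPONENTS:
        for pi, param in enumerate(PARAMS):
            if (comp, param) in dropped:
                continue
            a = pos_of.get(_reg_index(comp.lower(), pi))
            if a is not None and flat[a]:
                warnings.warn(
                    f"regression of risk on the {comp} {param} component is "
                    "unidentified at this solution; term dropped"
                )
                dropped.append((comp, param))

    reg_idx = [_reg_index(k, p) for k in "ace" for p in range(3)]

    def nat(th):
        return th[reg_idx]

    vals, ses = delta_method(fit, nat, cov_free=cov)
    rows = []
    for ci, comp in enumerate(COMPONENTS):
        for pi, param in enumerate(PARAMS):
            j = ci * 3 + pi
            is_dropped = (comp, param) in dropped
            est = np.nan if is_dropped else vals[j]
            se = np.nan if is_dropped else ses[j]
            p = (
                np.nan
                if is_dropped or not np.isfinite(se) or se == 0
                else float(2 * stats.norm.sf(abs(est / se)))
            )
            rows.append(
                {"component": comp, "parameter": param, "estimate": est,
                 "se": se, "p": p}
            )
    reg_table = pd.DataFrame(rows).set_index(["component", "parameter"])

    def nat_var(th):
        A, C, E = _component_covs(th[5:17])
        s = th[26:30]
        return np.concatenate([np.diag(A), np.diag(C), np.diag(E), s**2])

    v_vals, v_ses = delta_method(fit, nat_var, cov_free=cov)
    variances = pd.DataFrame(
        {
            "var_a": v_vals[0:3], "se_var_a": v_ses[0:3],
            "var_c": v_vals[3:6], "se_var_c": v_ses[3:6],
            "var_e": v_vals[6:9], "se_var_e": v_ses[6:9],
        },
        index=list(PARAMS),
    )
    SA, SC, SE = _component_covs(fit.theta[5:17])
    components = VarianceComponents(
        variances=variances,
        cov_is={"A": float(SA[0, 1]), "C": float(SC[0, 1]), "E": float(SE[0, 1])},
        fixed=fit.theta[:3].copy(),
        resid_var=float(np.exp(2 * fit.theta[4])),
        loglik=float(fit.loglik),
        n_params=model.n_params,
        n_pairs=n_complete,
        dropped=dropped,
        _fit=fit,
    )
    resid = pd.DataFrame(
        {
            "within": [v_vals[9], v_vals[11]],
            "between": [v_vals[10], v_vals[12]],
            "se_within": [v_ses[9], v_ses[11]],
            "se_between": [v_ses[10], v_ses[12]],
        },
        index=["MZ", "DZ"],
    )
    return BiometricRegressionFit(
        mu=float(fit.theta[3]),
        regressions=reg_table,
        resid_var_by_group=resid,
        components=components,
        dropped_terms=dropped,
        loglik=float(fit.loglik),
        n_params=model.n_params,
        n_free=fit.n_free,
        converged=fit.converged,
        _fit=fit,
    )


# ---------------------------------------------------------------------------
# equality constraints


def _constraint_indices(full: BiometricRegressionFit, name: str):
    """Map a natural parameter name to theta indices (on the chol scale)."""
    names = full.param_names
    if name in names:
        return [names.index(name)]
    if name.startswith("var_"):
        _, comp, param = name.split("_", 2)
        comp = comp.upper()
        if (comp, param) in full.dropped_terms:
            raise EstimationError(f"cannot constrain dropped component {name}")
        block = 5 + 4 * COMPONENTS.index(comp)
        return [block + off for off in _CHOL_OF_PARAM[param]]
    raise EstimationError(f"unknown parameter name {name!r}")


def constrain_and_test(
    full: BiometricRegressionFit,
    constraints: dict,
    alpha: float = ALPHA,
) -> ModelComparison:
    """Refit the biometric model under equality/fix constraints and LRT it.

    ``constraints`` may contain ``equate`` (list of groups of parameter
    names forced equal, e.g. ``[["areg1", "creg1"]]``) and ``fix`` (mapping
    name -> value).  Variance names (``var_a_intercept``...) are tied on the
    Cholesky scale, which equates the variances exactly for the intercept
    and quadratic and ties the full (variance, covariance) block for the
    linear slope.  Constraints on dropped components raise.
    """
    equate = constraints.get("equate", [])
    fix = constraints.get("fix", {})
    for name in [n for grp in equate for n in grp] + list(fix):
        for comp, param in full.dropped_terms:
            idx = _reg_index(comp.lower(), PARAMS.index(param))
            if name in full.param_names and full.param_names.index(name) == idx:
                raise EstimationError(f"cannot constrain dropped parameter {name!r}")

    ties = []
    for grp in equate:
        cols = [_constraint_indices(full, n) for n in grp]
        width = {len(c) for c in cols}
        if len(width) != 1:
            raise EstimationError("cannot equate parameters of different structure")
        for row in zip(*cols):
            ties.append(list(row))

    fixed = dict(full._fit.fixed)
    for name, value in fix.items():
        idxs = _constraint_indices(full, name)
        if name.startswith("var_"):
            vals = [np.sqrt(max(value, 0.0))] + [0.0] * (len(idxs) - 1)
        else:
            vals = [value] * len(idxs)
        for i, v in zip(idxs, vals):
            fixed[i] = v

    model = full._fit.model
    bounds = {4: (np.log(1e-5), np.log(1e3))}
    constrained = model.fit(full._fit.theta.copy(), fixed=fixed, ties=ties,
                            bounds=bounds)
    ddf = full.n_free - constrained.n_free
    if ddf <= 0:
        raise EstimationError("constraints do not reduce the free parameter count")
    lrt = max(0.0, 2.0 * (full.loglik - constrained.loglik))
    p = float(stats.chi2.sf(lrt, ddf))
    k_full, k_con = full.n_free, constrained.n_free
    return ModelComparison(
        lrt_stat=float(lrt),
        delta_df=int(ddf),
        p_value=p,
        aic_each={"full": -2 * full.loglik + 2 * k_full,
                  "constrained": -2 * constrained.loglik + 2 * k_con},
        bic_each={
            "full": -2 * full.loglik + np.log(max(full.components.n_pairs, 2)) * k_full,
            "constrained": -2 * constrained.loglik
            + np.log(max(full.components.n_pairs, 2)) * k_con,
        },
        preferred="full" if p < alpha else "constrained",
        labels=("constrained", "full"),
    )
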