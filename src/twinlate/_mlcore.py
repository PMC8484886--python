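"""Batched marginal Gaussian maximum likelihood for clustered designs.

Every latent-growth model in this package has the same marginal form: for
cluster j (a person, or a twin pair with its risk scores appended),

    y_j ~ N( X_j beta,  B_j K_{g(j)} B_j' + sigma^2 D_j + P_j )

where ``B_j`` loads the observed rows on a cluster-level latent vector,
``K_g`` is a small structured covariance shared by all clusters of group g
(e.g. MZ vs DZ), ``D_j`` marks rows carrying level-1 residual variance and
``P_j`` is a fixed unit diagonal on padding rows.  Clusters are padded to a
common row count so likelihoods evaluate as batched linear algebra; padding
rows have zero response, zero design and unit variance, contributing only an
additive constant.

The gradient uses the standard Gaussian score.  With
S_j = Sigma_j^{-1} - Sigma_j^{-1} r_j r_j' Sigma_j^{-1},

    d(-ll)/d(theta) = 1/2 sum_j tr(S_j dSigma_j) - sum_j (dmu_j)' Sigma^{-1} r_j.

For parameters entering only through K this reduces to
1/2 tr(dK_g W_g) with W_g = sum_{j in g} B_j' S_j B_j, so the expensive
per-cluster pass happens once per gradient; dK_g/dtheta is obtained by
central differences on the (cheap, low-degree polynomial) K assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MarginalData:
    """Padded arrays for a set of clusters.

    Y : (P, M) responses, 0 on padding rows
    X : (P, M, p) fixed-effect design
    B : (P, M, L) latent loadings
    obs : (P, M) 1 where sigma^2 applies (observation rows)
    pad : (P, M) 1 on padding rows (fixed unit variance)
    group : (P,) int group label indexing the K list
    extra_diag : optional (P, M) fixed additions to the diagonal
    """

    Y: np.ndarray
    X: np.ndarray
    B: np.ndarray
    obs: np.ndarray
    pad: np.ndarray
    group: np.ndarray
    n_groups: int = 1

    @property
    def n_rows(self) -> int:
        """Number of real (non-padding) rows across clusters."""
        return int((1 - self.pad).sum())


class MarginalModel:
    """Gaussian ML for one :class:`MarginalData` with a structured K.

    Parameters
    ----------
    data : MarginalData
    assemble_K : callable (kparams,) -> list of (L, L) arrays, one per group
    n_kparams : length of the K-parameter block
    """

    #: tiny ridge keeping risk-row variances away from exact singularity
    JITTER = 1e-9

    def __init__(self, data: MarginalData, assemble_K, n_kparams: int, k_grad=None):
        self.d = data
        self.assemble_K = assemble_K
        self.n_k = n_kparams
        #: optional analytic gradient of 1/2 sum_g tr(K_g W_g) w.r.t. kparams;
        #: signature (kp, [W_g]) -> (n_k,).  Falls back to central differences
        #: on the K assembly when absent.
        self.k_grad = k_grad
        self.p = data.X.shape[2]
        self.n_params = self.p + 1 + n_kparams  # beta, log_sigma, kparams

    # -- parameter layout ---------------------------------------------
    def split(self, theta):
        beta = theta[: self.p]
        log_sigma = theta[self.p]
        kp = theta[self.p + 1 :]
        return beta, log_sigma, kp

    # -- core likelihood ----------------------------------------------
    def _sigma_stack(self, kmats, sigma2):
        d = self.d
        P, M, _ = d.B.shape
        Sig = np.empty((P, M, M))
        for g in range(d.n_groups):
            sel = d.group == g
            Bg = d.B[sel]
            Sig[sel] = np.einsum("pmi,ij,pnj->pmn", Bg, kmats[g], Bg, optimize=True)
        diag = sigma2 * d.obs + d.pad + self.JITTER
        Sig[:, np.arange(M), np.arange(M)] += diag
        return Sig

    def nll_grad(self, theta):
        """Negative log-likelihood and its gradient.

        The mean parameters are profiled: given the covariance parameters,
        beta is the exact GLS solution, so ``theta``'s leading block is
        ignored on input and the returned gradient is zero there (envelope
        theorem).  The profiled beta and its GLS covariance are cached on
        the instance for retrieval after fitting.
        """
        d = self.d
        _, log_sigma, kp = self.split(theta)
        sigma2 = np.exp(2.0 * log_sigma)
        kmats = self.assemble_K(kp)
        Sig = self._sigma_stack(kmats, sigma2)

        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return 1e10 + float(np.sum(theta**2)), 2.0 * theta

        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        Sinv = np.linalg.inv(Sig)

        A = np.einsum("pmi,pmn,pnj->ij", d.X, Sinv, d.X, optimize=True)
        b = np.einsum("pmi,pmn,pn->i", d.X, Sinv, d.Y, optimize=True)
        beta = np.linalg.solve(A + 1e-12 * np.eye(self.p), b)
        self._beta = beta
        self._beta_cov = np.linalg.inv(A + 1e-12 * np.eye(self.p))

        r = d.Y - np.einsum("pmi,i->pm", d.X, beta)
        alpha = np.einsum("pmn,pn->pm", Sinv, r)
        quad = float(np.einsum("pm,pm->", r, alpha))
        n_real = d.n_rows
        nll = 0.5 * (logdet + quad + n_real * _LOG2PI)

        # S_j = Sigma^-1 - alpha alpha'
        S = Sinv - np.einsum("pm,pn->pmn", alpha, alpha)

        g_beta = np.zeros(self.p)  # profiled: score is zero at the GLS beta
        diag_S = np.einsum("pmm->pm", S)
        g_logsig = 0.5 * float((diag_S * d.obs).sum()) * 2.0 * sigma2

        # group-wise W = sum B' S B, then chain through the K assembly
        W = [
            np.einsum(
                "pmi,pmn,pnj->ij",
                self.d.B[d.group == g],
                S[d.group == g],
                self.d.B[d.group == g],
                optimize=True,
            )
            for g in range(d.n_groups)
        ]
        if self.k_grad is not None:
            g_k = self.k_grad(kp, W)
        else:
            g_k = np.empty(self.n_k)
            h = 1e-6
            for m in range(self.n_k):
                step = h * max(1.0, abs(kp[m]))
                kp_hi = kp.copy(); kp_hi[m] += step
                kp_lo = kp.copy(); kp_lo[m] -= step
                Khi = self.assemble_K(kp_hi)
                Klo = self.assemble_K(kp_lo)
                acc = 0.0
                for g in range(d.n_groups):
                    dK = (Khi[g] - Klo[g]) / (2.0 * step)
                    acc += float(np.sum(dK * W[g]))
                g_k[m] = 0.5 * acc

        grad = np.concatenate([g_beta, [g_logsig], g_k])
        return nll, grad

    def nll(self, theta):
        return self.nll_grad(theta)[0]

    # -- fitting --------------------------------------------------------
    def fit(self, theta0, fixed=None, ties=None, bounds=None, maxiter=2000):
        """Minimise the negative log-likelihood.

        Parameters
        ----------
        fixed : dict index -> value, parameters frozen at a value (boundary
            refits, fix-to-value constraints).
        ties : list of index groups forced equal (equality constraints);
            each group of k indices removes k-1 free parameters.
        bounds : dict index -> (lo, hi) box bounds on individual parameters.
        """
        theta0 = np.asarray(theta0, dtype=float)
        fixed = dict(fixed or {})
        ties = [list(g) for g in (ties or [])]
        bounds = dict(bounds or {})

        leader = {}
        for grp in ties:
            head = min(grp)
            for i in grp:
                leader[i] = head
        rep = [leader.get(i, i) for i in range(self.n_params)]
        for i, head in leader.items():
            if head in fixed:
                fixed[i] = fixed[head]
        free = np.array(
            sorted(
                {
                    rep[i]
                    for i in range(self.p, self.n_params)  # beta is profiled
                    if rep[i] not in fixed
                }
            )
        )
        pos = {i: a for a, i in enumerate(free)}

        def embed(tf):
            th = np.zeros(self.n_params)
            for i in range(self.p, self.n_params):
                th[i] = fixed[i] if rep[i] in fixed or i in fixed else tf[pos[rep[i]]]
            return th

        def fun(tf):
            nll, grad = self.nll_grad(embed(tf))
            gfree = np.zeros(len(free))
            for i in range(self.n_params):
                if rep[i] in pos and i not in fixed:
                    gfree[pos[rep[i]]] += grad[i]
            return nll, gfree

        box = [bounds.get(i, (None, None)) for i in free]

        def projected_gnorm(tf, grad):
            # ignore gradient components pushing against an active bound
            g = grad.copy()
            for a, (lo, hi) in enumerate(box):
                if lo is not None and tf[a] <= lo + 1e-12 and g[a] > 0:
                    g[a] = 0.0
                if hi is not None and tf[a] >= hi - 1e-12 and g[a] < 0:
                    g[a] = 0.0
            return float(np.max(np.abs(g))) if len(g) else 0.0

        best = None
        start = theta0[free]
        for attempt in range(2):
            res = minimize(
                fun,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=box if bounds else None,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            nll_fit, grad_fit = fun(res.x)
            gnorm = projected_gnorm(res.x, grad_fit)
            if best is None or nll_fit < best[1]:
                best = (res, nll_fit, gnorm)
            if res.success or gnorm < 1e-2:
                break
            # retry once from a mildly perturbed start
            rng = np.random.default_rng(0)
            start = res.x + 0.05 * rng.standard_normal(len(free)) * np.maximum(
                1.0, np.abs(res.x)
            )
            for a, (lo, hi) in enumerate(box):
                if lo is not None:
                    start[a] = max(start[a], lo)
                if hi is not None:
                    start[a] = min(start[a], hi)

        res, nll, gnorm = best
        theta = embed(res.x)
        self.nll_grad(theta)  # refresh the cached profiled beta at the optimum
        theta[: self.p] = self._beta
        converged = bool(res.success or gnorm < 1e-2)
        if not converged and gnorm > 1.0:
            raise ConvergenceError(
                f"optimiser failed (status {res.status}, max|grad| = {gnorm:.3g})"
            )
        n_free = len(free)
        return FitResult(
            theta, -nll, converged, gnorm, free, fixed, self, rep, n_free,
            beta_cov=self._beta_cov.copy(),
        )


@dataclass
class FitResult:
    """An ML solution plus the bookkeeping needed for SEs and refits."""

    theta: np.ndarray
    loglik: float
    converged: bool
    grad_norm: float
    free: np.ndarray
    fixed: dict
    model: MarginalModel
    rep: list = None
    n_free: int = None
    beta_cov: np.ndarray = None  # GLS covariance of the profiled mean params

    def __post_init__(self):
        if self.rep is None:
            self.rep = list(range(self.model.n_params))
        if self.n_free is None:
            self.n_free = len(self.free)

    def _embed(self, tf):
        pos = {i: a for a, i in enumerate(self.free)}
        th = self.theta.copy()  # beta block stays at its profiled value
        for i in range(self.model.p, self.model.n_params):
            r = self.rep[i]
            th[i] = self.fixed[i] if (r in self.fixed or i in self.fixed) else tf[pos[r]]
        return th

    def _free_grad(self, tf):
        _, grad = self.model.nll_grad(self._embed(tf))
        pos = {i: a for a, i in enumerate(self.free)}
        g = np.zeros(len(self.free))
        for i in range(self.model.n_params):
            r = self.rep[i]
            if r in pos and i not in self.fixed:
                g[pos[r]] += grad[i]
        return g

    def hessian(self, h=1e-4):
        """Central-difference Hessian of the negative log-likelihood (free coords)."""
        tf0 = self.theta[self.free]
        H = np.zeros((len(self.free), len(self.free)))
        for a in range(len(self.free)):
            step = h * max(1.0, abs(tf0[a]))
            hi = tf0.copy(); hi[a] += step
            lo = tf0.copy(); lo[a] -= step
            H[a] = (self._free_grad(hi) - self._free_grad(lo)) / (2.0 * step)
        return 0.5 * (H + H.T)

    #: curvature (in nll units) below which a free coordinate is treated as
    #: carrying no information at this solution
    FLAT_TOL = 1e-3

    def flat_coordinates(self):
        """Boolean mask over free coords with (numerically) no curvature.

        A flat coordinate means the likelihood does not respond to that
        parameter at this solution (e.g. a regression on a component whose
        variance collapsed): its Wald machinery is meaningless and the term
        should be treated as unidentified.
        """
        if not hasattr(self, "_H"):
            self._H = self.hessian()
        return np.abs(np.diag(self._H)) < self.FLAT_TOL

    def covariance(self):
        """Asymptotic covariance of the free coordinates (inverse Hessian).

        Flat directions are conditioned out (rows/columns zeroed): they are
        unidentified at this solution and are reported as such by callers,
        rather than being assigned arbitrary huge or tiny variances.
        """
        if not hasattr(self, "_H"):
            self._H = self.hessian()
        H = self._H
        flat = np.abs(np.diag(H)) < self.FLAT_TOL
        keep = ~flat
        cov = np.zeros_like(H)
        if keep.any():
            Hr = H[np.ix_(keep, keep)]
            w, V = np.linalg.eigh(Hr)
            floor = max(1e-10, 1e-10 * float(np.max(np.abs(w))))
            w = np.maximum(w, floor)
            cov[np.ix_(keep, keep)] = (V / w) @ V.T
        return cov


def delta_method(fit: FitResult, transform, h=1e-5, cov_free=None):
    """SEs of ``transform(theta)`` via the delta method.

    ``transform`` maps the full parameter vector to a 1-d array of derived
    quantities (variances, regressions...).  Returns (values, se).
    """
    vals = np.asarray(transform(fit.theta), dtype=float)
    if cov_free is None:
        cov_free = fit.covariance()
    tf0 = fit.theta[fit.free]
    J = np.zeros((len(vals), len(fit.free)))
    for a in range(len(fit.free)):
        step = h * max(1.0, abs(tf0[a]))
        hi = tf0.copy(); hi[a] += step
        lo = tf0.copy(); lo[a] -= step
        J[:, a] = (
            np.asarray(transform(fit._embed(hi)))
            - np.asarray(transform(fit._embed(lo)))
        ) / (2 * step)
    var = np.einsum("ia,ab,ib->i", J, cov_free, J)
    return vals, np.sqrt(np.clip(var, 0.0, None))


def chol_to_cov(l11, l21, l22, l33=None):
    """Covariance block from Cholesky factors: full 2x2 (+ independent quad)."""
    if l33 is None:
        return np.array([[l11**2, l11 * l21], [l11 * l21, l21**2 + l22**2]])
    return np.array(
        [
            [l11**2, l11 * l21, 0.0],
            [l11 * l21, l21**2 + l22**2, 0.0],
            [0.0, 0.0, l33**2],
        ]
    )
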