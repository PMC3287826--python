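"""Zero-inflated Poisson regression with covariate-linked components.

The model: each subject's collapsed rare-variant count T_i is a
structural zero with probability p_i, and otherwise Poisson(mu_i):

    P(T_i = 0) = p_i + (1 - p_i) exp(-mu_i)
    P(T_i = t) = (1 - p_i) exp(-mu_i) mu_i^t / t!,   t >= 1

with canonical links  logit(p_i) = g_i' gamma  and  log(mu_i) = b_i' beta,
where both linear predictors carry the phenotype (or quantitative trait)
and the covariates (age, sex, smoking, ancestry eigenvectors).  The
association test is the Wald test of the phenotype coefficient beta_1 in
the log-mean component; a likelihood-ratio alternative is provided.

The joint likelihood is maximised by quasi-Newton (BFGS) with an
analytic gradient, warm-started from a plain Poisson regression; the
coefficient covariance is the inverse observed information (numerical
Hessian of the log-likelihood at the optimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = ["ZipDesign", "ZipFit", "zip_loglik", "fit_zip", "wald_test",
           "lrt_test", "DegenerateFitError", "OptimizationFailure"]


class DegenerateFitError(RuntimeError):
    """The fit cannot support a test (all-zero counts, singular information)."""


class OptimizationFailure(RuntimeError):
    """The optimizer failed to improve on its nested starting point."""


@dataclass
class ZipDesign:
    """Outcome counts plus design matrices for the two ZIP components.

    Both matrices must include an intercept column and be full column
    rank; constant non-intercept columns are rejected at validation.
    """

    counts: np.ndarray
    X_zero: np.ndarray
    X_mean: np.ndarray
    zero_names: list[str] = field(default_factory=list)
    mean_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0) or np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        self.X_zero = np.atleast_2d(np.asarray(self.X_zero, dtype=float))
        self.X_mean = np.atleast_2d(np.asarray(self.X_mean, dtype=float))
        n = self.counts.shape[0]
        for name, X in (("X_zero", self.X_zero), ("X_mean", self.X_mean)):
            if X.shape[0] != n:
                raise ValueError(f"{name} has {X.shape[0]} rows, expected {n}")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(f"{name} is rank deficient")
        if not self.zero_names:
            self.zero_names = [f"z{k}" for k in range(self.X_zero.shape[1])]
        if not self.mean_names:
            self.mean_names = [f"b{k}" for k in range(self.X_mean.shape[1])]

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_params(self) -> int:
        return self.X_zero.shape[1] + self.X_mean.shape[1]

    def drop_column(self, name: str) -> "ZipDesign":
        """Reduced design with ``name`` removed from both components
        (for likelihood-ratio testing)."""
        kz = [i for i, c in enumerate(self.zero_names) if c != name]
        km = [i for i, c in enumerate(self.mean_names) if c != name]
        return ZipDesign(self.counts, self.X_zero[:, kz], self.X_mean[:, km],
                         [self.zero_names[i] for i in kz],
                         [self.mean_names[i] for i in km])


@dataclass
class ZipFit:
    """Fitted ZIP regression.

    ``fallback`` records how the fit was obtained: "none" is a full ZIP
    fit; "poisson" means the zero-inflation component was dropped (no
    zero counts, or the structural-zero mass collapsed to its boundary)
    and coefficients come from the nested Poisson regression;
    "degenerate" means no test is possible.
    """

    gamma: np.ndarray | None
    beta: np.ndarray | None
    cov: np.ndarray | None        # covariance of (gamma, beta) stacked
    loglik: float
    converged: bool
    fallback: str = "none"
    zero_names: list[str] = field(default_factory=list)
    mean_names: list[str] = field(default_factory=list)
    n_obs: int = 0
    message: str = ""

    def se_beta(self, index: int) -> float:
        """Standard error of beta[index] from the covariance block."""
        if self.cov is None:
            raise DegenerateFitError("no covariance available")
        offset = 0 if self.gamma is None else len(self.gamma)
        return float(np.sqrt(self.cov[offset + index, offset + index]))


def _split(theta: np.ndarray, design: ZipDesign) -> tuple[np.ndarray, np.ndarray]:
    pz = design.X_zero.shape[1]
    return theta[:pz], theta[pz:]


def zip_loglik(gamma: np.ndarray, beta: np.ndarray, design: ZipDesign) -> float:
    """Joint log-likelihood of the ZIP model at (gamma, beta).

    Zero counts use log-sum-exp stabilisation:
    log f(0) = logaddexp(log p, log(1-p) - mu) with
    log p = -softplus(-eta), log(1-p) = -softplus(eta), eta = X_zero gamma.
    """
    gamma = np.asarray(gamma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if gamma.shape[0] != design.X_zero.shape[1]:
        raise ValueError("gamma length does not match zero-component design")
    if beta.shape[0] != design.X_mean.shape[1]:
        raise ValueError("beta length does not match mean-component design")
    eta = design.X_zero @ gamma
    xi = design.X_mean @ beta
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError(
            "non-finite linear predictor in the zero component; "
            "rescale the offending covariate")
    if not np.all(np.isfinite(xi)) or np.any(xi > 700):
        raise FloatingPointError(
            "non-finite linear predictor in the mean component; "
            "rescale the offending covariate")
    T = design.counts
    mu = np.exp(xi)
    log_p = -np.logaddexp(0.0, -eta)      # log sigmoid(eta)
    log_1mp = -np.logaddexp(0.0, eta)     # log sigmoid(-eta)
    zero = T == 0
    ll = np.empty(design.n)
    ll[zero] = np.logaddexp(log_p[zero], log_1mp[zero] - mu[zero])
    nz = ~zero
    ll[nz] = (log_1mp[nz] - mu[nz] + T[nz] * xi[nz]
              - special.gammaln(T[nz] + 1.0))
    return float(ll.sum())


def _negloglik_and_grad(theta: np.ndarray, design: ZipDesign
                        ) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its analytic gradient in (gamma, beta)."""
    gamma, beta = _split(theta, design)
    eta = design.X_zero @ gamma
    xi = design.X_mean @ beta
    if not (np.all(np.isfinite(eta)) and np.all(np.isfinite(xi))) or \
            np.any(xi > 500):
        return np.inf, np.zeros_like(theta)
    T = design.counts
    mu = np.exp(xi)
    p = special.expit(eta)
    log_p = -np.logaddexp(0.0, -eta)
    log_1mp = -np.logaddexp(0.0, eta)
    zero = T == 0

    ll = np.empty(design.n)
    ll[zero] = np.logaddexp(log_p[zero], log_1mp[zero] - mu[zero])
    nz = ~zero
    ll[nz] = log_1mp[nz] - mu[nz] + T[nz] * xi[nz] - special.gammaln(T[nz] + 1.0)

    # d ll / d eta and d ll / d xi per observation.  For zero counts the
    # posterior weight of the structural-zero component is
    # w = p / (p + (1-p) e^{-mu}) = expit(eta + mu), which keeps the
    # ratios finite even when p or e^{-mu} underflow:
    #   d/d eta = w (1-p)(1 - e^{-mu}),   d/d xi = -(1 - w) mu
    d_eta = np.empty(design.n)
    d_xi = np.empty(design.n)
    emu = np.exp(-mu[zero])
    w = special.expit(eta[zero] + mu[zero])
    d_eta[zero] = w * (1.0 - p[zero]) * (1.0 - emu)
    d_xi[zero] = -(1.0 - w) * mu[zero]
    # nonzero observations
    d_eta[nz] = -p[nz]
    d_xi[nz] = T[nz] - mu[nz]

    grad = np.concatenate([design.X_zero.T @ d_eta, design.X_mean.T @ d_xi])
    return -ll.sum(), -grad


def _numerical_hessian(theta: np.ndarray, design: ZipDesign,
                       step: float = 1e-5) -> np.ndarray:
    """Observed information: central finite differences of the analytic
    gradient of the negative log-likelihood."""
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _negloglik_and_grad(tp, design)
        _, gm = _negloglik_and_grad(tm, design)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _fit_poisson(design: ZipDesign) -> tuple[np.ndarray, np.ndarray, float]:
    """Plain Poisson GLM on the mean-component design (warm start / fallback)."""
    import warnings as _w
    model = sm.GLM(design.counts, design.X_mean, family=sm.families.Poisson())
    with _w.catch_warnings():
        # sparse genes routinely separate; the ladder handles the fallout
        _w.simplefilter("ignore")
        res = model.fit()
    return np.asarray(res.params), np.asarray(res.cov_params()), float(res.llf)


def _maximize(design: ZipDesign, beta0: np.ndarray, gtol: float,
              max_restarts: int, seed: int):
    """BFGS maximisation from the Poisson warm start; returns
    (theta, llf, converged, cov-or-None)."""
    T = design.counts
    mu0 = np.exp(design.X_mean @ beta0)
    z_obs = float(np.mean(T == 0))
    z_pois = float(np.mean(np.exp(-mu0)))
    p_start = np.clip((z_obs - z_pois) / max(1.0 - z_pois, 1e-12), 1e-3, 0.999)
    gamma0 = np.zeros(design.X_zero.shape[1])
    gamma0[_intercept_index(design.X_zero)] = special.logit(p_start)
    theta0 = np.concatenate([gamma0, beta0])

    rng = np.random.default_rng(seed)
    best = None
    theta_try = theta0
    for _ in range(max_restarts + 1):
        res = optimize.minimize(_negloglik_and_grad, theta_try, args=(design,),
                                jac=True, method="BFGS",
                                options={"gtol": gtol, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
        if res.success or float(np.max(np.abs(res.jac))) < 1e-5:
            break
        if np.max(np.abs(res.x[: design.X_zero.shape[1]])) > 50.0:
            break  # separation ridge in the zero component; restarts cannot help
        theta_try = theta0 + rng.normal(scale=0.2, size=theta0.size)

    theta = best.x
    llf = -float(best.fun)
    converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-5)
    H = _numerical_hessian(theta, design)
    cov, ok = _safe_inverse(H)
    return theta, llf, converged, (cov if ok else None)


def fit_zip(design: ZipDesign, gtol: float = 1e-8, max_restarts: int = 5,
            seed: int = 0) -> ZipFit:
    """Maximum-likelihood ZIP fit with Poisson warm start and restarts.

    Degenerate and boundary inputs are dispatched down an explicit
    fitting ladder rather than forced through the full mixture:

    1. full ZIP (covariates in both components) — ``fallback = "none"``;
    2. if the zero-component information is singular (quasi-separation,
       common when the counts have no real zero excess), ZIP with an
       intercept-only zero component — ``fallback = "intercept_zero"``;
    3. if the structural-zero mass itself sits at the boundary p = 0,
       the nested Poisson regression — ``fallback = "poisson"`` (also
       used when there are no zero counts at all, where the mixture is
       unidentified);
    4. all-zero counts — ``fallback = "degenerate"``, no test.

    At every rung the reported fit is the maximum-likelihood solution of
    the rung's model, and the Wald test of the mean-component trait
    coefficient remains valid.
    """
    T = design.counts
    if design.n <= design.n_params:
        raise ValueError(
            f"N = {design.n} must exceed the {design.n_params} coefficients")
    if np.all(T == 0):
        return ZipFit(None, None, None, 0.0, False, "degenerate",
                      design.zero_names, design.mean_names, design.n,
                      "all counts zero")

    beta0, pois_cov, pois_llf = _fit_poisson(design)
    pois = ZipFit(None, beta0, pois_cov, pois_llf, True, "poisson",
                  design.zero_names, design.mean_names, design.n,
                  "zero-inflation at boundary; nested Poisson MLE")
    if np.all(T > 0):
        pois.message = "no zero counts; ZIP mixture unidentified"
        return pois

    theta, llf, converged, cov = _maximize(design, beta0, gtol,
                                           max_restarts, seed)
    gamma, beta = _split(theta, design)
    if converged and cov is not None and llf >= pois_llf:
        return ZipFit(gamma, beta, cov, llf, True, "none",
                      design.zero_names, design.mean_names, design.n)

    # rung 2: intercept-only zero component
    i0 = _intercept_index(design.X_zero)
    reduced = ZipDesign(design.counts, design.X_zero[:, [i0]], design.X_mean,
                        [design.zero_names[i0]], list(design.mean_names))
    theta, llf, converged, cov = _maximize(reduced, beta0, gtol,
                                           max_restarts, seed)
    gamma, beta = _split(theta, reduced)
    if converged and cov is not None and llf >= pois_llf:
        return ZipFit(gamma, beta, cov, llf, True, "intercept_zero",
                      reduced.zero_names, reduced.mean_names, design.n,
                      "zero-component covariates dropped (separation)")
    if llf <= pois_llf:
        return pois
    return ZipFit(gamma, beta, cov, llf, converged, "degenerate",
                  reduced.zero_names, reduced.mean_names, design.n,
                  "singular observed information" if cov is None
                  else "optimizer did not converge")


def _intercept_index(X: np.ndarray) -> int:
    const = np.where(np.all(X == X[0], axis=0) & (X[0] != 0))[0]
    return int(const[0]) if const.size else 0


def _safe_inverse(H: np.ndarray) -> tuple[np.ndarray | None, bool]:
    """Invert the observed information; reject non-PD or ill-conditioned H.

    Conditioning is judged on the correlation-scaled matrix so that
    covariate columns of very different scales (age in years next to
    unit-norm eigenvectors) do not masquerade as singularity.
    """
    d = np.sqrt(np.abs(np.diag(H)))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        return None, False
    Hs = H / np.outer(d, d)
    try:
        cond = np.linalg.cond(Hs)
    except np.linalg.LinAlgError:
        return None, False
    if not np.isfinite(cond) or cond > 1e10:
        return None, False
    try:
        L = np.linalg.cholesky(Hs)
    except np.linalg.LinAlgError:
        return None, False
    Linv = np.linalg.solve(L, np.eye(H.shape[0]))
    return (Linv.T @ Linv) / np.outer(d, d), True


def wald_test(fit: ZipFit, coefficient: str | int = 1) -> tuple[float, float]:
    """Wald z test of a mean-component (log mu) coefficient being zero.

    Returns (z, two-sided p).  ``coefficient`` may be an index into beta
    or a name from ``mean_names``.  Under a Poisson fallback the test
    uses the Poisson fit's coefficient and covariance.
    """
    if fit.fallback == "degenerate" or fit.beta is None or fit.cov is None:
        raise DegenerateFitError(f"no test possible: {fit.message}")
    if isinstance(coefficient, str):
        coefficient = fit.mean_names.index(coefficient)
    b = float(fit.beta[coefficient])
    se = fit.se_beta(coefficient)
    if not np.isfinite(se) or se <= 0:
        raise DegenerateFitError("non-positive standard error")
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def lrt_test(full: ZipFit, reduced: ZipFit, tol: float = 1e-6
             ) -> tuple[float, float]:
    """Likelihood-ratio test of the full model against a nested reduction.

    Degrees of freedom come from the difference in coefficient counts
    (2 when the phenotype enters both components).  A full-model
    likelihood below the reduced one beyond tolerance signals an
    optimization failure and triggers a refit upstream.
    """
    for f in (full, reduced):
        if not f.converged or f.fallback == "degenerate":
            raise DegenerateFitError("both fits must have converged")
    df = (_n_coef(full) - _n_coef(reduced))
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -tol:
        raise OptimizationFailure(
            f"full-model log-likelihood {full.loglik:.6f} below reduced "
            f"{reduced.loglik:.6f}")
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 1.0
    return float(stat), float(stats.chi2.sf(stat, df))


def _n_coef(fit: ZipFit) -> int:
    n = 0 if fit.gamma is None else fit.gamma.size
    return n + (0 if fit.beta is None else fit.beta.size)
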