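"""Random-intercept logistic regression via adaptive Gauss-Hermite quadrature.

Fits the two-level model

    y_ij ~ Bernoulli(p_ij),   logit p_ij = x_ij' beta + b_i,
    b_i ~ Normal(0, sigma^2)

by maximum likelihood.  The per-cluster marginal likelihood integral over
the random intercept is evaluated with adaptive Gauss-Hermite quadrature:
the integrand's mode and curvature are located per cluster by Newton steps
(the log-integrand is strictly concave), and the Hermite nodes are centred
and scaled there.  Wald standard errors come from the numerical Hessian of
the log-likelihood at the optimum.

This is the standard frequentist GLMM estimator (the same family of
quadrature-based fitters used by ``lme4::glmer`` and Stata's mixed logit
commands); it is written here because the Python scientific stack ships no
frequentist adaptive-quadrature mixed logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.special import expit, log_expit
from statsmodels.tools.numdiff import approx_hess

__all__ = ["MixedLogitFit", "fit_mixed_logit"]

_SEPARATION_BOUND = 15.0


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails and the fallback also fails."""


@dataclass
class MixedLogitFit:
    """Maximum-likelihood fit of the random-intercept logit."""

    params: np.ndarray  # fixed-effect coefficients (log-odds scale)
    cov: np.ndarray  # covariance of the fixed-effect coefficients
    sigma: float  # random-intercept standard deviation
    loglik: float
    exog_names: list[str]
    quadrature_order: int
    converged: bool
    n_iter: int
    separation: bool = False
    penalized: bool = False
    message: str = ""
    diagnostics: dict = field(default_factory=dict)

    def contrast(self, weights: np.ndarray) -> tuple[float, float]:
        """Estimate and standard error of a linear contrast of coefficients."""
        weights = np.asarray(weights, dtype=float)
        est = float(weights @ self.params)
        se = float(np.sqrt(weights @ self.cov @ weights))
        return est, se


def _cluster_loglik(
    beta: np.ndarray,
    log_sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    weights: np.ndarray,
    ridge: float = 0.0,
) -> float:
    """Marginal log-likelihood, summed over clusters (AGQ)."""
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    var = sigma**2

    # Newton iterations for the per-cluster mode of the log-integrand
    b = np.zeros(n_groups)
    for _ in range(50):
        p = expit(eta0 + b[groups])
        score = np.bincount(groups, weights=y - p, minlength=n_groups) - b / var
        info = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1 / var
        step = score / info
        b += step
        if np.max(np.abs(step)) < 1e-9:
            break
    p = expit(eta0 + b[groups])
    info = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1 / var
    tau = 1.0 / np.sqrt(info)  # curvature scale at the mode

    # evaluate the shifted/scaled quadrature nodes
    log_terms = np.empty((len(nodes), n_groups))
    for k, (x_k, w_k) in enumerate(zip(nodes, weights)):
        bk = b + tau * x_k
        eta = eta0 + bk[groups]
        ll_obs = y * eta + log_expit(-eta)  # y*eta - log(1 + e^eta)
        ll = np.bincount(groups, weights=ll_obs, minlength=n_groups)
        ll += -0.5 * bk**2 / var - 0.5 * np.log(2 * np.pi * var)
        log_terms[k] = np.log(w_k) + ll + 0.5 * x_k**2

    m = log_terms.max(axis=0)
    cluster_ll = m + np.log(np.exp(log_terms - m).sum(axis=0)) + np.log(tau)
    total = float(cluster_ll.sum())
    if ridge:
        total -= ridge * float(beta @ beta)
    return total


def _pooled_loglik(beta: np.ndarray, y: np.ndarray, X: np.ndarray, ridge=0.0) -> float:
    eta = X @ beta
    total = float(np.sum(y * eta + log_expit(-eta)))
    if ridge:
        total -= ridge * float(beta @ beta)
    return total


def fit_mixed_logit(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    exog_names: list[str] | None = None,
    quadrature_order: int = 15,
    var_fixed: float | None = None,
    ridge: float = 0.0,
) -> MixedLogitFit:
    """Fit the random-intercept logit by adaptive Gauss-Hermite quadrature.

    Parameters
    ----------
    y, X, groups
        Binary outcome, fixed-effect design matrix (include the intercept
        column explicitly) and integer cluster labels.
    quadrature_order
        Number of Hermite nodes (default 15).
    var_fixed
        When set, the random-intercept variance is held at this value
        instead of being estimated; ``var_fixed=0`` degenerates to the
        pooled (ordinary) logistic fit.
    ridge
        Optional L2 penalty on the coefficients, used as the documented
        fallback under complete separation.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    k = X.shape[1]
    names = exog_names or [f"x{j}" for j in range(k)]
    # probabilists' Hermite rule; with the curvature scaling, the cluster
    # integral is tau * sum_k w_k exp(g(m + tau x_k) + x_k^2 / 2)
    nodes, weights = hermegauss(quadrature_order)

    pooled_only = var_fixed is not None and var_fixed == 0.0

    def negloglik(theta: np.ndarray) -> float:
        if pooled_only:
            return -_pooled_loglik(theta, y, X, ridge)
        if var_fixed is not None:
            beta, log_sigma = theta, 0.5 * np.log(var_fixed)
        else:
            beta, log_sigma = theta[:k], theta[k]
        return -_cluster_loglik(
            beta, log_sigma, y, X, codes, n_groups, nodes, weights, ridge
        )

    # pooled logistic starting values via a few Newton steps
    beta0 = np.zeros(k)
    for _ in range(25):
        p = expit(X @ beta0)
        grad = X.T @ (y - p) - 2 * ridge * beta0
        hess = (X * (p * (1 - p))[:, None]).T @ X + 2 * ridge * np.eye(k) + 1e-10 * np.eye(k)
        step = np.linalg.solve(hess, grad)
        beta0 += step
        if np.max(np.abs(step)) < 1e-10:
            break

    if pooled_only or (var_fixed is not None):
        x0 = beta0
    else:
        x0 = np.append(beta0, np.log(0.5))

    res = optimize.minimize(
        negloglik, x0, method="BFGS", options={"gtol": 1e-7, "maxiter": 500}
    )
    # BFGS with finite-difference gradients often stops with a "precision
    # loss" status at an excellent optimum; judge convergence by the
    # gradient norm rather than the status flag alone.
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-2
    theta = res.x
    separation = bool(np.max(np.abs(theta[:k])) > _SEPARATION_BOUND)
    penalized = False
    if (not converged or separation) and ridge == 0.0:
        # documented fallback: small L2 penalty stabilizes infinite estimates
        fallback = fit_mixed_logit(
            y,
            X,
            codes,
            exog_names=names,
            quadrature_order=quadrature_order,
            var_fixed=var_fixed,
            ridge=1e-3,
        )
        fallback.separation = separation
        fallback.penalized = True
        fallback.message = (
            "unpenalized fit "
            + ("did not converge" if not converged else "showed separation")
            + "; refit with L2 penalty 1e-3"
        )
        return fallback

    hess = approx_hess(theta, negloglik)
    try:
        cov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(hess)

    if pooled_only:
        sigma = 0.0
    elif var_fixed is not None:
        sigma = float(np.sqrt(var_fixed))
    else:
        sigma = float(np.exp(theta[k]))

    return MixedLogitFit(
        params=theta[:k].copy(),
        cov=cov_all[:k, :k],
        sigma=sigma,
        loglik=-float(res.fun),
        exog_names=list(names),
        quadrature_order=quadrature_order,
        converged=converged,
        n_iter=int(res.nit),
        separation=separation,
        penalized=penalized,
        message=str(res.message),
        diagnostics={"grad_norm": grad_norm},
    )
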