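"""Restricted maximum likelihood for dense-kernel mixed models.

The engine maximizes the restricted log-likelihood

    l_R(theta) = -1/2 [ log|V| + log|Xᵀ V⁻¹ X| + yᵀ P y ] - (q - rank X)/2 log 2π

where ``V(theta)`` is the phenotypic covariance, ``X`` the fixed-effects
design and ``P = V⁻¹ - V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹``. Gradients use the standard
identity dl/dθ = -1/2 [tr(P dV/dθ) - yᵀ P (dV/dθ) P y]; because P and
dV/dθ are symmetric the trace is an elementwise sum, so one Cholesky and
one explicit inverse per iteration dominate the cost (fine for q up to a
few thousand records).

Models plug in through a covariance callback returning ``V`` and the list
of partial derivatives at the current parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize

__all__ = ["RemlOptimum", "reml_loglik_parts", "maximize_reml"]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class RemlOptimum:
    theta: np.ndarray
    loglik: float
    beta: np.ndarray  # GLS fixed-effect estimates at the optimum
    converged: bool
    n_iter: int


def _pinv_logdet(A: np.ndarray):
    """Inverse and log-determinant of a small SPD matrix."""
    c, low = linalg.cho_factor(A, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv = linalg.cho_solve((c, low), np.eye(A.shape[0]))
    return inv, logdet


def _spd_inv_logdet(V: np.ndarray):
    """Explicit inverse + log-determinant of an SPD matrix via potrf/potri."""
    c, info = linalg.lapack.dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv, info = linalg.lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet


def reml_loglik_parts(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Restricted log-likelihood plus the pieces needed for gradients.

    Returns ``(loglik, P, Py, beta)``. Raises ``np.linalg.LinAlgError``
    when V is not positive definite.
    """
    y = np.asarray(y, float).ravel()
    q = y.size
    Vinv, logdet_V = _spd_inv_logdet(V)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    XtVinvX_inv, logdet_X = _pinv_logdet(XtVinvX)
    P = Vinv - VinvX @ XtVinvX_inv @ VinvX.T
    Py = P @ y
    beta = XtVinvX_inv @ (VinvX.T @ y)
    quad = float(y @ Py)
    rank_x = X.shape[1]
    ll = -0.5 * (logdet_V + logdet_X + quad) - 0.5 * (q - rank_x) * LOG2PI
    return ll, P, Py, beta


def _neg_ll_and_grad(theta, y, X, cov_fn):
    V, dVs = cov_fn(np.asarray(theta, float))
    try:
        ll, P, Py, _ = reml_loglik_parts(y, X, V)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(len(theta))
    grad = np.empty(len(dVs))
    for k, dV in enumerate(dVs):
        # tr(P dV) via elementwise sum; both symmetric
        grad[k] = -0.5 * (np.sum(P * dV) - Py @ dV @ Py)
    return -ll, -grad


def maximize_reml(
    y: np.ndarray,
    X: np.ndarray,
    cov_fn: Callable[[np.ndarray], tuple],
    starts: Sequence[np.ndarray],
    bounds: Sequence[tuple] | None = None,
    rel_tol: float = 1e-8,
    max_iter: int = 500,
) -> RemlOptimum:
    """Maximize the restricted log-likelihood with L-BFGS-B.

    Runs the optimizer from every start in ``starts`` and keeps the best
    optimum; a start whose objective is not finite is skipped.
    """
    y = np.asarray(y, float).ravel()
    best = None
    for theta0 in starts:
        theta0 = np.asarray(theta0, float)
        f0, _ = _neg_ll_and_grad(theta0, y, X, cov_fn)
        if not np.isfinite(f0):
            continue
        res = optimize.minimize(
            _neg_ll_and_grad,
            theta0,
            args=(y, X, cov_fn),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": rel_tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise np.linalg.LinAlgError("restricted likelihood undefined at every start")
    theta = np.asarray(best.x, float)
    V, _ = cov_fn(theta)
    ll, _, _, beta = reml_loglik_parts(y, X, V)
    converged = bool(best.success) or best.status == 1  # status 1: iteration cap
    return RemlOptimum(
        theta=theta,
        loglik=float(ll),
        beta=np.asarray(beta, float),
        converged=bool(best.success),
        n_iter=int(best.nit),
    )
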