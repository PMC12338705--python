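"""REML estimation and BLUP prediction for the kernel (RKHS) mixed models.

Four nested models share one machinery, differing only in which kernels
enter the phenotypic covariance of the q records:

* ``G-BLUP``    y = mu + a + e_res,           cov(a)  = Z G Zᵀ sigma2_a
* ``E-BLUP``    y = mu + e + e_res,           cov(e)  = E sigma2_e
* ``GE-BLUP``   y = mu + a + e + e_res
* ``GxE-BLUP``  y = mu + a + e + ae + e_res,  cov(ae) = (Z G Zᵀ ∘ E) sigma2_ae

All are fitted by REML with an intercept-only fixed part. Variance
components are optimized on the log scale (L-BFGS-B with analytic
gradients, three deterministic restarts); models with a single kernel take
an eigen-rotated fast path where every likelihood evaluation is O(q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kernels import KernelSet
from .reml import LOG2PI, RemlOptimum, maximize_reml, reml_loglik_parts, _spd_inv_logdet

__all__ = [
    "MODEL_KERNELS",
    "ModelSpec",
    "FitResult",
    "VariancePartition",
    "restricted_loglik",
    "fit_reml",
    "blup_predict",
    "partition_variance",
]

#: kernels entering each model, in a fixed order
MODEL_KERNELS = {
    "G-BLUP": ("ZGZt",),
    "E-BLUP": ("E",),
    "GE-BLUP": ("ZGZt", "E"),
    "GxE-BLUP": ("ZGZt", "E", "GxE"),
}

#: variances below this fraction of the total are snapped to exactly zero
BOUNDARY_SNAP = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Which kernels a model uses; see :data:`MODEL_KERNELS`."""

    name: str

    def __post_init__(self):
        if self.name not in MODEL_KERNELS:
            raise ValueError(f"unknown model {self.name!r}; expected one of {list(MODEL_KERNELS)}")

    @property
    def kernel_names(self) -> tuple:
        return MODEL_KERNELS[self.name]


@dataclass
class FitResult:
    """One fitted RKHS model: intercept, variances, BLUPs, likelihood."""

    model: str
    mu: float
    var_components: dict  # kernel name -> sigma^2, plus "residual"
    blups: dict  # kernel name -> per-training-record BLUP
    loglik: float
    converged: bool
    kernel_names: tuple = ()
    _y_train: np.ndarray = field(default=None, repr=False)

    @property
    def resid_var(self) -> float:
        return self.var_components["residual"]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "mu": self.mu,
            "var_components": dict(self.var_components),
            "loglik": self.loglik,
            "converged": self.converged,
        }

    def by_kernel(self, kernels_full: KernelSet, name: str) -> np.ndarray:
        return kernels_full.by_name(name)


@dataclass
class VariancePartition:
    """Proportion of phenotypic variance explained per component."""

    pve: dict  # component name -> fraction, residual included

    def __post_init__(self):
        total = sum(self.pve.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"PVE must sum to 1, got {total}")


def _build_v(kernels, variances, resid_var, q):
    V = resid_var * np.eye(q)
    for K, s2 in zip(kernels, variances):
        V += s2 * K
    return V


def restricted_loglik(y, kernels, variances, resid_var) -> float:
    """Restricted log-likelihood of an intercept-only kernel mixed model.

    ``l_R = -1/2 [log|V| + log(1ᵀV⁻¹1) + yᵀPy] - (q-1)/2 log 2π`` with
    ``V = sum_k sigma2_k K_k + sigma2_eps I``.
    """
    y = np.asarray(y, float).ravel()
    q = y.size
    V = _build_v(kernels, variances, float(resid_var), q)
    X = np.ones((q, 1))
    ll, _, _, _ = reml_loglik_parts(y, X, V)
    return float(ll)


def _starts(n_kernels: int, vary: float) -> list:
    """Deterministic restart points: equal split, residual- and kernel-dominant."""
    k = n_kernels
    out = [np.full(k + 1, vary / (k + 1))]
    out.append(np.array([0.1 * vary / k] * k + [0.9 * vary]))
    out.append(np.array([0.9 * vary / k] * k + [0.1 * vary]))
    return [np.log(s) for s in out]


def _fit_single_kernel(y, K, vary, rel_tol=1e-8):
    """Eigen-rotated REML for one kernel + residual: O(q) per evaluation."""
    q = y.size
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(q)

    def nll_grad(theta):
        s2k, s2e = np.exp(theta)
        d = s2k * w + s2e
        if d.min() <= 0:
            return np.inf, np.zeros(2)
        invd = 1.0 / d
        sxx = np.sum(xt**2 * invd)
        sxy = np.sum(xt * yt * invd)
        syy = np.sum(yt**2 * invd)
        quad = syy - sxy**2 / sxx
        ll = -0.5 * (np.sum(np.log(d)) + np.log(sxx) + quad) - 0.5 * (q - 1) * LOG2PI
        # P y and diag-wise traces in the eigenbasis
        Py = yt * invd - (sxy / sxx) * xt * invd
        grad = np.empty(2)
        for j, dv in enumerate((w, np.ones(q))):
            tr = np.sum(dv * invd) - np.sum(xt**2 * dv * invd**2) / sxx
            grad[j] = -0.5 * (tr - np.sum(Py**2 * dv))
        sc = np.array([s2k, s2e])
        return -ll, -grad * sc  # chain rule to log scale

    from scipy import optimize

    lb, ub = np.log(BOUNDARY_SNAP * vary), np.log(1e4 * vary)
    best = None
    for theta0 in _starts(1, vary):
        res = optimize.minimize(
            nll_grad, theta0, jac=True, method="L-BFGS-B",
            bounds=[(lb, ub)] * 2, options={"ftol": rel_tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    s2k, s2e = np.exp(best.x)
    d = s2k * w + s2e
    invd = 1.0 / d
    sxx = np.sum(xt**2 * invd)
    mu = np.sum(xt * yt * invd) / sxx
    return RemlOptimum(
        theta=np.log([s2k, s2e]), loglik=-best.fun, beta=np.array([mu]),
        converged=bool(best.success), n_iter=int(best.nit),
    )


def fit_reml(y_train, kernels_train, spec: ModelSpec, rel_tol: float = 1e-8) -> FitResult:
    """Fit one RKHS model on training records by REML.

    ``kernels_train`` is the ordered list of training-subset kernels
    matching ``spec.kernel_names``. Variances are maximized over the
    non-negative orthant; the lower bound on the log scale lets a
    component hit an effective zero, which is then snapped to exactly 0.
    """
    y = np.asarray(y_train, float).ravel()
    q = y.size
    if q < 2:
        raise ValueError("need at least 2 training records")
    kernels = [np.asarray(K, float) for K in kernels_train]
    if len(kernels) != len(spec.kernel_names):
        raise ValueError(f"{spec.name} expects kernels {spec.kernel_names}")
    for K in kernels:
        if K.shape != (q, q):
            raise ValueError("kernel not conformable with y_train")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("training phenotype is constant; variance components undefined")

    if len(kernels) == 1:
        opt = _fit_single_kernel(y, kernels[0], vary, rel_tol)
    else:
        X = np.ones((q, 1))

        def cov_fn(theta):
            s2 = np.exp(theta)
            V = _build_v(kernels, s2[:-1], s2[-1], q)
            dVs = [s2[k] * kernels[k] for k in range(len(kernels))]
            dVs.append(s2[-1] * np.eye(q))
            return V, dVs

        lb, ub = np.log(BOUNDARY_SNAP * vary), np.log(1e4 * vary)
        opt = maximize_reml(
            y, X, cov_fn, starts=_starts(len(kernels), vary),
            bounds=[(lb, ub)] * (len(kernels) + 1), rel_tol=rel_tol,
        )
    if not opt.converged:
        warnings.warn(f"REML for {spec.name} did not converge", stacklevel=2)

    s2 = np.exp(opt.theta)
    total = s2.sum()
    # Boundary refinement: the optimizer can stall on the flat shoulder of a
    # component whose optimum is zero, leaving numerical dust. If removing a
    # near-boundary kernel variance costs no restricted likelihood within the
    # convergence tolerance, it belongs at exactly zero (the residual is
    # never zeroed).
    loglik = opt.loglik
    for k in range(len(kernels)):
        if 0.0 < s2[k] < 1e-5 * total:
            trial = s2.copy()
            trial[k] = 0.0
            ll0 = restricted_loglik(y, kernels, trial[:-1], trial[-1])
            if ll0 >= loglik - 1e-6 * max(1.0, abs(loglik)):
                s2, loglik = trial, max(ll0, loglik)
    s2 = np.where(s2 < BOUNDARY_SNAP * 10 * total, 0.0, s2)
    var_components = dict(zip(spec.kernel_names, s2[:-1]))
    var_components["residual"] = float(s2[-1])

    # intercept at the final variance components (residual floored so V
    # stays invertible when the optimum sits on the residual boundary)
    V = _build_v(kernels, s2[:-1], max(s2[-1], 1e-10 * total), q)
    _, _, _, beta = reml_loglik_parts(y, np.ones((q, 1)), V)
    mu = float(beta[0])
    blups = _blup_components(y, kernels, spec.kernel_names, var_components, mu)
    return FitResult(
        model=spec.name, mu=mu, var_components=var_components, blups=blups,
        loglik=float(loglik), converged=opt.converged,
        kernel_names=spec.kernel_names, _y_train=y,
    )


def _v_inv_resid(y, kernels, kernel_names, var_components, mu):
    q = y.size
    V = _build_v(kernels, [var_components[n] for n in kernel_names],
                 max(var_components["residual"], 1e-12), q)
    Vinv, _ = _spd_inv_logdet(V)
    return Vinv @ (y - mu)


def _blup_components(y, kernels, kernel_names, var_components, mu):
    r = _v_inv_resid(y, kernels, kernel_names, var_components, mu)
    return {n: var_components[n] * (K @ r) for n, K in zip(kernel_names, kernels)}


def blup_predict(fit: FitResult, kernels_full: KernelSet, train_idx, test_idx) -> np.ndarray:
    """Predict phenotypes of held-out records from a trained fit.

    Extends each random effect to all records via
    ``u_k = sigma2_k K_k[:, train] V_train⁻¹ (y_train - mu)`` and returns
    ``mu + sum_k u_k`` at the test records.
    """
    train_idx = np.asarray(train_idx, int)
    test_idx = np.asarray(test_idx, int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("test indices overlap the training indices")
    kernels_tr = [fit.by_kernel(kernels_full, n)[np.ix_(train_idx, train_idx)]
                  for n in fit.kernel_names]
    r = _v_inv_resid(fit._y_train, kernels_tr, fit.kernel_names, fit.var_components, fit.mu)
    yhat = np.full(test_idx.size, fit.mu)
    for n in fit.kernel_names:
        K_cross = fit.by_kernel(kernels_full, n)[np.ix_(test_idx, train_idx)]
        yhat += fit.var_components[n] * (K_cross @ r)
    return yhat


def partition_variance(fit: FitResult) -> VariancePartition:
    """Proportion of variance explained per component, residual included."""
    if not fit.converged:
        warnings.warn("partitioning variance from a non-converged fit", stacklevel=2)
    vals = np.array(list(fit.var_components.values()), float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("all variance components are zero")
    return VariancePartition(pve={k: v / total for k, v in fit.var_components.items()})
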