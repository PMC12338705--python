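"""Reaction-norm random-regression model (RRM) on Legendre polynomials.

Each line's lifespan is modelled as a polynomial function of a scalar
environmental value x in [-1, 1]:

    y_ij = sum_t beta_t P_t(x_j) + sum_t a_it P_t(x_j) + eps_ij

with fixed coefficients beta, random line coefficients a_i whose
vectorized covariance is ``G ⊗ Sigma_a``, and a separate residual
variance per environment. The environmental value of environment j is the
mean phenotype across training lines in that environment, mapped to
[-1, 1] by min-max over the training environments. The default order is
T = 1 (intercept and slope), i.e. a linear reaction norm.

The covariance of the q records has the Hadamard form
``V = (Phi Sigma_a Phiᵀ) ∘ Z G Zᵀ + D`` (D diagonal per environment),
which is maximized by REML over a log-Cholesky parameterization of
Sigma_a and the log residual variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reml import maximize_reml, reml_loglik_parts
from .kernels import build_env_design

__all__ = ["EnvValueMap", "RRMFit", "legendre_basis", "env_values",
           "extrapolate_env_values", "fit_rrm", "predict_rrm"]


def legendre_basis(x: float, T: int) -> np.ndarray:
    """Values (P_0(x), ..., P_T(x)) of the plain Legendre polynomials.

    Uses the Bonnet recurrence (t+1) P_{t+1} = (2t+1) x P_t - t P_{t-1}.
    """
    if T < 0:
        raise ValueError("order T must be >= 0")
    x = float(x)
    if abs(x) > 1 + 1e-9:
        raise ValueError(f"environmental value {x} outside [-1, 1]")
    x = min(max(x, -1.0), 1.0)
    out = np.empty(T + 1)
    out[0] = 1.0
    if T >= 1:
        out[1] = x
    for t in range(1, T):
        out[t + 1] = ((2 * t + 1) * x * out[t] - t * out[t - 1]) / (t + 1)
    return out


@dataclass
class EnvValueMap:
    """Per-environment raw mean phenotypes and their [-1, 1] mapping."""

    raw_means: dict  # env id -> training mean phenotype (days)
    m_min: float
    m_max: float
    x: dict = field(default_factory=dict)  # env id -> standardized value

    def __post_init__(self):
        if not self.x:
            self.x = {e: self.map(m) for e, m in self.raw_means.items()}

    def map(self, raw_mean: float, clip: bool = False) -> float:
        v = 2.0 * (raw_mean - self.m_min) / (self.m_max - self.m_min) - 1.0
        return min(max(v, -1.0), 1.0) if clip else v

    def add(self, env_id, raw_mean: float) -> None:
        """Register an extrapolated environment, clipping into [-1, 1]."""
        self.raw_means[env_id] = raw_mean
        self.x[env_id] = self.map(raw_mean, clip=True)


def _env_label(df: pd.DataFrame) -> pd.Series:
    t = pd.to_numeric(df["temperature"]).astype(float)
    return df["sex"].astype(str) + "_" + t.map(lambda v: f"{v:g}")


def env_values(pheno_train: pd.DataFrame) -> EnvValueMap:
    """Environmental values from training data only.

    The raw value of an environment is its mean phenotype over training
    records; values are mapped to [-1, 1] by min-max over the training
    environments. Location shifts of the phenotype cancel out.
    """
    means = pheno_train.groupby(_env_label(pheno_train))["lifespan"].mean()
    m_min, m_max = float(means.min()), float(means.max())
    if m_max == m_min:
        raise ValueError("all environments share one mean phenotype; environmental gradient degenerate")
    return EnvValueMap(raw_means=means.to_dict(), m_min=m_min, m_max=m_max)


def extrapolate_env_values(env_map: EnvValueMap, design) -> None:
    """Fill unmapped environments by regressing training means on covariates.

    Ordinary least squares of the training environments' raw means on
    [1, standardized sex, standardized temperature] predicts the raw mean
    of an unseen environment, which is then min-max-mapped with the
    training bounds and clipped to [-1, 1]. This keeps the test
    environment's phenotypes out of the mapping (no leakage).
    """
    missing = [e for e in design.env_ids if e not in env_map.x]
    if not missing:
        return
    known = [e for e in design.env_ids if e in env_map.raw_means]
    pos = {e: i for i, e in enumerate(design.env_ids)}
    Xk = np.column_stack([np.ones(len(known)), design.covariates[[pos[e] for e in known]]])
    mk = np.array([env_map.raw_means[e] for e in known])
    coef, *_ = np.linalg.lstsq(Xk, mk, rcond=None)
    for e in missing:
        xrow = np.concatenate([[1.0], design.covariates[pos[e]]])
        env_map.add(e, float(xrow @ coef))


@dataclass
class RRMFit:
    """Fitted reaction-norm model."""

    beta: np.ndarray  # (T+1,) fixed Legendre coefficients
    Sigma_a: np.ndarray  # (T+1, T+1) genetic covariance of random coefficients
    resid_vars: dict  # env id -> residual variance
    coef_blups: np.ndarray  # (n, T+1) predicted random coefficients
    env_map: EnvValueMap
    line_ids: np.ndarray
    loglik: float
    converged: bool
    T: int = 1

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "Sigma_a": self.Sigma_a.tolist(),
            "resid_vars": dict(self.resid_vars),
            "env_values": dict(self.env_map.x),
            "loglik": self.loglik,
            "converged": self.converged,
        }


def _chol_expand(theta_L: np.ndarray, m: int):
    """Lower-triangular L from log-Cholesky parameters (log diagonal)."""
    L = np.zeros((m, m))
    idx = 0
    for i in range(m):
        for j in range(i + 1):
            L[i, j] = np.exp(theta_L[idx]) if i == j else theta_L[idx]
            idx += 1
    return L


def _chol_grads(L: np.ndarray):
    """d(L Lᵀ)/d(theta_p) for each log-Cholesky parameter, in order."""
    m = L.shape[0]
    grads = []
    for i in range(m):
        for j in range(i + 1):
            Eij = np.zeros((m, m))
            Eij[i, j] = L[i, j] if i == j else 1.0  # chain rule for log diagonal
            grads.append(Eij @ L.T + L @ Eij.T)
    return grads


def fit_rrm(pheno_train: pd.DataFrame, G: np.ndarray, line_ids, T: int = 1,
            env_map: EnvValueMap | None = None, rel_tol: float = 1e-8) -> RRMFit:
    """REML fit of the random-regression model on training records.

    ``G`` is the genomic relationship matrix over ``line_ids`` (all lines,
    trained or not; only rows with training records enter the fit).
    ``env_map`` defaults to :func:`env_values` of the training table.
    """
    df = pheno_train.reset_index(drop=True)
    if df.groupby([_env_label(df), df["line"]]).size().max() > 1:
        raise ValueError("more than one record per line and environment")
    line_ids = np.asarray(line_ids, dtype=object)
    if env_map is None:
        env_map = env_values(df)
    env = _env_label(df)
    envs_train = list(dict.fromkeys(env))
    if len(envs_train) < 2:
        raise ValueError("need at least 2 environments to fit a reaction norm")
    y = df["lifespan"].to_numpy(float)
    q = y.size
    m = T + 1

    Phi = np.vstack([legendre_basis(env_map.x[e], T) for e in env])
    pos = {l: i for i, l in enumerate(line_ids)}
    rows = df["line"].map(pos).to_numpy()
    ZGZt = G[np.ix_(rows, rows)]
    env_masks = [(env == e).to_numpy().astype(float) for e in envs_train]

    vary = float(np.var(y, ddof=1))
    n_chol = m * (m + 1) // 2

    def cov_fn(theta):
        L = _chol_expand(theta[:n_chol], m)
        Sa = L @ L.T
        s2 = np.exp(theta[n_chol:])
        D = np.zeros(q)
        for j, mask in enumerate(env_masks):
            D += s2[j] * mask
        V = (Phi @ Sa @ Phi.T) * ZGZt + np.diag(D)
        dVs = [(Phi @ dSa @ Phi.T) * ZGZt for dSa in _chol_grads(L)]
        for j, mask in enumerate(env_masks):
            dVs.append(np.diag(s2[j] * mask))
        return V, dVs

    # starts: balanced, residual-dominant, genetic-dominant
    starts = []
    for g_frac, r_frac in ((0.5, 0.5), (0.1, 0.9), (0.9, 0.1)):
        thL = np.zeros(n_chol)
        idx = 0
        for i in range(m):
            for j in range(i + 1):
                if i == j:
                    thL[idx] = 0.5 * np.log(g_frac * vary / (2.0 * m))
                idx += 1
        starts.append(np.concatenate([thL, np.full(len(envs_train), np.log(r_frac * vary))]))

    lb_r = np.log(1e-8 * vary)
    bounds = [(0.5 * np.log(1e-12 * vary), 0.5 * np.log(1e6 * vary)) if i == j else (None, None)
              for i in range(m) for j in range(i + 1)]
    bounds += [(lb_r, np.log(1e4 * vary))] * len(envs_train)

    opt = maximize_reml(y, Phi, cov_fn, starts=starts, bounds=bounds, rel_tol=rel_tol)
    if not opt.converged:
        warnings.warn("RRM REML did not converge", stacklevel=2)

    L = _chol_expand(opt.theta[:n_chol], m)
    Sa = L @ L.T
    s2 = np.exp(opt.theta[n_chol:])
    V, _ = cov_fn(opt.theta)
    _, _, Py, beta = reml_loglik_parts(y, Phi, V)
    # coefficient BLUPs: u = (G ⊗ Sigma_a) "cross-cov" V⁻¹ (y - Phi beta);
    # P y equals V⁻¹(y - Phi beta) at the GLS beta
    S = Phi @ Sa  # (q, m): Sigma_a phi_m per record
    Mmat = np.zeros((len(line_ids), m))
    np.add.at(Mmat, rows, Py[:, None] * S)
    coef_blups = G @ Mmat

    return RRMFit(
        beta=np.asarray(beta, float),
        Sigma_a=Sa,
        resid_vars={e: float(v) for e, v in zip(envs_train, s2)},
        coef_blups=coef_blups,
        env_map=env_map,
        line_ids=line_ids,
        loglik=opt.loglik,
        converged=opt.converged,
        T=T,
    )


def predict_rrm(fit: RRMFit, targets, G_full: np.ndarray = None, line_ids_full=None) -> np.ndarray:
    """Predict (line, environment) cells from a fitted reaction norm.

    ``y_hat = sum_t (beta_t + a_it) P_t(x_j)``. Lines without fitted
    coefficients get them from the genomic conditional expectation
    ``G[new, old] G[old, old]⁻¹ a_hat`` (requires ``G_full``). An
    environment with no mapped value raises; extrapolate first with
    :func:`extrapolate_env_values`.
    """
    fit_pos = {l: i for i, l in enumerate(fit.line_ids)}
    coefs = {}
    new_lines = list(dict.fromkeys(l for l, _ in targets if l not in fit_pos))
    if new_lines:
        if G_full is None or line_ids_full is None:
            raise ValueError("new lines need G_full and line_ids_full")
        full_pos = {l: i for i, l in enumerate(line_ids_full)}
        old_rows = [full_pos[l] for l in fit.line_ids]
        new_rows = [full_pos[l] for l in new_lines]
        G_oo = G_full[np.ix_(old_rows, old_rows)]
        ridge = 1e-8 * np.trace(G_oo) / G_oo.shape[0]
        ext = G_full[np.ix_(new_rows, old_rows)] @ np.linalg.solve(
            G_oo + ridge * np.eye(G_oo.shape[0]), fit.coef_blups
        )
        coefs = {l: ext[k] for k, l in enumerate(new_lines)}

    out = np.empty(len(targets))
    for k, (line, env) in enumerate(targets):
        if env not in fit.env_map.x:
            raise KeyError(f"environment {env!r} has no environmental value; extrapolate first")
        phi = legendre_basis(fit.env_map.x[env], fit.T)
        a = fit.coef_blups[fit_pos[line]] if line in fit_pos else coefs[line]
        out[k] = phi @ (fit.beta + a)
    return out
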