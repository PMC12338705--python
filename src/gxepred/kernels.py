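"""Covariance kernels for multi-environment genomic prediction.

Builds every covariance structure shared by the RKHS mixed models:

* variant filtering (MAF / missingness) and mean imputation,
* the VanRaden genomic relationship matrix ``G`` among inbred lines,
* the environmental design (sex, temperature covariates) and the
  environmental similarity kernel ``E ∝ X Xᵀ``,
* the record-level expansion ``Z G Zᵀ`` and the Hadamard interaction
  kernel ``Z G Zᵀ ∘ E`` that carries gene-environment interaction.

Lines are assumed fully inbred (allele dosages in {0, 2}); heterozygous
dosages are accepted with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "EnvironmentDesign",
    "KernelSet",
    "filter_variants",
    "compute_grm",
    "build_env_design",
    "compute_env_kernel",
    "expand_and_interact",
    "check_psd",
]

#: relative eigenvalue below which a kernel is considered indefinite
PSD_RTOL = 1e-8
#: relative eigenvalue down to which negative eigenvalues are clipped
PSD_REPAIR_RTOL = 1e-6


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix for a panel of inbred lines.

    Parameters
    ----------
    line_ids : array-like of str
        Ordered identifiers of the ``n`` lines; must be unique.
    dosages : ndarray, shape (n, p)
        Counted-allele dosages in ``[0, 2]``; ``NaN`` marks missing calls.
    variant_ids : array-like of str
        Ordered identifiers of the ``p`` variants.
    """

    line_ids: np.ndarray
    dosages: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (lines x variants) array")
        n, p = self.dosages.shape
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} dosage rows")
        if len(self.variant_ids) != p:
            raise ValueError(f"{len(self.variant_ids)} variant ids for {p} dosage columns")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosage values outside [0, 2]")
        if vals.size and np.any((vals != 0) & (vals != 2)):
            warnings.warn(
                "heterozygous dosages present; lines are expected to be fully inbred",
                stacklevel=2,
            )

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.variant_ids)


@dataclass
class EnvironmentDesign:
    """Discrete environments (sex x temperature cells) and their covariates.

    ``covariates`` holds one row per distinct environment with columns
    ``[sex code, temperature]`` standardized to zero mean and unit variance
    over the q records. ``record_index`` maps each record to its
    ``(line, environment)`` pair.
    """

    env_ids: list
    covariates: np.ndarray  # (r, c), standardized
    record_index: pd.DataFrame  # columns: line, env

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def n_records(self) -> int:
        return len(self.record_index)

    def record_covariates(self) -> np.ndarray:
        """Expand the per-environment covariates to the q records (X_q)."""
        pos = {e: i for i, e in enumerate(self.env_ids)}
        rows = self.record_index["env"].map(pos).to_numpy()
        return self.covariates[rows]

    def incidence(self, line_ids) -> np.ndarray:
        """q x n incidence matrix Z mapping records to lines."""
        pos = {l: i for i, l in enumerate(line_ids)}
        Z = np.zeros((self.n_records, len(line_ids)))
        for row, line in enumerate(self.record_index["line"]):
            try:
                Z[row, pos[line]] = 1.0
            except KeyError:
                raise KeyError(f"record line {line!r} not among the genotyped lines")
        return Z


@dataclass
class KernelSet:
    """The q x q covariance kernels shared by the RKHS models."""

    G: np.ndarray
    Z: np.ndarray
    ZGZt: np.ndarray
    E: np.ndarray
    GxE: np.ndarray
    line_ids: np.ndarray = field(default=None)

    def by_name(self, name: str) -> np.ndarray:
        try:
            return {"ZGZt": self.ZGZt, "E": self.E, "GxE": self.GxE}[name]
        except KeyError:
            raise KeyError(f"unknown kernel {name!r}; expected ZGZt, E or GxE")


def _maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant: min(p, 1-p), p = mean dosage / 2."""
    p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_variants(
    geno: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.2
) -> GenotypeMatrix:
    """Drop variants by MAF and missing rate; impute the rest to the variant mean.

    Keeps exactly the variants with MAF >= ``maf_min`` and missing-call rate
    <= ``miss_max``, then replaces the remaining missing dosages by the
    variant mean. Line order is preserved; the operation is idempotent.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if not 0 <= miss_max <= 1:
        raise ValueError("miss_max must be in [0, 1]")
    X = geno.dosages
    miss_rate = np.isnan(X).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        maf = _maf(X)
    keep = (np.nan_to_num(maf, nan=-1.0) >= maf_min) & (miss_rate <= miss_max)
    if not keep.any():
        raise ValueError("empty genotype matrix: no variant passed the filters")
    Xk = X[:, keep].copy()
    col_mean = np.nanmean(Xk, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(Xk))
    Xk[nan_r, nan_c] = col_mean[nan_c]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # re-validation of inherited heterozygotes
        return GenotypeMatrix(geno.line_ids, Xk, geno.variant_ids[keep])


def compute_grm(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    ``G = W Wᵀ / (2 Σⱼ pⱼ(1 − pⱼ))`` with ``pⱼ`` the counted-allele
    frequency of variant ``j`` and ``W`` the column-centered dosages.
    For fully inbred lines (dosages in {0, 2}) the diagonal averages ≈ 2.
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; run filter_variants first")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all variants are monomorphic; GRM undefined")
    W = X - 2.0 * p
    G = W @ W.T / denom
    return (G + G.T) / 2.0


def build_env_design(records) -> EnvironmentDesign:
    """Construct the environmental design from (line, sex, temperature) records.

    Sex is coded 0/1, temperature kept in °C; both columns are then
    standardized to mean 0, variance 1 across the q records. Environments
    are the distinct sex x temperature cells, labelled ``"{sex}_{temp}"``.
    """
    df = pd.DataFrame(list(records), columns=["line", "sex", "temperature"])
    if df.empty:
        raise ValueError("no records")
    sexes = sorted(df["sex"].astype(str).unique())
    if len(sexes) > 2:
        raise ValueError(f"expected at most 2 sex levels, got {sexes}")
    sex_code = df["sex"].astype(str).map({s: float(i) for i, s in enumerate(sexes)})
    temp = pd.to_numeric(df["temperature"]).astype(float)

    env_label = df["sex"].astype(str) + "_" + temp.map(lambda t: f"{t:g}")
    env_ids = list(dict.fromkeys(env_label))  # first-appearance order

    X_rec = np.column_stack([sex_code.to_numpy(), temp.to_numpy()])
    mu = X_rec.mean(axis=0)
    sd = X_rec.std(axis=0)
    if np.any(sd == 0):
        bad = ["sex", "temperature"][int(np.argmin(sd))]
        raise ValueError(f"covariate {bad!r} has zero variance across records")
    X_std = (X_rec - mu) / sd

    # one covariate row per environment (identical within an environment)
    first = {e: i for i, e in reversed(list(enumerate(env_label)))}
    cov = np.array([X_std[first[e]] for e in env_ids])

    record_index = pd.DataFrame({"line": df["line"], "env": env_label})
    return EnvironmentDesign(env_ids=env_ids, covariates=cov, record_index=record_index)


def compute_env_kernel(design: EnvironmentDesign) -> np.ndarray:
    """Environmental similarity kernel ``E = X_q X_qᵀ / c`` at record level.

    Dividing by the number of covariates c makes the diagonal average ≈ 1;
    the proportionality constant is otherwise absorbed by the variance
    component. Records sharing an environment get identical rows.
    """
    Xq = design.record_covariates()
    c = Xq.shape[1]
    E = Xq @ Xq.T / c
    return (E + E.T) / 2.0


def check_psd(K: np.ndarray, name: str = "kernel", repair: bool = True) -> np.ndarray:
    """Verify symmetry and positive semidefiniteness; optionally repair.

    Negative eigenvalues within ``PSD_REPAIR_RTOL`` of the largest one are
    clipped to zero; anything more negative raises.
    """
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    top = max(w.max(), 0.0)
    if w.min() >= -PSD_RTOL * max(top, 1.0):
        return K
    if repair and w.min() >= -PSD_REPAIR_RTOL * max(top, 1.0):
        w = np.clip(w, 0.0, None)
        return (U * w) @ U.T
    raise ValueError(f"{name} is not positive semidefinite (min eigenvalue {w.min():.3e})")


def expand_and_interact(G: np.ndarray, Z: np.ndarray, E: np.ndarray) -> KernelSet:
    """Expand G to record level and form the Hadamard interaction kernel.

    ``ZGZt = Z G Zᵀ`` and ``GxE = ZGZt ∘ E``; the latter is PSD whenever
    both factors are (Schur product theorem).
    """
    q, n = Z.shape
    if G.shape != (n, n):
        raise ValueError(f"G is {G.shape}, expected ({n}, {n}) for Z {Z.shape}")
    if E.shape != (q, q):
        raise ValueError(f"E is {E.shape}, expected ({q}, {q}) for Z {Z.shape}")
    if not np.all((Z == 0) | (Z == 1)) or not np.all(Z.sum(axis=1) == 1):
        raise ValueError("Z must be a 0/1 incidence matrix with one 1 per row")
    ZGZt = Z @ G @ Z.T
    ZGZt = (ZGZt + ZGZt.T) / 2.0
    GxE = ZGZt * E
    return KernelSet(G=G, Z=Z, ZGZt=ZGZt, E=(E + E.T) / 2.0, GxE=(GxE + GxE.T) / 2.0)


def build_kernel_set(geno: GenotypeMatrix, design: EnvironmentDesign) -> KernelSet:
    """GRM + environment kernel + incidence -> full KernelSet.

    The GRM is rescaled to unit mean diagonal before expansion (VanRaden's
    matrix has diagonal ≈ 2 for fully inbred lines). With E likewise on a
    unit-diagonal scale, every kernel contributes variance on the
    phenotypic scale, so variance-component ratios read directly as
    proportions of variance explained; the rescaling is absorbed by the
    corresponding variance component and changes no likelihood optimum.
    """
    G = compute_grm(geno)
    G = G / np.mean(np.diag(G))
    Z = design.incidence(geno.line_ids)
    E = compute_env_kernel(design)
    ks = expand_and_interact(G, Z, E)
    ks.line_ids = geno.line_ids
    return ks
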