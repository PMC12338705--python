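"""Synthetic DGRP-like genotypes and multi-environment lifespan phenotypes.

Emulates a panel of fully inbred fly lines measured once per line in each
of 6 environments (2 sexes x 3 rearing temperatures), with phenotypes
drawn from the additive + environment + interaction + residual
decomposition

    y = mu + a + e + ae + eps,
    a ~ N(0, ZGZᵀ), e = X_q gamma, ae ~ N(0, ZGZᵀ ∘ E), eps ~ N(0, I).

Each component vector is rescaled so its realized variance equals the
requested fraction of the total phenotypic variance exactly; the default
fractions (0.12, 0.72, 0.08, 0.08) match the variance partition estimated
for lifespan in the real panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (
    EnvironmentDesign,
    GenotypeMatrix,
    KernelSet,
    build_env_design,
    build_kernel_set,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_genotypes",
           "simulate_phenotypes", "simulate_dataset"]


@dataclass
class SimulationConfig:
    """Design of one synthetic dataset.

    Defaults mirror the real study design: 176 inbred lines, 6
    environments from {F, M} x {18, 25, 28} °C, one record per line and
    environment, and variance fractions (genetic, environment, G×E,
    residual) = (0.12, 0.72, 0.08, 0.08). ``total_variance`` is in days²
    and ``mu`` in days.
    """

    n_lines: int = 176
    n_variants: int = 3000
    maf_range: tuple = (0.05, 0.5)
    sexes: tuple = ("F", "M")
    temperatures: tuple = (18.0, 25.0, 28.0)
    pve_targets: tuple = (0.12, 0.72, 0.08, 0.08)
    total_variance: float = 1.0
    mu: float = 50.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        t = np.asarray(self.pve_targets, float)
        if t.min() < 0 or abs(t.sum() - 1.0) > 1e-9:
            raise ValueError("pve_targets must be nonnegative and sum to 1")

    @property
    def n_envs(self) -> int:
        return len(self.sexes) * len(self.temperatures)


@dataclass
class SimulationTruth:
    """The drawn component vectors and their realized variance fractions."""

    components: dict  # name -> q-vector for a, e, ae, residual
    realized_pve: dict
    kernels: KernelSet = field(repr=False, default=None)
    design: EnvironmentDesign = field(repr=False, default=None)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Biallelic dosages for fully inbred lines, independent variants.

    Per variant a frequency is drawn uniformly from ``maf_range`` and each
    line carries dosage 2 with that probability, else 0. Monomorphic
    variants are redrawn so the GRM denominator is always positive.
    """
    if config.n_variants < 50:
        raise ValueError("need >= 50 variants for a stable GRM")
    rng = np.random.default_rng(config.seed)
    n, p = config.n_lines, config.n_variants
    maf = rng.uniform(*config.maf_range, size=p)
    X = 2.0 * (rng.random((n, p)) < maf)
    # redraw monomorphic columns (finite-sample fixation)
    for _ in range(100):
        mono = (X.min(axis=0) == X.max(axis=0))
        if not mono.any():
            break
        k = int(mono.sum())
        maf_new = rng.uniform(*config.maf_range, size=k)
        X[:, mono] = 2.0 * (rng.random((n, k)) < maf_new)
    else:
        raise RuntimeError("could not draw polymorphic variants; enlarge n_lines")
    line_ids = np.array([f"line_{i:04d}" for i in range(n)], dtype=object)
    variant_ids = np.array([f"snp_{j:06d}" for j in range(p)], dtype=object)
    return GenotypeMatrix(line_ids, X, variant_ids)


def _scaled(vec: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale so the sample variance (ddof=1) equals target_var exactly."""
    if target_var == 0:
        return np.zeros_like(vec)
    v = np.var(vec, ddof=1)
    if v <= 0:
        raise ValueError("component realization has zero variance; cannot hit a positive target")
    return vec * np.sqrt(target_var / v)


def _draw_mvn(rng, K, size=None):
    """Sample N(0, K) through the eigendecomposition (K may be singular)."""
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(K.shape[0])
    return U @ (np.sqrt(w) * z)


def simulate_phenotypes(geno: GenotypeMatrix, config: SimulationConfig):
    """Draw lifespan records under the additive + environment + G×E model.

    Returns ``(records DataFrame, SimulationTruth)``. The DataFrame has
    columns (line, sex, temperature, lifespan), one row per line and
    environment. Each variance component is empirically rescaled so the
    realized fractions equal ``pve_targets`` exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    recs = [(l, s, t) for l in geno.line_ids for s in config.sexes for t in config.temperatures]
    design = build_env_design(recs)
    ks = build_kernel_set(geno, design)
    q = design.n_records
    tv = config.total_variance
    tg, te, tae, tr = config.pve_targets

    a = _scaled(_draw_mvn(rng, ks.ZGZt), tg * tv) if tg > 0 else np.zeros(q)
    if tg > 0 and np.abs(ks.ZGZt).max() < 1e-12:
        raise ValueError("genetic target > 0 but the genomic kernel is numerically zero")
    gamma = rng.standard_normal(design.covariates.shape[1])
    e = design.record_covariates() @ gamma
    e = _scaled(e, te * tv) if te > 0 else np.zeros(q)
    ae = _scaled(_draw_mvn(rng, ks.GxE), tae * tv) if tae > 0 else np.zeros(q)
    eps = _scaled(rng.standard_normal(q), tr * tv) if tr > 0 else np.zeros(q)

    y = config.mu + a + e + ae + eps
    table = pd.DataFrame(recs, columns=["line", "sex", "temperature"])
    table["lifespan"] = y

    comp = {"genetic": a, "environment": e, "gxe": ae, "residual": eps}
    realized = {k: float(np.var(v, ddof=1)) / tv for k, v in comp.items()}
    truth = SimulationTruth(components=comp, realized_pve=realized, kernels=ks, design=design)
    return table, truth


def simulate_dataset(config: SimulationConfig):
    """Genotypes + phenotypes + truth in one call."""
    geno = simulate_genotypes(config)
    pheno, truth = simulate_phenotypes(geno, config)
    return geno, pheno, truth
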