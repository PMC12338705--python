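"""Cross-validation schemes and accuracy for multi-environment prediction.

Three schemes probe different training/test relationships:

* ``RandomLines`` — a random 17% of the lines, with all their records,
  form the test set: the genotype is never seen in training (the
  human-cohort situation).
* ``RandomObservations`` — a random 17% of the line x environment records
  form the test set: every line and every environment is seen in
  training, only the specific combinations are not (the agricultural
  situation).
* ``NewEnvironment`` — all records of one sex/temperature cell form the
  test set, one fold per environment: the environment is never seen in
  training.

Accuracy is the R² from regressing true phenotypes on predictions,
i.e. the squared Pearson correlation, averaged over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import GenotypeMatrix, build_env_design, build_kernel_set
from .mixedmodel import MODEL_KERNELS, ModelSpec, blup_predict, fit_reml
from .mtm import ChainConfig, fit_mtm_gibbs, predict_mtm
from .rrm import env_values, extrapolate_env_values, fit_rrm, predict_rrm, _env_label

__all__ = ["SCHEMES", "PhenotypeTable", "Fold", "CVResult", "make_folds",
           "accuracy_r2", "run_cv"]

SCHEMES = ("RandomLines", "RandomObservations", "NewEnvironment")
ALL_MODELS = tuple(MODEL_KERNELS) + ("mvG-BLUP", "RRM")


@dataclass
class PhenotypeTable:
    """Long-format records (line, sex, temperature, lifespan in days)."""

    df: pd.DataFrame

    def __post_init__(self):
        need = {"line", "sex", "temperature", "lifespan"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(need)}")
        self.df = self.df.reset_index(drop=True)
        y = pd.to_numeric(self.df["lifespan"])
        if not np.isfinite(y).all():
            raise ValueError("lifespan contains non-finite values")
        dup = self.df.assign(_env=_env_label(self.df)).duplicated(["line", "_env"])
        if dup.any():
            raise ValueError("more than one record per line and environment")

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def env_labels(self) -> pd.Series:
        return _env_label(self.df)

    @property
    def lines(self) -> np.ndarray:
        return self.df["line"].unique()


@dataclass
class Fold:
    """One train/test split of the record indices."""

    scheme: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    replicate: int
    seed: int
    env: str | None = None  # the held-out environment (NewEnvironment only)

    def __post_init__(self):
        tr, te = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")
        if not te:
            raise ValueError("empty test set")
        if not tr:
            raise ValueError("empty training set")


@dataclass
class CVResult:
    """Per-replicate and mean accuracy of one model under one scheme."""

    scheme: str
    model: str
    per_replicate_r2: list
    mean_r2: float = None
    per_environment_r2: dict | None = None

    def __post_init__(self):
        if self.mean_r2 is None:
            self.mean_r2 = float(np.mean(self.per_replicate_r2))

    def to_frame(self) -> pd.DataFrame:
        envs = (list(self.per_environment_r2) if self.per_environment_r2
                else [None] * len(self.per_replicate_r2))
        return pd.DataFrame({
            "scheme": self.scheme, "model": self.model,
            "replicate": np.arange(1, len(self.per_replicate_r2) + 1),
            "environment": envs, "r2": self.per_replicate_r2,
        })


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_folds(pheno: PhenotypeTable, scheme: str, fraction: float = 0.17,
               n_replicates: int = 6, seed: int = 0) -> list:
    """Build the train/test splits of one CV scheme.

    RandomLines and RandomObservations draw independently per replicate
    with seeds ``seed+1 .. seed+n_replicates``; NewEnvironment is
    deterministic with exactly one fold per environment.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    q = pheno.n_records
    all_idx = np.arange(q)
    folds = []
    if scheme == "NewEnvironment":
        env = pheno.env_labels
        env_ids = list(dict.fromkeys(env))
        if n_replicates != len(env_ids):
            raise ValueError(
                f"NewEnvironment has one fold per environment: n_replicates must be {len(env_ids)}"
            )
        for rep, e in enumerate(env_ids, start=1):
            test = all_idx[(env == e).to_numpy()]
            folds.append(Fold(scheme, np.setdiff1d(all_idx, test), test, rep, seed, env=e))
        return folds

    lines = pheno.lines
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(seed + rep)
        if scheme == "RandomLines":
            k = _round_half_up(fraction * len(lines))
            test_lines = set(rng.choice(lines, size=k, replace=False).tolist())
            test = all_idx[pheno.df["line"].isin(test_lines).to_numpy()]
        else:  # RandomObservations
            k = _round_half_up(fraction * q)
            test = np.sort(rng.choice(all_idx, size=k, replace=False))
        folds.append(Fold(scheme, np.setdiff1d(all_idx, test), test, rep, seed))
    return folds


def accuracy_r2(y_true, y_pred) -> float:
    """R² of the regression of true on predicted phenotypes.

    Equals the squared Pearson correlation; a constant prediction vector
    is scored 0 with a warning so a degenerate model cannot abort a sweep.
    """
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_true.size < 3:
        raise ValueError("need at least 3 pairs")
    # constant to machine precision counts as constant
    if (np.std(y_pred) <= 1e-12 * max(np.abs(y_pred).max(), 1.0)
            or np.std(y_true) <= 1e-12 * max(np.abs(y_true).max(), 1.0)):
        warnings.warn("constant predictions; accuracy defined as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(y_true, y_pred)[0, 1]
    return float(r**2)


def _fit_predict_rkhs(model, y, kernels, fold):
    spec = ModelSpec(model)
    tr = fold.train_idx
    ks_train = [kernels.by_name(n)[np.ix_(tr, tr)] for n in spec.kernel_names]
    fit = fit_reml(y[tr], ks_train, spec)
    return blup_predict(fit, kernels, tr, fold.test_idx)


def _fit_predict_mtm(pheno, geno, G, fold, chain):
    df = pheno.df
    env = pheno.env_labels
    env_ids = list(dict.fromkeys(env))
    lines = list(geno.line_ids)
    lpos = {l: i for i, l in enumerate(lines)}
    epos = {e: j for j, e in enumerate(env_ids)}
    Y = np.full((len(lines), len(env_ids)), np.nan)
    rows = df["line"].map(lpos).to_numpy()
    cols = env.map(epos).to_numpy()
    Y[rows, cols] = df["lifespan"].to_numpy(float)
    Y[rows[fold.test_idx], cols[fold.test_idx]] = np.nan  # hide test cells

    keep = ~np.isnan(Y).all(axis=1)  # lines with no training record drop out
    fit = fit_mtm_gibbs(
        Y[keep], G[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))],
        chain=chain, line_ids=np.asarray(lines, object)[keep], trait_names=env_ids,
    )
    cells = [(df["line"].iloc[i], env.iloc[i]) for i in fold.test_idx]
    return predict_mtm(fit, cells, G, line_ids_full=lines)


def _fit_predict_rrm(pheno, geno, G, fold, T, leak_env_mean):
    df = pheno.df
    train_df = df.iloc[fold.train_idx]
    env_map = env_values(train_df)
    env = pheno.env_labels
    missing = set(env.iloc[fold.test_idx]) - set(env_map.x)
    if missing:
        if leak_env_mean:
            test_df = df.iloc[fold.test_idx]
            for e, m in test_df.groupby(_env_label(test_df))["lifespan"].mean().items():
                if e in missing:
                    env_map.add(e, float(m))
        else:
            design = build_env_design(
                df[["line", "sex", "temperature"]].itertuples(index=False, name=None)
            )
            extrapolate_env_values(env_map, design)
    fit = fit_rrm(train_df, G, geno.line_ids, T=T, env_map=env_map)
    targets = [(df["line"].iloc[i], env.iloc[i]) for i in fold.test_idx]
    return predict_rrm(fit, targets, G_full=G, line_ids_full=geno.line_ids)


def run_cv(
    pheno,
    geno: GenotypeMatrix,
    models,
    scheme: str,
    fraction: float = 0.17,
    n_replicates: int = 6,
    seed: int = 0,
    chain: ChainConfig | None = None,
    rrm_order: int = 1,
    leak_env_mean: bool = False,
) -> list:
    """Run one CV scheme for a list of models and score each replicate.

    Kernels are built once from the full record structure (genotypes and
    the sex/temperature design carry no phenotype information); every
    phenotype-derived quantity — variance components, intercepts,
    environmental values — is estimated from training records only.
    mvG-BLUP cannot be fitted under NewEnvironment (no estimate of the
    unseen environment's intercept or covariances) and raises.
    """
    if isinstance(pheno, pd.DataFrame):
        pheno = PhenotypeTable(pheno)
    models = [models] if isinstance(models, str) else list(models)
    for m in models:
        if m not in ALL_MODELS:
            raise ValueError(f"unknown model {m!r}; expected one of {ALL_MODELS}")
        if m == "mvG-BLUP" and scheme == "NewEnvironment":
            raise ValueError(
                "mvG-BLUP cannot be fitted in the NewEnvironment scheme: the held-out "
                "environment has no intercept, genetic or residual (co)variance estimates"
            )
    chain = chain or ChainConfig()
    df = pheno.df
    design = build_env_design(df[["line", "sex", "temperature"]].itertuples(index=False, name=None))
    kernels = build_kernel_set(geno, design)
    y = df["lifespan"].to_numpy(float)
    folds = make_folds(pheno, scheme, fraction, n_replicates, seed)

    results = []
    for model in models:
        r2s, env_r2 = [], {}
        for fold in folds:
            if model in MODEL_KERNELS:
                yhat = _fit_predict_rkhs(model, y, kernels, fold)
            elif model == "mvG-BLUP":
                chain_f = ChainConfig(chain.iterations, chain.burn_in, chain.thin,
                                      seed=chain.seed + fold.replicate)
                yhat = _fit_predict_mtm(pheno, geno, kernels.G, fold, chain_f)
            else:
                yhat = _fit_predict_rrm(pheno, geno, kernels.G, fold, rrm_order, leak_env_mean)
            r2 = accuracy_r2(y[fold.test_idx], yhat)
            r2s.append(r2)
            if fold.env is not None:
                env_r2[fold.env] = r2
        results.append(CVResult(scheme=scheme, model=model, per_replicate_r2=r2s,
                                per_environment_r2=env_r2 or None))
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Tidy CSV-ready table: scheme, model, replicate, environment, r2."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
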