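"""Readers and writers for genotype, phenotype and result files.

Genotypes come either as CSV (rows = lines, first column the line id,
header = variant ids) or as the text PLINK ``.raw`` dialect
(``FID IID PAT MAT SEX PHENOTYPE`` followed by one dosage column per
variant). Phenotypes are long-format CSV with columns line, sex,
temperature, lifespan; lines missing any sex/temperature cell are dropped
so the retained table is balanced (complete cases by line).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernels import GenotypeMatrix
from .rrm import _env_label

__all__ = ["read_genotypes", "write_genotypes", "read_phenotypes",
           "write_phenotypes", "load_config", "write_manifest"]

PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _validate_dosages(vals: pd.DataFrame, path) -> np.ndarray:
    X = vals.apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad_nonnum = vals.notna().to_numpy() & np.isnan(X)
    if bad_nonnum.any():
        i, j = np.argwhere(bad_nonnum)[0]
        raise ValueError(
            f"{path}: non-numeric dosage at line {vals.index[i]!r}, variant {vals.columns[j]!r}"
        )
    out_of_range = ~np.isnan(X) & ((X < 0) | (X > 2))
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"{path}: dosage {X[i, j]} outside [0, 2] at line {vals.index[i]!r}, "
            f"variant {vals.columns[j]!r}"
        )
    return X


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read a line x variant dosage file (CSV or PLINK .raw text dialect).

    ``format='auto'`` sniffs the header: a leading ``FID IID`` pair means
    PLINK .raw, otherwise CSV. Missing dosages are NA; values outside
    [0, 2], non-numeric cells and duplicate line ids are rejected.
    """
    path = Path(path)
    if format == "auto":
        with open(path) as fh:
            head = fh.readline()
        format = "plink_raw" if head.split()[:2] == ["FID", "IID"] else "csv"
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        missing_meta = [c for c in PLINK_META_COLS if c not in df.columns[:6].tolist()]
        if missing_meta:
            raise ValueError(f"{path}: malformed PLINK .raw header, missing {missing_meta}")
        line_ids = df["IID"].astype(str)
        vals = df.drop(columns=PLINK_META_COLS)
    elif format == "csv":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        line_ids = pd.Series(df.index.astype(str))
        vals = df
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if line_ids.duplicated().any():
        dup = line_ids[line_ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate line id {dup!r}")
    vals.index = line_ids
    X = _validate_dosages(vals, path)
    return GenotypeMatrix(line_ids.to_numpy(object), X, vals.columns.to_numpy(object))


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    """Write the CSV dialect (rows = lines, header = variant ids, NA missing)."""
    geno.to_frame().to_csv(path, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    """Read the long-format phenotype CSV and drop incomplete lines.

    A line missing any of the observed sex/temperature cells is removed
    entirely, so every retained line has one record per environment.
    """
    df = pd.read_csv(path)
    need = {"line", "sex", "temperature", "lifespan"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: phenotype file needs columns {sorted(need)}")
    df = df.dropna(subset=["lifespan"])
    env = _env_label(df)
    if df.assign(_env=env).duplicated(["line", "_env"]).any():
        raise ValueError(f"{path}: duplicate line x environment rows")
    n_env = env.nunique()
    counts = df.groupby("line", sort=False)["lifespan"].size()
    complete = counts[counts == n_env].index
    return df[df["line"].isin(complete)].reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration (flat or nested key-value)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg.setdefault("seed", 1)
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs=()) -> Path:
    """Record everything needed to reproduce a run: config, seed, version, input digests."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "gxepred",
        "version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
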