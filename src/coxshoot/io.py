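"""Delimited-text I/O: survival tables, expression matrices, coefficient files.

TSV vs CSV is auto-detected from the file extension (.tsv/.txt -> tab,
anything else -> comma).  Coefficient files are two-column (feature, value)
with full float precision and exact zeros preserved, so selection metrics
can be recomputed downstream without thresholds.  Every CLI run writes a
JSON metadata record next to its outputs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .survival_core import SurvivalDataset


def _sep(path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def read_survival_table(path) -> SurvivalDataset:
    """Parse a delimited table with 'time' and 'status' columns; remaining
    numeric columns become covariates in file order."""
    df = pd.read_csv(path, sep=_sep(path))
    for col in ("time", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if df.isna().any().any():
        bad = df.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(f"{path}: missing value at row {row}, column '{col}'")
    bad_status = ~df["status"].isin((0, 1))
    if bad_status.any():
        row = int(np.flatnonzero(bad_status)[0])
        raise ValueError(
            f"{path}: status must be 0/1; offending value "
            f"{df['status'].iloc[row]!r} at row {row}")
    cov_cols = [c for c in df.columns if c not in ("time", "status")]
    for c in cov_cols:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"{path}: covariate column '{c}' is not numeric")
    return SurvivalDataset(
        df["time"].to_numpy(dtype=np.float64),
        df["status"].to_numpy(),
        df[cov_cols].to_numpy(dtype=np.float64),
        feature_names=cov_cols,
    )


def write_survival_table(data: SurvivalDataset, path) -> None:
    data.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_expression_matrix(path, clinical_path) -> SurvivalDataset:
    """Join a features x samples expression matrix to a clinical table.

    The expression file's first column holds feature ids and its header the
    sample ids; the clinical table needs columns sample, time, status.
    Clinical rows without expression data are dropped with a warning; the
    output preserves the clinical table's sample order.
    """
    expr = pd.read_csv(path, sep=_sep(path), index_col=0)
    clin = pd.read_csv(clinical_path, sep=_sep(clinical_path))
    for col in ("sample", "time", "status"):
        if col not in clin.columns:
            raise ValueError(f"{clinical_path}: missing required column '{col}'")
    if expr.columns.duplicated().any():
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id '{dup}'")
    if clin["sample"].duplicated().any():
        dup = clin["sample"][clin["sample"].duplicated()].iloc[0]
        raise ValueError(f"{clinical_path}: duplicate sample id '{dup}'")
    samples = clin["sample"].astype(str)
    available = set(map(str, expr.columns))
    missing = [s for s in samples if s not in available]
    if missing:
        warnings.warn(
            f"{len(missing)} clinical sample(s) missing from the expression "
            f"matrix and dropped: {missing[:5]}")
        clin = clin[samples.isin(available)].reset_index(drop=True)
        samples = clin["sample"].astype(str)
    X = expr[list(samples)].to_numpy(dtype=np.float64).T
    return SurvivalDataset(
        clin["time"].to_numpy(dtype=np.float64),
        clin["status"].to_numpy(),
        X,
        feature_names=[str(f) for f in expr.index],
    )


def write_coefficients(path, beta, feature_names=None) -> None:
    beta = np.asarray(beta, dtype=np.float64)
    names = feature_names or [f"x{j + 1}" for j in range(beta.shape[0])]
    with open(path, "w") as fh:
        fh.write("feature\tcoefficient\n")
        for name, value in zip(names, beta):
            fh.write(f"{name}\t{float(value)!r}\n")


def read_coefficients(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return list(df["feature"].astype(str)), df["coefficient"].to_numpy(dtype=np.float64)


def write_metadata(path, record: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=_default)
        fh.write("\n")
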