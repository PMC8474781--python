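"""Reference-based leukocyte deconvolution (constrained projection).

Whole-blood methylation is modeled as a proportion-weighted mixture of
purified cell-type methylomes at a panel of discriminating CpGs. The
reference is built from purified samples by ranking CpGs on a two-sample
t-statistic (one type against all others) and keeping the strongest hyper-
and hypomethylated markers per type. Proportions are estimated per sample
by non-negative least squares with an optional sum constraint:

    minimize ||b - R w||^2   s.t.  w >= 0  and  sum(w) = 1  (default)
                                             or sum(w) <= 1

The equality constraint is enforced through an augmented penalty row
(weight 1e4) on top of the active-set NNLS solver; the inequality mode
adds a non-negative slack component instead.

Count-style surrogate estimates (naive/exhausted T-cell subsets,
plasmablasts) are plain linear predictors ``intercept + sum w_j beta_j``
with user-supplied coefficient files; they are flagged as surrogates
because the published coefficients belong to their source publications.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .exceptions import (
    CoverageError,
    DataError,
    DegenerateDataError,
    FormatError,
)
from .io import BetaMatrix

SUM_PENALTY = 1e4


@dataclass
class CellReference:
    """Cell-type mean methylomes at discriminating CpGs.

    ``mean_betas`` is CpG x cell type; ``lineages`` optionally maps each
    cell type to 'myeloid' or 'lymphoid'.
    """

    mean_betas: pd.DataFrame
    lineages: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mean_betas.shape[1] < 2:
            raise DataError("reference needs >= 2 cell types")
        vals = self.mean_betas.to_numpy(dtype=float)
        if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
            raise FormatError("reference betas outside [0,1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_betas.columns)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.mean_betas.index)


def build_reference(
    purified: BetaMatrix,
    sheet: pd.DataFrame,
    n_per_type: int = 50,
    cell_types: list[str] | None = None,
) -> CellReference:
    """Select discriminating CpGs and average purified profiles per type.

    For each cell type the CpGs are ranked by the two-sample t-statistic
    of that type's samples against all other purified samples; the
    ``n_per_type`` most hypermethylated and ``n_per_type`` most
    hypomethylated markers enter the panel. Reference values are the
    per-type arithmetic means over the union panel.
    """
    if "cell_type_label" not in sheet.columns:
        raise DataError("sheet lacks 'cell_type_label'")
    labels = sheet.set_index(sheet["sample_id"].astype(str))["cell_type_label"]
    labels = labels.reindex(purified.sample_ids)
    if cell_types is None:
        cell_types = [c for c in labels.dropna().unique()]
    counts = labels.value_counts()
    for ct in cell_types:
        if counts.get(ct, 0) < 2:
            raise DataError(
                f"cell type {ct!r} has {counts.get(ct, 0)} purified "
                "sample(s); >= 2 required"
            )
    X = purified.values.to_numpy(dtype=float)
    chosen: set[str] = set()
    index = purified.values.index
    for ct in cell_types:
        in_mask = (labels == ct).to_numpy()
        out_mask = labels.isin(cell_types).to_numpy() & ~in_mask
        a, b = X[:, in_mask], X[:, out_mask]
        na, nb = a.shape[1], b.shape[1]
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=1) - b.mean(axis=1)) / se
        t = np.where(np.isfinite(t), t, 0.0)
        order = np.argsort(t)
        chosen.update(index[order[-n_per_type:]])  # hyper in this type
        chosen.update(index[order[:n_per_type]])  # hypo in this type
    panel = [c for c in index if c in chosen]
    means = {}
    for ct in cell_types:
        in_mask = (labels == ct).to_numpy()
        means[ct] = purified.values.loc[panel].to_numpy(dtype=float)[
            :, in_mask
        ].mean(axis=1)
    ref = pd.DataFrame(means, index=panel)
    lineages = None
    if "lineage" in sheet.columns:
        lineages = (
            sheet.dropna(subset=["cell_type_label"])
            .drop_duplicates("cell_type_label")
            .set_index("cell_type_label")["lineage"]
            .to_dict()
        )
        lineages = {k: v for k, v in lineages.items() if k in cell_types}
    return CellReference(mean_betas=ref, lineages=lineages)


def _project_simplex(b: np.ndarray, R: np.ndarray, mode: str) -> tuple[np.ndarray, float]:
    """One-sample constrained projection; returns (weights, residual norm)."""
    k = R.shape[1]
    if mode == "sum-to-one":
        A = np.vstack([R, SUM_PENALTY * np.ones((1, k))])
        y = np.concatenate([b, [SUM_PENALTY]])
        w, _ = nnls(A, y)
    elif mode == "sum-le-one":
        # slack component absorbs 1 - sum(w); zero signal rows
        A = np.vstack(
            [np.hstack([R, np.zeros((R.shape[0], 1))]),
             SUM_PENALTY * np.ones((1, k + 1))]
        )
        y = np.concatenate([b, [SUM_PENALTY]])
        w_full, _ = nnls(A, y)
        w = w_full[:k]
    else:
        raise DataError(f"unknown constraint mode {mode!r}")
    resid = float(np.linalg.norm(b - R @ w))
    return w, resid


def estimate_proportions(
    beta: BetaMatrix,
    reference: CellReference,
    mode: str = "sum-to-one",
) -> pd.DataFrame:
    """Estimate cell-type proportions for every sample in ``beta``.

    Returns a DataFrame indexed by sample with one column per cell type
    plus ``fit_residual_norm``. Missing betas are mean-imputed per CpG
    before projection. Requires at least 10 shared CpGs per cell type and
    a full-rank reference at the shared CpGs.
    """
    shared = [c for c in reference.cpg_ids if c in beta.values.index]
    k = len(reference.cell_types)
    if len(shared) < 10 * k:
        raise CoverageError(
            f"only {len(shared)} reference CpGs shared; need >= {10 * k}"
        )
    R = reference.mean_betas.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < k:
        raise DegenerateDataError(
            "reference rank-deficient at shared CpGs; cell types not "
            "identifiable"
        )
    B = beta.values.loc[shared]
    if B.isna().any().any():
        B = B.apply(lambda r: r.fillna(r.mean()), axis=1)
    B = B.to_numpy(dtype=float)
    rows = []
    for j in range(B.shape[1]):
        w, resid = _project_simplex(B[:, j], R, mode)
        rows.append(np.concatenate([w, [resid]]))
    out = pd.DataFrame(
        rows,
        index=beta.values.columns,
        columns=list(reference.cell_types) + ["fit_residual_norm"],
    )
    out.index.name = "sample_id"
    return out


def read_reference(path: str | Path) -> CellReference:
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t", index_col=0)
    df.index.name = None
    return CellReference(mean_betas=df.astype(float))


def write_reference(reference: CellReference, path: str | Path) -> None:
    df = reference.mean_betas.copy()
    df.index.name = "cpg_id"
    df.to_csv(path, sep="," if str(path).endswith(".csv") else "\t")


def read_count_predictors(path: str | Path) -> pd.DataFrame:
    """Coefficient table for count surrogates: rows = 'intercept' + CpGs,
    one column per target population."""
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t", index_col=0)
    df.index.name = None
    if "intercept" not in df.index:
        raise FormatError(f"{path}: predictor file lacks an 'intercept' row")
    return df.astype(float)


def write_count_predictors(pred: pd.DataFrame, path: str | Path) -> None:
    df = pred.copy()
    df.index.name = "cpg_id"
    df.to_csv(path, sep="," if str(path).endswith(".csv") else "\t")


def estimate_extended_counts(
    beta: BetaMatrix,
    predictors: pd.DataFrame,
    max_missing: float = 0.2,
) -> pd.DataFrame:
    """Linear-predictor surrogate counts: intercept + sum w_j beta_j.

    ``predictors`` holds one column per target population with an
    'intercept' row plus CpG weights. More than ``max_missing`` of a
    population's CpGs absent from the matrix raises CoverageError.
    Outputs carry ``attrs['surrogate'] = True``.
    """
    cpg_rows = [r for r in predictors.index if r != "intercept"]
    out = {}
    for pop in predictors.columns:
        weights = predictors.loc[cpg_rows, pop]
        weights = weights[weights.notna() & (weights != 0.0)]
        present = [c for c in weights.index if c in beta.values.index]
        if len(weights) and (1 - len(present) / len(weights)) > max_missing:
            raise CoverageError(
                f"population {pop!r}: {len(weights) - len(present)}/"
                f"{len(weights)} predictor CpGs missing"
            )
        sub = beta.values.loc[present]
        if sub.isna().any().any():
            sub = sub.apply(lambda r: r.fillna(r.mean()), axis=1)
        score = predictors.loc["intercept", pop] + (
            weights.loc[present].to_numpy() @ sub.to_numpy(dtype=float)
        )
        out[pop] = pd.Series(score, index=beta.values.columns)
    result = pd.DataFrame(out)
    result.index.name = "sample_id"
    result.attrs["surrogate"] = True
    return result
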