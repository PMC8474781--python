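"""Tabular input/output, matrix/sheet alignment and technical-variation PCs.

All analysis-facing containers are thin wrappers around pandas objects:

* :class:`BetaMatrix` — CpG x sample methylation fractions (beta values).
* :class:`ControlProbeMatrix` — array control-probe levels, used only for
  technical principal components.
* sample sheets — plain :class:`pandas.DataFrame` with a ``sample_id``
  column (one row per sample/visit).

Files are plain delimited text; ``.csv`` means comma, anything else tab.
A read-only GEO series-matrix dialect is supported (the
``!series_matrix_table_begin`` block only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DegenerateDataError,
    FormatError,
    ParseError,
)

_MISSING_TOKENS = {"", "na", "nan", "null", "none", "missing"}

BOUND_TOL = 1e-9


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation beta fractions.

    ``values`` is indexed by probe ID with one column per sample; entries
    are in [0, 1] or NaN (missing). Identifiers must be unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate probe ID {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < -BOUND_TOL) | (vals > 1.0 + BOUND_TOL)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value {vals[i, j]!r} outside [0,1] at probe "
                f"{idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def impute_row_means(self) -> "BetaMatrix":
        """Replace missing betas with the per-CpG (row) mean."""
        filled = self.values.apply(lambda r: r.fillna(r.mean()), axis=1)
        return BetaMatrix(filled)


@dataclass
class ControlProbeMatrix:
    """Control-probe levels (probe x sample); values unconstrained."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate control-probe ID")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ID in control probes")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TechnicalPCs:
    """Leading principal components of the control-probe matrix.

    ``scores`` is sample x component (columns PC1, PC2, ...);
    ``explained_variance_fractions`` aligns with the score columns and is
    non-increasing. The sign of each component is fixed so that its
    largest-magnitude probe loading is positive.
    """

    sample_ids: list[str]
    scores: pd.DataFrame
    explained_variance_fractions: np.ndarray
    loadings: pd.DataFrame = field(repr=False, default=None)


def _parse_numeric_table(raw: pd.DataFrame, path: str) -> pd.DataFrame:
    """Exact (correctly rounded) float parsing with cell-level diagnostics."""

    def convert(cell, row, col):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        s = str(cell).strip()
        if s.lower() in _MISSING_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric value {cell!r} at row {row!r}, "
                f"column {col!r}"
            ) from None

    out = {}
    for col in raw.columns:
        series = raw[col]
        if series.dtype != object:
            out[col] = series.astype(float)
            continue
        out[col] = pd.Series(
            [convert(v, r, col) for r, v in series.items()],
            index=series.index, dtype=float)
    return pd.DataFrame(out, index=raw.index)


def _read_geo_series_matrix(path: str | Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines)
            if ln.strip().lower().startswith("!series_matrix_table_begin")
        )
    except StopIteration:
        raise FormatError(f"{path}: no !series_matrix_table_begin block")
    rows = []
    for ln in lines[start + 1:]:
        if ln.strip().lower().startswith("!series_matrix_table_end"):
            break
        if ln.strip():
            rows.append([f.strip().strip('"') for f in ln.split("\t")])
    else:
        raise FormatError(f"{path}: unterminated series-matrix table")
    if not rows:
        raise FormatError(f"{path}: empty series-matrix table")
    header = rows[0]
    body = rows[1:]
    df = pd.DataFrame(body, columns=header).set_index(header[0])
    df.index.name = None
    return df


def read_beta_matrix(path: str | Path, dialect: str = "plain") -> BetaMatrix:
    """Read a beta matrix from delimited text or a GEO series-matrix file.

    Parameters
    ----------
    path : str or Path
        File with a header row of sample IDs and probe IDs in column 1.
    dialect : {"plain", "geo-series-matrix"}
        ``plain`` autodetects comma vs tab from the extension.
    """
    if dialect == "geo-series-matrix":
        raw = _read_geo_series_matrix(path)
    elif dialect == "plain":
        raw = pd.read_csv(
            path, sep=_sep_for(path), index_col=0,
            na_values=sorted(_MISSING_TOKENS), float_precision="round_trip")
        raw.index.name = None
    else:
        raise FormatError(f"unknown beta-matrix dialect {dialect!r}")
    raw.index = raw.index.astype(str).str.strip()
    return BetaMatrix(_parse_numeric_table(raw, str(path)))


def _repr_float(v: float) -> str:
    return repr(float(v))


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    df = beta.values.copy()
    df.index.name = "cpg_id"
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format=_repr_float)


def read_control_probes(path: str | Path) -> ControlProbeMatrix:
    raw = pd.read_csv(
        path, sep=_sep_for(path), index_col=0,
        na_values=sorted(_MISSING_TOKENS), float_precision="round_trip")
    raw.index.name = None
    raw.index = raw.index.astype(str).str.strip()
    return ControlProbeMatrix(_parse_numeric_table(raw, str(path)))


def write_control_probes(controls: ControlProbeMatrix, path: str | Path) -> None:
    df = controls.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format=_repr_float)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet; requires a ``sample_id`` column."""
    sheet = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in sheet.columns:
        raise FormatError(f"{path}: sample sheet lacks a 'sample_id' column")
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    if "age_years" in sheet.columns:
        ages = pd.to_numeric(sheet["age_years"], errors="coerce")
        if (ages.dropna() <= 0).any():
            raise FormatError(f"{path}: non-positive age_years")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


def align(
    beta: BetaMatrix, sheet: pd.DataFrame
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Restrict matrix and sheet to their common samples, in matching order.

    The surviving order is the matrix's column order. Dropped samples are
    reported through :class:`UserWarning`; an empty intersection raises
    :class:`AlignmentError`.
    """
    if "sample_id" not in sheet.columns:
        raise FormatError("sample sheet lacks a 'sample_id' column")
    sheet_ids = set(sheet["sample_id"].astype(str))
    keep = [s for s in beta.sample_ids if s in sheet_ids]
    if not keep:
        raise AlignmentError("beta matrix and sample sheet share no samples")
    dropped_beta = [s for s in beta.sample_ids if s not in sheet_ids]
    dropped_sheet = sorted(sheet_ids - set(beta.sample_ids))
    if dropped_beta or dropped_sheet:
        warnings.warn(
            f"align dropped {len(dropped_beta)} matrix sample(s) "
            f"{dropped_beta[:5]} and {len(dropped_sheet)} sheet sample(s) "
            f"{dropped_sheet[:5]}",
            stacklevel=2,
        )
    aligned_beta = BetaMatrix(beta.values.loc[:, keep])
    aligned_sheet = (
        sheet.set_index(sheet["sample_id"].astype(str))
        .loc[keep]
        .reset_index(drop=True)
    )
    return aligned_beta, aligned_sheet


def technical_pcs(
    controls: ControlProbeMatrix, n_components: int = 2
) -> TechnicalPCs:
    """Principal components of control-probe levels, per sample.

    The sample x probe matrix is mean-imputed per probe, column
    mean-centered, and decomposed by SVD. Scores are U·S; the sign of each
    component is fixed so its largest-magnitude loading is positive, which
    makes the result deterministic across platforms.
    """
    X = controls.values.to_numpy(dtype=float).T  # samples x probes
    n_samples, n_probes = X.shape
    if n_components < 1 or n_components > min(n_probes, n_samples):
        raise DegenerateDataError(
            f"n_components={n_components} exceeds min(probes, samples)"
        )
    col_means = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, np.broadcast_to(col_means, X.shape), X)
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    if total_var <= 1e-12:
        raise DegenerateDataError("control-probe matrix has no variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    fractions = s**2 / (s**2).sum()
    scores = U * s
    for j in range(n_components):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    score_df = pd.DataFrame(
        scores[:, :n_components], index=controls.sample_ids, columns=comp_names
    )
    loading_df = pd.DataFrame(
        Vt[:n_components].T, index=controls.probe_ids, columns=comp_names
    )
    return TechnicalPCs(
        sample_ids=list(controls.sample_ids),
        scores=score_df,
        explained_variance_fractions=fractions[:n_components],
        loadings=loading_df,
    )
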