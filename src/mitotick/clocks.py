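"""DNA-methylation clocks and age-acceleration measures.

The mitotic clock score (``pcgt_age``) is the unweighted mean beta over a
fixed set of polycomb-group-target promoter CpGs; these sites start
unmethylated in fetal tissue and gain methylation with cell division, so
the mean tracks the replicative history of the sampled tissue. Acceleration
measures are ordinary-least-squares residuals:

* ``AccelEpiTOC`` — residual of pcgt_age on chronologic age.
* ``AgeAccel``     — residual of a linear DNAm age on chronologic age.
* ``IEAA``         — residual of DNAm age on age *and* blood-cell
  composition (composition-independent aging).
* ``EEAA``         — residual on age of an immune-cell-weighted DNAm age
  (immune-system aging; weights configurable, surrogate by default).

Raw residuals are reported together with SD-standardized twins
(sample SD, n−1 denominator), matching the usual per-SD reporting of
epigenetic aging effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CollinearityError,
    ConfigError,
    CoverageError,
    DegenerateDataError,
    FormatError,
)
from .io import BetaMatrix


def _horvath_calibration(adult_age: float = 20.0) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone inverse transform used by pan-tissue-style clocks."""

    def inverse(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(
            x < 0, (1 + adult_age) * np.exp(x) - 1, (1 + adult_age) * x + adult_age
        )

    return inverse


_CALIBRATIONS: dict[str, Callable[..., Callable[[np.ndarray], np.ndarray]]] = {
    "identity": lambda: (lambda x: np.asarray(x, dtype=float)),
    "horvath": _horvath_calibration,
}


@dataclass
class ClockDefinition:
    """A named CpG set with optional weights, intercept and calibration.

    ``weights=None`` declares a uniform-mean clock (the mitotic clock case):
    the score is the plain mean beta over the CpG set. Otherwise the score
    is ``calibration(intercept + sum(w_j * beta_j))``.
    """

    name: str
    cpg_ids: list[str]
    weights: np.ndarray | None = None
    intercept: float = 0.0
    calibration: str = "identity"
    calibration_params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise FormatError(f"clock {self.name!r}: duplicate CpG IDs")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.cpg_ids):
                raise FormatError(
                    f"clock {self.name!r}: {len(self.weights)} weights for "
                    f"{len(self.cpg_ids)} CpGs"
                )
        if self.calibration not in _CALIBRATIONS:
            raise ConfigError(f"unknown calibration {self.calibration!r}")

    @property
    def is_uniform_mean(self) -> bool:
        return self.weights is None

    def calibrate(self, x: np.ndarray) -> np.ndarray:
        return _CALIBRATIONS[self.calibration](*self.calibration_params)(x)


def read_clock_definition(path: str | Path) -> ClockDefinition:
    """Read a clock file: `#name=`, `#intercept=`, `#calibration=` header
    lines, then `cpg_id<TAB>weight` rows (blank weight => uniform-mean)."""
    name, intercept, calibration, params = Path(path).stem, 0.0, "identity", ()
    cpgs: list[str] = []
    weights: list[float] = []
    saw_weight = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            key, val = key.strip().lower(), val.strip()
            if key == "name":
                name = val
            elif key == "intercept":
                intercept = float(val)
            elif key == "calibration":
                head, _, tail = val.partition(":")
                calibration = head.strip()
                params = tuple(float(t) for t in tail.split(",") if t.strip())
            continue
        parts = line.split("\t")
        if parts[0].lower() in {"cpg_id", "probe_id"}:
            continue
        cpgs.append(parts[0])
        if len(parts) > 1 and parts[1].strip():
            saw_weight = True
            weights.append(float(parts[1]))
        else:
            weights.append(np.nan)
    if saw_weight and any(np.isnan(weights)):
        raise FormatError(f"{path}: clock mixes weighted and blank rows")
    return ClockDefinition(
        name=name,
        cpg_ids=cpgs,
        weights=np.array(weights) if saw_weight else None,
        intercept=intercept,
        calibration=calibration,
        calibration_params=params,
    )


def write_clock_definition(clock: ClockDefinition, path: str | Path) -> None:
    lines = [f"#name={clock.name}", f"#intercept={clock.intercept}"]
    cal = clock.calibration
    if clock.calibration_params:
        cal += ":" + ",".join(str(p) for p in clock.calibration_params)
    lines.append(f"#calibration={cal}")
    lines.append("cpg_id\tweight")
    for i, cpg in enumerate(clock.cpg_ids):
        w = "" if clock.weights is None else repr(float(clock.weights[i]))
        lines.append(f"{cpg}\t{w}")
    Path(path).write_text("\n".join(lines) + "\n")


def packaged_clock(name: str = "epitoc385-synthetic") -> ClockDefinition:
    """Load a clock definition shipped with the package.

    The packaged mitotic-clock file is a synthetic stand-in CpG list (the
    published 385-probe set is distributed with its source publication);
    supply your own list for real-array analyses.
    """
    path = Path(__file__).parent / "data" / f"{name.replace('-', '_')}.tsv"
    if not path.exists():
        raise ConfigError(f"no packaged clock named {name!r}")
    return read_clock_definition(path)


def pcgt_age(
    beta: BetaMatrix,
    clock: ClockDefinition,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Mitotic-age score: per-sample mean beta over the clock CpG set.

    Missing betas are dropped per sample (available-case mean). Raises
    :class:`CoverageError` when fewer than ``min_coverage`` of the clock
    CpGs are present in the matrix.

    Returns a DataFrame indexed by sample with columns ``pcgt_age``,
    ``n_clock_cpgs_used`` and ``coverage``.
    """
    present = [c for c in clock.cpg_ids if c in beta.values.index]
    coverage = len(present) / len(clock.cpg_ids)
    if coverage < min_coverage:
        raise CoverageError(
            f"only {len(present)}/{len(clock.cpg_ids)} clock CpGs present "
            f"(coverage {coverage:.3f} < {min_coverage})"
        )
    sub = beta.values.loc[present]
    score = sub.mean(axis=0, skipna=True)
    n_used = sub.notna().sum(axis=0)
    return pd.DataFrame(
        {
            "pcgt_age": score,
            "n_clock_cpgs_used": n_used.astype(int),
            "coverage": n_used / len(clock.cpg_ids),
        }
    )


def linear_clock_age(beta: BetaMatrix, clock: ClockDefinition) -> pd.Series:
    """Weighted linear DNAm age: calibration(intercept + sum w_j beta_j)."""
    if clock.weights is None:
        raise FormatError(f"clock {clock.name!r} has no weights")
    missing = [c for c in clock.cpg_ids if c not in beta.values.index]
    if missing:
        raise CoverageError(
            f"clock {clock.name!r}: {len(missing)} CpGs absent, e.g. "
            f"{missing[:3]}"
        )
    sub = beta.values.loc[clock.cpg_ids]
    if sub.isna().any().any():
        sub = sub.apply(lambda r: r.fillna(r.mean()), axis=1)
    raw = clock.intercept + clock.weights @ sub.to_numpy(dtype=float)
    return pd.Series(
        clock.calibrate(raw), index=beta.values.columns, name=clock.name
    )


@dataclass
class ResidualFit:
    """OLS residuals plus the fitted line/plane that produced them."""

    residuals: pd.Series
    coefficients: pd.Series
    design_columns: list[str] = field(default_factory=list)


def _ols_residuals(y: np.ndarray, X: np.ndarray, colnames: list[str]) -> tuple[np.ndarray, np.ndarray]:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        _, R, piv = _qr_pivoted(X)
        aliased = [colnames[p] for p in piv[rank:]]
        raise CollinearityError(f"design is rank deficient; aliased: {aliased}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef, coef


def _qr_pivoted(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, pivoting=True, mode="economic")
    return Q, R, piv


def age_acceleration(
    estimate: pd.Series, age_years: pd.Series
) -> ResidualFit:
    """Residual of a clock estimate on chronologic age (OLS, with intercept).

    This is the raw acceleration: observed minus the value expected for the
    sample's age, fitted on the analysis sample itself.
    """
    est, age = estimate.align(age_years, join="inner")
    mask = est.notna() & age.notna()
    est, age = est[mask], age[mask]
    if len(est) < 3:
        raise DegenerateDataError("age_acceleration needs >= 3 samples")
    if float(np.var(age)) == 0.0:
        raise DegenerateDataError("age has zero variance; design singular")
    X = np.column_stack([np.ones(len(age)), age.to_numpy(dtype=float)])
    resid, coef = _ols_residuals(est.to_numpy(dtype=float), X, ["intercept", "age"])
    return ResidualFit(
        residuals=pd.Series(resid, index=est.index, name="accel"),
        coefficients=pd.Series(coef, index=["intercept", "age"]),
        design_columns=["intercept", "age"],
    )


def intrinsic_acceleration(
    dnam_age: pd.Series,
    age_years: pd.Series,
    cell_composition: pd.DataFrame,
) -> ResidualFit:
    """IEAA: residual of DNAm age on age plus cell-composition columns.

    Zero-variance cell columns are dropped (the measure then reduces to
    plain age acceleration); a rank-deficient design raises
    :class:`CollinearityError` naming the aliased columns.
    """
    df = pd.concat(
        {"__y": dnam_age, "__age": age_years}, axis=1, join="inner"
    ).join(cell_composition, how="inner")
    df = df.dropna()
    if len(df) < 3:
        raise DegenerateDataError("intrinsic_acceleration needs >= 3 samples")
    cells = [c for c in cell_composition.columns if df[c].var() > 0]
    cols = ["intercept", "age"] + cells
    X = np.column_stack(
        [np.ones(len(df)), df["__age"].to_numpy(dtype=float)]
        + [df[c].to_numpy(dtype=float) for c in cells]
    )
    resid, coef = _ols_residuals(df["__y"].to_numpy(dtype=float), X, cols)
    return ResidualFit(
        residuals=pd.Series(resid, index=df.index, name="ieaa"),
        coefficients=pd.Series(coef, index=cols),
        design_columns=cols,
    )


def extrinsic_acceleration(
    base_clock_age: pd.Series,
    age_years: pd.Series,
    immune_cells: pd.DataFrame | None = None,
    immune_weights: Mapping[str, float] | None = None,
) -> ResidualFit:
    """EEAA: residual on age of an immune-weighted DNAm age.

    The immune-weighted age is ``base_clock_age + sum_k w_k * cell_k`` with
    configurable weights (all-zero weights reduce to plain acceleration of
    the base clock). The weights used are recorded on the result.
    """
    weighted = base_clock_age.astype(float).copy()
    immune_weights = dict(immune_weights or {})
    if immune_weights:
        if immune_cells is None:
            raise ConfigError("immune weights given without immune_cells")
        for cell, w in immune_weights.items():
            if cell not in immune_cells.columns:
                raise ConfigError(f"immune cell column {cell!r} missing")
            weighted = weighted + w * immune_cells[cell].astype(float)
    fit = age_acceleration(weighted, age_years)
    fit.residuals.name = "eeaa"
    fit.coefficients.attrs["immune_weights"] = immune_weights
    return fit


def standardize_sd(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Center and scale to unit sample SD (n−1 denominator)."""
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDataError("cannot SD-standardize: zero variance")
    out = (arr - arr.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def build_accel_table(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    mitotic_clock: ClockDefinition,
    linear_clocks: Sequence[ClockDefinition] = (),
    cell_composition: pd.DataFrame | None = None,
    eeaa_clock: str | None = None,
    eeaa_weights: Mapping[str, float] | None = None,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Assemble the per-sample acceleration table.

    Always contains ``pcgt_age``, ``accel_epitoc_raw`` and
    ``accel_epitoc_sd``; adds ``<clock>_age`` / ``<clock>_age_accel`` per
    linear clock, and IEAA/EEAA (with ``_sd`` twins) when composition and
    an EEAA base clock are supplied. Residuals are fitted on the full
    analysis sample.
    """
    ages = pd.Series(
        sheet["age_years"].to_numpy(dtype=float),
        index=sheet["sample_id"].astype(str),
    )
    pa = pcgt_age(beta, mitotic_clock, min_coverage=min_coverage)
    table = pa.copy()
    accel = age_acceleration(pa["pcgt_age"], ages)
    table["accel_epitoc_raw"] = accel.residuals
    table["accel_epitoc_sd"] = standardize_sd(accel.residuals)
    for clock in linear_clocks:
        est = linear_clock_age(beta, clock)
        table[f"{clock.name}_age"] = est
        fit = age_acceleration(est, ages)
        table[f"{clock.name}_age_accel"] = fit.residuals
        table[f"{clock.name}_age_accel_sd"] = standardize_sd(fit.residuals)
        if cell_composition is not None:
            ieaa = intrinsic_acceleration(est, ages, cell_composition)
            if eeaa_clock is None or clock.name != eeaa_clock:
                table["ieaa"] = ieaa.residuals
                table["ieaa_sd"] = standardize_sd(ieaa.residuals)
        if eeaa_clock is not None and clock.name == eeaa_clock:
            eeaa = extrinsic_acceleration(
                est, ages, cell_composition, eeaa_weights
            )
            table["eeaa"] = eeaa.residuals
            table["eeaa_sd"] = standardize_sd(eeaa.residuals)
    table.index.name = "sample_id"
    return table
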