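"""Statistical layer: mixed models, logistic association, stepwise AIC,
paired tests and correlation panels.

Conventions shared by every fit:

* complete-case analysis on the columns a model touches;
* categorical covariates dummy-coded against their most frequent level;
* "per SD" predictors standardized on the model's analysis sample
  (sample SD, n−1);
* mixed-model p-values are Wald z (normal approximation);
* REML for reported mixed models, ML wherever AICs are compared.

Model estimation is delegated to statsmodels (Logit, OLS, MixedLM); this
module owns design construction, the stepwise-AIC search, and result
shaping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .exceptions import (
    CollinearityError,
    ConfigError,
    DataError,
    ModelError,
    SeparationError,
)

Z975 = st.norm.ppf(0.975)


@dataclass
class ModelSpec:
    """Declarative description of a regression model."""

    outcome: str
    terms: list[str] = field(default_factory=list)
    per_sd: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    random: list[str] = field(default_factory=list)  # subset of {intercept, time}
    family: str = "binomial-logit"
    estimation: str = "ML"

    def __post_init__(self) -> None:
        if self.family not in {"binomial-logit", "gaussian"}:
            raise ConfigError(f"unknown family {self.family!r}")
        for a, b in self.interactions:
            for t in (a, b):
                if t not in self.terms:
                    raise ConfigError(
                        f"interaction component {t!r} missing from main terms")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelSpec":
        d = dict(data)
        if "interactions" in d:
            d["interactions"] = [tuple(p) for p in d["interactions"]]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown model spec keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FitResult:
    """Tidy estimates with uncertainties plus fit-level diagnostics."""

    table: pd.DataFrame
    n_obs: int
    n_subjects: int | None = None
    log_likelihood: float | None = None
    aic: float | None = None
    model: str = ""

    def term(self, name: str) -> pd.Series:
        hits = self.table[self.table["term"] == name]
        if hits.empty:
            raise KeyError(f"no term {name!r} in fit result")
        return hits.iloc[0]

    def summary(self) -> str:
        lines = [f"{self.model}  (n_obs={self.n_obs}"
                 + (f", n_subjects={self.n_subjects}" if self.n_subjects else "")
                 + ")"]
        if self.aic is not None:
            lines.append(f"loglik={self.log_likelihood:.3f}  AIC={self.aic:.3f}")
        with pd.option_context("display.width", 120):
            lines.append(self.table.to_string(index=False,
                                              float_format=lambda v: f"{v: .4g}"))
        return "\n".join(lines)


def _dummy_code(series: pd.Series, name: str) -> pd.DataFrame:
    """Dummy-code against the most frequent level (deterministic ties)."""
    counts = series.value_counts()
    top = counts.max()
    reference = sorted(counts[counts == top].index)[0]
    levels = [l for l in sorted(series.dropna().unique()) if l != reference]
    out = {}
    for lev in levels:
        out[f"{name}[{lev}]"] = (series == lev).astype(float)
    return pd.DataFrame(out, index=series.index)


def build_design(
    data: pd.DataFrame,
    terms: Sequence[str],
    per_sd: Iterable[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Numeric design matrix from named columns.

    Numeric columns pass through (SD-standardized when flagged per-SD);
    non-numeric columns are dummy-coded against their most frequent
    level; interaction columns are products of already-built columns.
    """
    per_sd = set(per_sd)
    pieces: dict[str, pd.Series] = {}
    built: dict[str, list[str]] = {}
    if add_intercept:
        pieces["intercept"] = pd.Series(1.0, index=data.index)
    for term in terms:
        if term not in data.columns:
            raise DataError(f"model term {term!r} missing from data")
        col = data[term]
        if pd.api.types.is_numeric_dtype(col):
            vals = col.astype(float)
            if term in per_sd:
                sd = vals.std(ddof=1)
                if not np.isfinite(sd) or sd == 0:
                    raise DataError(f"cannot per-SD scale constant term {term!r}")
                vals = (vals - vals.mean()) / sd
            pieces[term] = vals
            built[term] = [term]
        else:
            dummies = _dummy_code(col, term)
            for c in dummies.columns:
                pieces[c] = dummies[c]
            built[term] = list(dummies.columns)
    for a, b in interactions:
        for ca in built[a]:
            for cb in built[b]:
                pieces[f"{ca}:{cb}"] = pieces[ca] * pieces[cb]
    X = pd.DataFrame(pieces)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X.to_numpy(dtype=float), pivoting=True, mode="economic")
        aliased = [X.columns[p] for p in piv[rank:]]
        raise CollinearityError(f"rank-deficient design; aliased: {aliased}")
    return X


def _complete_cases(data: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"columns missing from data: {missing}")
    return data.dropna(subset=list(cols))


def _result_table(
    names: Sequence[str],
    est: np.ndarray,
    se: np.ndarray,
    binomial: bool,
) -> pd.DataFrame:
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    p = 2 * st.norm.sf(np.abs(z))
    tab = pd.DataFrame(dict(
        term=list(names), estimate=est, standard_error=se,
        ci_low=est - Z975 * se, ci_high=est + Z975 * se, p_value=p))
    if binomial:
        tab["odds_ratio"] = np.exp(est)
        tab["or_ci_low"] = np.exp(tab["ci_low"])
        tab["or_ci_high"] = np.exp(tab["ci_high"])
    return tab


def fit_logistic(
    data: pd.DataFrame,
    spec: ModelSpec,
    case_label: str = "case",
) -> FitResult:
    """Maximum-likelihood logistic regression for a binary outcome.

    The outcome may be 0/1 or labeled; ``case_label`` (or the
    lexicographically larger of two labels) maps to 1. Perfect separation
    is reported as :class:`SeparationError` rather than silently diverging.
    """
    if spec.family != "binomial-logit":
        raise ConfigError("fit_logistic requires a binomial-logit spec")
    cols = [spec.outcome] + list(spec.terms)
    df = _complete_cases(data, cols)
    y_raw = df[spec.outcome]
    if pd.api.types.is_numeric_dtype(y_raw):
        y = y_raw.astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise DataError("numeric outcome must be 0/1")
    else:
        levels = sorted(y_raw.unique())
        if len(levels) != 2:
            raise DataError(f"binary outcome has levels {levels}")
        positive = case_label if case_label in levels else levels[1]
        y = (y_raw == positive).astype(float)
    if y.nunique() < 2:
        raise DataError("outcome has a single class after complete-case filter")
    X = build_design(df, spec.terms, spec.per_sd, spec.interactions)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            fit = sm.Logit(y.to_numpy(), X.to_numpy()).fit(
                method="newton", tol=1e-10, maxiter=200, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning,
            ConvergenceWarning) as exc:
        raise SeparationError(
            f"logistic fit did not converge (likely separation): {exc}"
        ) from None
    if np.abs(fit.params).max() > 50:
        raise SeparationError(
            "logistic estimates diverged; outcome is (quasi-)separated")
    tab = _result_table(X.columns, fit.params, fit.bse, binomial=True)
    return FitResult(
        table=tab, n_obs=len(df),
        log_likelihood=float(fit.llf), aic=float(fit.aic),
        model=f"logit({spec.outcome}) ~ " + " + ".join(X.columns[1:]))


def paired_difference(
    values_a: pd.Series, values_b: pd.Series
) -> dict[str, float]:
    """Classical paired t-test on within-subject differences.

    Returns mean difference, 95% CI from the t quantile with n−1 df, the
    t statistic and p-value. With zero variance and a nonzero mean the
    exact difference is reported and the p-value flagged undefined (NaN).
    """
    a, b = values_a.align(values_b, join="inner")
    mask = a.notna() & b.notna()
    d = (a[mask] - b[mask]).to_numpy(dtype=float)
    n = len(d)
    if n < 2:
        raise DataError("paired_difference needs >= 2 complete pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    tq = st.t.ppf(0.975, n - 1)
    if sd == 0:
        return dict(mean_difference=mean, ci_low=mean, ci_high=mean,
                    t=0.0 if mean == 0 else np.nan,
                    p_value=1.0 if mean == 0 else np.nan, n_pairs=n)
    t_stat = mean / se
    p = 2 * st.t.sf(abs(t_stat), n - 1)
    return dict(mean_difference=mean, ci_low=mean - tq * se,
                ci_high=mean + tq * se, t=float(t_stat), p_value=float(p),
                n_pairs=n)


def _fit_mixedlm(
    endog: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    exog_re: pd.DataFrame | None,
    reml: bool,
) -> tuple[pd.DataFrame, float, float, bool]:
    """Fit a linear mixed model; fall back to OLS on failure/singularity."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                endog, X.to_numpy(), groups=groups,
                exog_re=None if exog_re is None else exog_re.to_numpy())
            fit = model.fit(reml=reml, method=["lbfgs", "powell"])
        k = X.shape[1]
        params = np.asarray(fit.params[:k], dtype=float)
        bse = np.asarray(fit.bse[:k], dtype=float)
        if not np.all(np.isfinite(bse)):
            raise np.linalg.LinAlgError("non-finite mixed-model SEs")
        tab = _result_table(X.columns, params, bse, binomial=False)
        return tab, float(fit.llf), float(fit.aic) if fit.aic else np.nan, True
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(
            f"mixed model failed ({exc}); falling back to fixed-effects OLS",
            stacklevel=2)
        ols = sm.OLS(endog, X.to_numpy()).fit()
        tab = _result_table(X.columns, ols.params, ols.bse, binomial=False)
        return tab, float(ols.llf), float(ols.aic), False


def fit_lmm_celltype(
    values: pd.Series,
    sheet: pd.DataFrame,
    contrast: str = "celltype",
    reference_level: str = "CD8 T",
    reml: bool = True,
) -> FitResult:
    """Within-subject cell-type model on a purified panel.

    ``values`` is one score per purified sample (indexed by sample_id).
    Fits a linear mixed model with a random subject intercept and fixed
    effects for cell type (``contrast='celltype'``, against
    ``reference_level``) or a binary myeloid indicator
    (``contrast='lineage'``, lymphoid reference).
    """
    df = sheet.copy()
    df["__y"] = df["sample_id"].map(values)
    df = df.dropna(subset=["__y", "subject_id"])
    if df["subject_id"].nunique() < 2:
        raise DataError("need >= 2 subjects for a within-subject model")
    if contrast == "celltype":
        if reference_level not in set(df["cell_type_label"]):
            raise ConfigError(f"reference level {reference_level!r} absent")
        levels = [l for l in sorted(df["cell_type_label"].unique())
                  if l != reference_level]
        X = pd.DataFrame({"intercept": 1.0}, index=df.index)
        for lev in levels:
            X[f"cell_type[{lev}]"] = (df["cell_type_label"] == lev).astype(float)
    elif contrast == "lineage":
        if "lineage" not in df.columns:
            raise DataError("sheet lacks a 'lineage' column")
        X = pd.DataFrame({
            "intercept": 1.0,
            "lineage[myeloid]": (df["lineage"] == "myeloid").astype(float),
        }, index=df.index)
    else:
        raise ConfigError(f"unknown contrast {contrast!r}")
    tab, llf, aic, mixed = _fit_mixedlm(
        df["__y"].to_numpy(dtype=float), X,
        df["subject_id"].to_numpy(), exog_re=None, reml=reml)
    return FitResult(
        table=tab, n_obs=len(df), n_subjects=df["subject_id"].nunique(),
        log_likelihood=llf, aic=aic,
        model=("mixed " if mixed else "ols ") + f"score ~ {contrast} + (1|subject)")


def fit_lmm_progression(
    visits: pd.DataFrame,
    spec: ModelSpec,
    accel_term: str = "accel_sd",
    time_term: str = "visit_time_years",
    reml: bool = True,
) -> FitResult:
    """Longitudinal mixed model with an acceleration-by-time interaction.

    Random intercept (+ random slope on time when ``'time'`` is in
    ``spec.random``, the default behaviour of the pipeline) per subject;
    the ``accel:time`` interaction estimate is the yearly change in the
    exam score per SD of acceleration.
    """
    if spec.family != "gaussian":
        raise ConfigError("progression model must be gaussian")
    cols = [spec.outcome, "subject_id"] + list(spec.terms)
    df = _complete_cases(visits, cols)
    per_subj = df.groupby("subject_id")[time_term].nunique()
    if (per_subj < 2).all():
        raise DataError("progression model needs >= 2 visits per subject")
    if per_subj.index.size < 2:
        raise DataError("progression model needs >= 2 subjects")
    interactions = list(spec.interactions) or [(accel_term, time_term)]
    X = build_design(df, spec.terms, spec.per_sd, interactions)
    exog_re = pd.DataFrame({"intercept": 1.0}, index=df.index)
    if "time" in spec.random or time_term in spec.random:
        exog_re[time_term] = df[time_term].astype(float)
    tab, llf, aic, mixed = _fit_mixedlm(
        df[spec.outcome].to_numpy(dtype=float), X,
        df["subject_id"].to_numpy(), exog_re=exog_re, reml=reml)
    return FitResult(
        table=tab, n_obs=len(df), n_subjects=df["subject_id"].nunique(),
        log_likelihood=llf, aic=aic,
        model=("mixed " if mixed else "ols ")
        + f"{spec.outcome} ~ {accel_term}*{time_term} + covariates")


def stepwise_aic(
    data: pd.DataFrame,
    spec: ModelSpec,
    candidates: Sequence[str],
    locked: Sequence[str] | None = None,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Bidirectional greedy AIC selection from the locked model.

    At each step the single add/drop move with the largest AIC decrease is
    taken (ties broken by term name); the search stops when no move
    improves AIC by more than 1e-6. Locked terms are never dropped. All
    fits use the complete-case intersection over locked + candidate
    columns so AICs are comparable; estimation is ML.
    """
    locked = list(spec.terms if locked is None else locked)
    candidates = sorted(set(candidates) - set(locked))
    all_cols = [spec.outcome] + locked + candidates
    df = _complete_cases(data, all_cols)

    def fit_aic(terms: list[str]) -> float:
        sub = ModelSpec(outcome=spec.outcome, terms=terms,
                        per_sd=[t for t in spec.per_sd if t in terms],
                        family=spec.family)
        if spec.family == "binomial-logit":
            return fit_logistic(df, sub).aic
        X = build_design(df, terms, sub.per_sd)
        return float(sm.OLS(df[spec.outcome].astype(float).to_numpy(),
                            X.to_numpy()).fit().aic)

    current: list[str] = list(locked)
    current_aic = fit_aic(current)
    trace = [dict(step=0, action="start", term="", aic=current_aic)]
    step = 0
    while True:
        moves: list[tuple[float, str, str]] = []
        in_model = set(current)
        for c in candidates:
            if c not in in_model:
                moves.append((fit_aic(current + [c]), "add", c))
            else:
                moves.append((fit_aic([t for t in current if t != c]),
                              "drop", c))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, action, term = moves[0]
        if current_aic - best_aic <= 1e-6:
            break
        step += 1
        if action == "add":
            current = current + [term]
        else:
            current = [t for t in current if t != term]
        current_aic = best_aic
        trace.append(dict(step=step, action=action, term=term, aic=best_aic))
    selected = ModelSpec(
        outcome=spec.outcome, terms=current,
        per_sd=[t for t in spec.per_sd if t in current],
        family=spec.family)
    return selected, pd.DataFrame(trace)


def pearson_corr_matrix(
    columns: pd.DataFrame,
    partial_on: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with p-values from the t transform.

    With ``partial_on`` every variable is first residualized (OLS with
    intercept) on the covariates; the correlations of the residuals are
    the partial correlations given those covariates. Zero-variance
    columns are flagged with a warning and yield NaN rows/columns.
    Pairwise-complete observations are used per pair (minimum n = 3).
    """
    work = columns.astype(float).copy()
    if partial_on is not None:
        Z = partial_on.astype(float)
        Z = sm.add_constant(Z, has_constant="add")
        common = work.index.intersection(Z.dropna().index)
        work = work.loc[common]
        Zm = Z.loc[common].to_numpy()
        for c in work.columns:
            y = work[c].to_numpy()
            ok = np.isfinite(y)
            coef, *_ = np.linalg.lstsq(Zm[ok], y[ok], rcond=None)
            work.loc[ok, c] = y[ok] - Zm[ok] @ coef
    names = list(work.columns)
    k = len(names)
    R = pd.DataFrame(np.eye(k), index=names, columns=names)
    P = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    degenerate = [c for c in names if work[c].dropna().nunique() <= 1]
    if degenerate:
        warnings.warn(f"zero-variance columns in correlation panel: "
                      f"{degenerate}", stacklevel=2)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = work[names[i]], work[names[j]]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3 or names[i] in degenerate or names[j] in degenerate:
                r, p = np.nan, np.nan
            else:
                xv = x[ok].to_numpy() - x[ok].mean()
                yv = y[ok].to_numpy() - y[ok].mean()
                denom = np.sqrt((xv**2).sum() * (yv**2).sum())
                if denom == 0:
                    r, p = np.nan, np.nan
                else:
                    r = float((xv * yv).sum() / denom)
                    r = max(min(r, 1.0), -1.0)
                    if abs(r) == 1.0:
                        p = 0.0
                    else:
                        t_stat = r * np.sqrt((n - 2) / (1 - r**2))
                        p = float(2 * st.t.sf(abs(t_stat), n - 2))
            R.iloc[i, j] = R.iloc[j, i] = r
            P.iloc[i, j] = P.iloc[j, i] = p
    return R, P


def stratify(
    data: pd.DataFrame,
    by: str,
    fit: Callable[[pd.DataFrame], FitResult],
    min_n: int = 10,
) -> dict[str, FitResult]:
    """Re-run a fit within each stratum of ``by``; small strata skipped."""
    if by not in data.columns:
        raise DataError(f"stratification column {by!r} missing")
    out: dict[str, FitResult] = {}
    for level, sub in data.groupby(by, sort=True):
        if len(sub) < min_n:
            warnings.warn(
                f"stratum {by}={level!r} has n={len(sub)} < {min_n}; skipped",
                stacklevel=2)
            continue
        out[str(level)] = fit(sub.reset_index(drop=True))
    return out
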