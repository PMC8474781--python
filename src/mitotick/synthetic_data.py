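"""Synthetic hematopoietic methylomes with known ground truth.

The generator emulates the three data layers the analysis consumes:

1. **Purified-cell panels** — flow-sorted myeloid (granulocytes,
   neutrophils, eosinophils, monocytes) and lymphoid (B, CD4 T, CD8 T, NK)
   methylomes from a handful of adult donors. Mitotic-clock CpGs start
   near-unmethylated and gain beta in proportion to cumulative divisions;
   lymphoid compartments carry a longer effective division history than
   short-lived myeloid cells, and myeloid profiles show a small global
   methylation deficit.
2. **Whole-blood case-control cohorts** — per-subject Dirichlet mixtures
   of the cell profiles (granulocyte-dominant), with cases ticking faster
   (a calibrated division-rate multiplier) *and* shifted toward
   granulocytes, so that the composition confounds the disease association
   negatively: the unadjusted mitotic-acceleration odds ratio is masked
   while the composition-adjusted one recovers the injected effect.
3. **Longitudinal exam scores** — per-patient linear trajectories whose
   slopes depend on the patient's true mitotic acceleration (negative for
   a cognition-style exam, positive for motor-style exams), with Gaussian
   random intercepts/slopes and residual noise.

Cumulative divisions are modeled as ``r_k * (A0 + kappa * age)``: a
developmental expansion equivalent to ``A0`` adult-years plus a slower
adult accrual. This lets a large purified-cell lineage gap coexist with a
weak adult age correlation of the whole-blood score, as observed in real
blood. Ticking is deterministic in expectation; noise enters only at
measurement, on the logit scale.

Everything is driven by one integer seed; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clocks import ClockDefinition
from .exceptions import ConfigError, DataError
from .io import BetaMatrix, ControlProbeMatrix

MYELOID = "myeloid"
LYMPHOID = "lymphoid"

DEFAULT_CELL_TYPES: dict[str, str] = {
    "granulocytes": MYELOID,
    "neutrophils": MYELOID,
    "eosinophils": MYELOID,
    "monocytes": MYELOID,
    "B cells": LYMPHOID,
    "CD4 T": LYMPHOID,
    "CD8 T": LYMPHOID,
    "NK": LYMPHOID,
}

# the six circulating populations used for whole-blood mixing/deconvolution
DEFAULT_MIXTURE_TYPES = [
    "granulocytes", "monocytes", "B cells", "CD4 T", "CD8 T", "NK",
]

# effective divisions per adult-year by compartment; lymphoid compartments
# carry the longer division history
DEFAULT_TICK_RATES: dict[str, float] = {
    "granulocytes": 0.7,
    "neutrophils": 0.75,
    "eosinophils": 0.8,
    "monocytes": 0.9,
    "B cells": 2.2,
    "CD4 T": 2.4,
    "CD8 T": 2.7,
    "NK": 2.3,
}

# granulocyte-dominant Dirichlet concentration (mean ~0.60 granulocytes)
DEFAULT_PROPORTION_ALPHA: dict[str, float] = {
    "granulocytes": 8.5,
    "monocytes": 1.13,
    "B cells": 0.71,
    "CD4 T": 1.99,
    "CD8 T": 1.13,
    "NK": 0.71,
}

# random-slope and residual SDs are set so the interaction SE at ~330
# patients x 3 visits matches the reporting scale of clinical exams
DEFAULT_EXAMS: dict[str, dict[str, float]] = {
    # cognition-style exam: higher is better, acceleration speeds decline
    "MMSE": dict(baseline_mean=27.5, rint_sd=1.8, time_slope=-0.15,
                 slope_per_sd=-0.06, rslope_sd=0.25, resid_sd=1.0),
    # motor-style exam: higher is worse, acceleration speeds worsening
    "UPDRS_III": dict(baseline_mean=21.0, rint_sd=8.0, time_slope=1.5,
                      slope_per_sd=0.19, rslope_sd=1.5, resid_sd=4.5),
    # tremor sub-score of the motor exam
    "UPDRS_III_tremor": dict(baseline_mean=4.0, rint_sd=1.6, time_slope=0.2,
                             slope_per_sd=0.05, rslope_sd=0.25, resid_sd=1.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for all generators. Defaults are the calibrated
    conditions the analysis targets; see docs/methods.md for the rationale
    behind each value."""

    # methylome layout
    n_cpgs_total: int = 5000
    n_clock_cpgs: int = 385
    n_reference_cpgs_per_type: int = 50
    n_age_cpgs: int = 60  # per aging-clock block (two blocks)
    cell_types: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    mixture_cell_types: list[str] = field(
        default_factory=lambda: list(DEFAULT_MIXTURE_TYPES))
    # purified panel
    n_donors_purified: int = 6
    donor_age_mean_years: float = 38.0
    donor_age_sd_years: float = 13.6
    cell_frailty_sd_log: float = 0.30  # per-(donor, cell type) rate jitter
    # cohort design
    n_cases: int = 600
    n_controls: int = 600
    age_range_years: tuple[float, float] = (50.0, 90.0)
    male_fraction_cases: float = 0.626
    male_fraction_controls: float = 0.534
    # division / ticking model
    tick_increment_delta: float = 0.001  # beta gain per division at clock CpGs
    lineage_tick_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TICK_RATES))
    development_years: float = 28.5  # A0: early-life expansion, adult-year equivalents
    adult_rate_scale: float = 0.25  # kappa: adult accrual relative to r_k
    frailty_sd_log: float = 0.15  # per-subject division-rate multiplier
    clock_baseline_offset_sd: float = 0.004  # age-independent clock background
    myeloid_depletion_shift: float = 0.02  # genome-wide myeloid beta deficit
    # disease effects (calibrated; see docs/methods.md)
    disease_tick_multiplier: float = 1.092
    case_granulocyte_shift: float = 0.088
    target_adjusted_log_or_per_sd: float = 0.75  # calibration target
    # mixing + measurement
    proportion_concentration: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTION_ALPHA))
    noise_sd_logit: float = 0.05
    # aging-clock structure
    eeaa_frailty_years: float = 7.4  # immune-age years per unit frailty deviation
    eeaa_noise_sd_years: float = 3.8
    eeaa_case_shift_years: float = 1.4
    ieaa_noise_sd_years: float = 4.0
    ieaa_case_shift_years: float = 1.0
    # technical structure
    n_control_probes: int = 848
    batch_effect_sd: float = 0.05
    position_effect_sd: float = 0.02
    control_probe_noise_sd: float = 0.01
    # longitudinal design
    n_visits: int = 3
    visit_spacing_years: float = 2.35
    n_progression_patients: int = 336
    exam_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EXAMS.items()})
    seed: int = 0

    def validate(self) -> None:
        n_fixed = (self.n_clock_cpgs
                   + self.n_reference_cpgs_per_type * len(self.mixture_cell_types)
                   + 2 * self.n_age_cpgs)
        if self.n_clock_cpgs > self.n_cpgs_total:
            raise ConfigError("n_clock_cpgs exceeds n_cpgs_total")
        if n_fixed > self.n_cpgs_total:
            raise ConfigError(
                f"layout needs {n_fixed} CpGs but n_cpgs_total="
                f"{self.n_cpgs_total}")
        if self.n_cases + self.n_controls == 0:
            raise ConfigError("n_cases + n_controls must be positive")
        for name, rate in self.lineage_tick_rates.items():
            if rate < 0:
                raise ConfigError(f"negative tick rate for {name!r}")
        for ct in self.mixture_cell_types:
            if ct not in self.cell_types:
                raise ConfigError(f"mixture type {ct!r} not in cell_types")
            if self.proportion_concentration.get(ct, 0) <= 0:
                raise ConfigError(f"non-positive Dirichlet alpha for {ct!r}")
        if self.tick_increment_delta < 0 or self.noise_sd_logit < 0:
            raise ConfigError("negative delta or noise SD")
        if self.n_visits < 2:
            raise ConfigError("n_visits must be >= 2")


@dataclass
class TruthBundle:
    """Ground truth retained by the generators for recovery tests."""

    config: SimulationConfig
    seed: int
    proportions: pd.DataFrame | None = None  # sample x cell type
    division_counts: pd.DataFrame | None = None  # subject x cell type
    accel_true_sd: pd.Series | None = None  # standardized true acceleration
    true_disease_effect: float | None = None  # adjusted log-OR per SD target
    true_slopes: pd.DataFrame | None = None  # subject x exam total slope


@dataclass
class CellProfiles:
    """Baseline (age-zero) methylomes per cell type plus CpG block labels."""

    baseline: pd.DataFrame  # cpg x cell type
    clock_cpgs: list[str]
    reference_cpgs: list[str]
    hannum_cpgs: list[str]
    horvath_cpgs: list[str]
    age_baselines: pd.Series  # baseline beta of aging-block CpGs
    age_slopes: pd.Series  # beta gain per year of effective age

    def clock_definition(self, name: str = "epitoc-sim") -> ClockDefinition:
        return ClockDefinition(name=name, cpg_ids=list(self.clock_cpgs))

    def linear_clock(self, block: str, name: str) -> ClockDefinition:
        """Invert the aging block: weights recover effective age in years."""
        cpgs = self.hannum_cpgs if block == "hannum" else self.horvath_cpgs
        s = self.age_slopes.loc[cpgs].to_numpy()
        c = self.age_baselines.loc[cpgs].to_numpy()
        w = 1.0 / (len(cpgs) * s)
        intercept = -float(np.sum(w * c))
        return ClockDefinition(
            name=name, cpg_ids=list(cpgs), weights=w, intercept=intercept)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _mean_one_lognormal(
    rng: np.random.Generator, sd_log: float, size
) -> np.ndarray:
    """Lognormal multiplier with expectation exactly one."""
    return rng.lognormal(-0.5 * sd_log**2, sd_log, size=size)


def _logit_noise(
    values: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Measurement noise on the logit scale, clipped to [0.001, 0.999]."""
    clipped = np.clip(values, 1e-3, 1 - 1e-3)
    if sd == 0:
        return clipped
    noisy = expit(logit(clipped) + rng.normal(0.0, sd, size=clipped.shape))
    return np.clip(noisy, 1e-3, 1 - 1e-3)


def simulate_cell_profiles(config: SimulationConfig) -> CellProfiles:
    """Baseline per-cell-type methylomes and the CpG block layout.

    Clock CpGs start near-unmethylated (<= 0.05) identically in every
    type; each mixture cell type gets a block of discriminating reference
    CpGs; two blocks of aging-tracker CpGs gain beta linearly in effective
    age; the remainder is filler. Myeloid columns are globally depleted so
    the whole-methylome myeloid-minus-lymphoid mean equals
    ``-myeloid_depletion_shift`` at baseline.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_cpgs_total
    types = list(config.cell_types)
    cpg_ids = [f"cg{i:07d}" for i in range(n)]
    k_ref = config.n_reference_cpgs_per_type
    pos = 0
    clock = cpg_ids[pos:pos + config.n_clock_cpgs]; pos += config.n_clock_cpgs
    ref_blocks: dict[str, list[str]] = {}
    for ct in config.mixture_cell_types:
        ref_blocks[ct] = cpg_ids[pos:pos + k_ref]; pos += k_ref
    hannum = cpg_ids[pos:pos + config.n_age_cpgs]; pos += config.n_age_cpgs
    horvath = cpg_ids[pos:pos + config.n_age_cpgs]; pos += config.n_age_cpgs
    filler = cpg_ids[pos:]

    base = np.empty((n, len(types)))
    idx = {c: i for i, c in enumerate(cpg_ids)}

    clock_b0 = rng.uniform(0.003, 0.05, size=len(clock))
    base[:len(clock), :] = clock_b0[:, None]

    # granulocyte-subtype columns share the granulocyte fingerprint, which
    # also balances hyper-block counts across the two lineages
    fingerprint_sharers = {"granulocytes": ["neutrophils", "eosinophils"]}
    for ct, block in ref_blocks.items():
        rows = [idx[c] for c in block]
        hi = rng.uniform(0.70, 0.95, size=len(block))
        lo = rng.uniform(0.08, 0.30, size=(len(block), len(types)))
        base[rows, :] = lo
        for t in [ct] + fingerprint_sharers.get(ct, []):
            if t in types:
                base[rows, types.index(t)] = hi

    age_base = rng.uniform(0.25, 0.55, size=2 * config.n_age_cpgs)
    age_slope = rng.uniform(0.0015, 0.0035, size=2 * config.n_age_cpgs)
    for j, c in enumerate(hannum + horvath):
        base[idx[c], :] = age_base[j]

    rows = [idx[c] for c in filler]
    shared = rng.uniform(0.08, 0.92, size=len(filler))
    jitter = rng.normal(0.0, 0.01, size=(len(filler), len(types)))
    base[rows, :] = np.clip(shared[:, None] + jitter, 0.001, 0.999)

    # myeloid global depletion, scaled so the whole-methylome mean
    # difference equals the configured shift (clock CpGs are untouched)
    n_nonclock = n - len(clock)
    if n_nonclock > 0 and config.myeloid_depletion_shift != 0:
        shift = config.myeloid_depletion_shift * n / n_nonclock
        myeloid_cols = [i for i, t in enumerate(types)
                        if config.cell_types[t] == MYELOID]
        base[len(clock):, myeloid_cols] = np.clip(
            base[len(clock):, myeloid_cols] - shift, 0.001, 0.999)

    baseline = pd.DataFrame(base, index=cpg_ids, columns=types)
    return CellProfiles(
        baseline=baseline,
        clock_cpgs=clock,
        reference_cpgs=[c for b in ref_blocks.values() for c in b],
        hannum_cpgs=hannum,
        horvath_cpgs=horvath,
        age_baselines=pd.Series(age_base, index=hannum + horvath),
        age_slopes=pd.Series(age_slope, index=hannum + horvath),
    )


def _effective_age(config: SimulationConfig, age: np.ndarray) -> np.ndarray:
    """Division-years accumulated by a compartment of unit rate."""
    return config.development_years + config.adult_rate_scale * np.asarray(age)


def simulate_purified_panel(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, TruthBundle]:
    """One sample per (donor, cell type), ticked by lineage division rates.

    Clock betas are ``clip(b0 + delta * D)`` with divisions
    ``D = r_k * (A0 + kappa * age) * donor_frailty * cell_jitter``;
    logit-normal measurement noise is applied on top.
    """
    config.validate()
    profiles = simulate_cell_profiles(config)
    rng = _rng(config, 2)
    types = list(config.cell_types)
    delta = config.tick_increment_delta

    ages = np.clip(
        rng.normal(config.donor_age_mean_years, config.donor_age_sd_years,
                   size=config.n_donors_purified), 21.0, 70.0)
    frailty = _mean_one_lognormal(rng, config.frailty_sd_log,
                                  config.n_donors_purified)
    cell_jitter = _mean_one_lognormal(
        rng, config.cell_frailty_sd_log,
        (config.n_donors_purified, len(types)))
    rates = np.array([config.lineage_tick_rates[t] for t in types])
    eff_age = _effective_age(config, ages)
    divisions = rates[None, :] * eff_age[:, None] * frailty[:, None] * cell_jitter

    cols, meta = {}, []
    base = profiles.baseline
    age_rows = profiles.hannum_cpgs + profiles.horvath_cpgs
    for d in range(config.n_donors_purified):
        donor = f"donor{d + 1}"
        for k, ct in enumerate(types):
            vals = base[ct].copy()
            vals.loc[profiles.clock_cpgs] = np.clip(
                vals.loc[profiles.clock_cpgs] + delta * divisions[d, k],
                0.0, 1.0)
            vals.loc[age_rows] = np.clip(
                profiles.age_baselines + profiles.age_slopes * ages[d],
                0.001, 0.999)
            sid = f"{donor}_{ct.replace(' ', '')}"
            cols[sid] = vals.to_numpy()
            meta.append(dict(
                sample_id=sid, subject_id=donor, age_years=ages[d],
                sex="male", status="NA", cell_type_label=ct,
                lineage=config.cell_types[ct], visit_time_years=0.0))
    matrix = np.column_stack([cols[s] for s in cols])
    matrix = _logit_noise(matrix, config.noise_sd_logit, rng)
    beta = BetaMatrix(pd.DataFrame(
        matrix, index=base.index, columns=list(cols)))
    sheet = pd.DataFrame(meta)
    truth = TruthBundle(
        config=config, seed=config.seed,
        division_counts=pd.DataFrame(
            divisions, index=[f"donor{d + 1}" for d in range(len(ages))],
            columns=types))
    return beta, sheet, truth


def _case_alpha(config: SimulationConfig) -> np.ndarray:
    """Dirichlet parameters for cases: granulocyte mean shifted upward,
    other types rescaled, total concentration preserved."""
    types = config.mixture_cell_types
    alpha = np.array([config.proportion_concentration[t] for t in types])
    total = alpha.sum()
    mean = alpha / total
    g = types.index("granulocytes")
    new_mean = mean.copy()
    new_g = min(mean[g] + config.case_granulocyte_shift, 0.95)
    scale = (1.0 - new_g) / (1.0 - mean[g])
    new_mean *= scale
    new_mean[g] = new_g
    return new_mean * total


def simulate_whole_blood_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, ControlProbeMatrix, TruthBundle]:
    """Case-control whole-blood mixtures with confounding-by-composition.

    Cases' division counts are multiplied by ``disease_tick_multiplier``
    and their leukocyte proportions are shifted toward granulocytes, so
    the unadjusted acceleration-disease association is masked while the
    composition-adjusted one recovers the calibrated effect
    (``target_adjusted_log_or_per_sd``).
    """
    config.validate()
    profiles = simulate_cell_profiles(config)
    rng = _rng(config, 3)
    n = config.n_cases + config.n_controls
    types = config.mixture_cell_types
    delta = config.tick_increment_delta

    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    order = rng.permutation(n)
    status = status[order]
    is_case = status == "case"

    lo, hi = config.age_range_years
    age = rng.uniform(lo, hi, size=n)
    male_p = np.where(is_case, config.male_fraction_cases,
                      config.male_fraction_controls)
    sex = np.where(rng.uniform(size=n) < male_p, "male", "female")
    ancestry = np.where(
        rng.uniform(size=n) < np.where(is_case, 0.82, 0.96),
        "European", "Hispanic")
    smoking = rng.choice(["never", "former", "current"], size=n,
                         p=[0.48, 0.46, 0.06])
    wave = rng.choice(["wave1", "wave2"], size=n)
    education = rng.choice(["<=12y", "13-16y", ">16y"], size=n,
                           p=[0.45, 0.40, 0.15])

    alpha_ctrl = np.array([config.proportion_concentration[t] for t in types])
    alpha_case = _case_alpha(config)
    W = np.empty((n, len(types)))
    for i in range(n):
        W[i] = rng.dirichlet(alpha_case if is_case[i] else alpha_ctrl)

    frailty = _mean_one_lognormal(rng, config.frailty_sd_log, n)
    mult = np.where(is_case, config.disease_tick_multiplier, 1.0)
    rates = np.array([config.lineage_tick_rates[t] for t in types])
    eff_age = _effective_age(config, age)
    # divisions per compartment and their composition-weighted mixture rate
    D = rates[None, :] * eff_age[:, None] * frailty[:, None] * mult[:, None]
    mix_divisions = (W * D).sum(axis=1)
    offset = rng.normal(0.0, config.clock_baseline_offset_sd, size=n)

    base = profiles.baseline
    sample_ids = [f"WB{i + 1:04d}" for i in range(n)]
    n_clock = len(profiles.clock_cpgs)
    clock_b0 = base[types[0]].to_numpy()[:n_clock]  # identical across types
    M = np.empty((config.n_cpgs_total, n))
    M[:n_clock, :] = np.clip(
        clock_b0[:, None] + offset[None, :] + delta * mix_divisions[None, :],
        0.0, 1.0)
    P = base[types].to_numpy()[n_clock:, :]  # non-clock rows, mixture types
    M[n_clock:, :] = P @ W.T

    # aging-tracker blocks overwrite the mixed values: they track effective
    # ages, not composition
    idx = {c: i for i, c in enumerate(base.index)}
    immune_age = (age
                  + config.eeaa_frailty_years * (frailty - 1.0)
                  + rng.normal(0.0, config.eeaa_noise_sd_years, size=n)
                  + np.where(is_case, config.eeaa_case_shift_years, 0.0))
    tissue_age = (age
                  + rng.normal(0.0, config.ieaa_noise_sd_years, size=n)
                  + np.where(is_case, config.ieaa_case_shift_years, 0.0))
    for block, eff in ((profiles.hannum_cpgs, immune_age),
                       (profiles.horvath_cpgs, tissue_age)):
        rows = [idx[c] for c in block]
        b0 = profiles.age_baselines.loc[block].to_numpy()
        sl = profiles.age_slopes.loc[block].to_numpy()
        M[rows, :] = np.clip(b0[:, None] + sl[:, None] * eff[None, :],
                             0.001, 0.999)

    M = _logit_noise(M, config.noise_sd_logit, rng)
    beta = BetaMatrix(pd.DataFrame(M, index=base.index, columns=sample_ids))

    # control probes with batch (wave) and continuous position structure
    n_cp = config.n_control_probes
    cp_base = rng.uniform(0.2, 0.8, size=n_cp)
    batch_load = rng.normal(0.0, config.batch_effect_sd, size=n_cp)
    pos_load = rng.normal(0.0, config.position_effect_sd, size=n_cp)
    position = rng.uniform(-1.0, 1.0, size=n)
    batch = (wave == "wave2").astype(float)
    CP = (cp_base[:, None]
          + batch_load[:, None] * batch[None, :]
          + pos_load[:, None] * position[None, :]
          + rng.normal(0.0, config.control_probe_noise_sd, size=(n_cp, n)))
    controls = ControlProbeMatrix(pd.DataFrame(
        np.clip(CP, 0.0, 1.0),
        index=[f"ctrl{i + 1:04d}" for i in range(n_cp)],
        columns=sample_ids))

    sheet = pd.DataFrame(dict(
        sample_id=sample_ids,
        subject_id=[s.replace("WB", "subj") for s in sample_ids],
        age_years=age, sex=sex, status=status, ancestry_label=ancestry,
        smoking=smoking, wave=wave, education=education,
        pd_duration_years=np.where(
            is_case, np.clip(rng.normal(2.7, 2.0, size=n), 0.1, None), np.nan),
        visit_time_years=0.0))

    # true acceleration: noiseless expected score, residualized on age
    mu = clock_b0.mean() + offset + delta * mix_divisions
    X = np.column_stack([np.ones(n), age])
    coef, *_ = np.linalg.lstsq(X, mu, rcond=None)
    resid = mu - X @ coef
    accel_sd = (resid - resid.mean()) / resid.std(ddof=1)

    truth = TruthBundle(
        config=config, seed=config.seed,
        proportions=pd.DataFrame(W, index=sample_ids, columns=types),
        division_counts=pd.DataFrame(
            D, index=sheet["subject_id"], columns=types),
        accel_true_sd=pd.Series(
            accel_sd, index=sheet["subject_id"], name="accel_true_sd"),
        true_disease_effect=config.target_adjusted_log_or_per_sd)
    return beta, sheet, controls, truth


def simulate_longitudinal_scores(
    config: SimulationConfig,
    truth: TruthBundle,
    sheet: pd.DataFrame,
    accel_sd: pd.Series | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Visit records with exam scores whose slopes depend on acceleration.

    ``score_it = b0 + rint_i + (time_slope + slope_per_sd * accel_i +
    rslope_i) * t + eps``. Uses the generator's true standardized
    acceleration unless ``accel_sd`` overrides it. Returns a long-format
    visit sheet (patients only) and the truth bundle augmented with the
    per-subject total slopes.
    """
    config.validate()
    rng = _rng(config, 4)
    if accel_sd is None:
        if truth.accel_true_sd is None:
            raise DataError("truth bundle lacks accel_true_sd")
        accel_sd = truth.accel_true_sd
    patients = sheet[sheet["status"] == "case"].head(
        config.n_progression_patients)
    missing = set(patients["subject_id"]) - set(accel_sd.index)
    if missing:
        raise DataError(f"no true acceleration for subjects {sorted(missing)[:3]}")
    times = np.arange(config.n_visits) * config.visit_spacing_years
    rows = []
    slope_records = {}
    for _, p in patients.iterrows():
        subj = p["subject_id"]
        a = float(accel_sd.loc[subj])
        slopes = {}
        scores = {}
        for exam, par in config.exam_params.items():
            rint = rng.normal(0.0, par["rint_sd"])
            rslope = rng.normal(0.0, par["rslope_sd"])
            slope = par["time_slope"] + par["slope_per_sd"] * a + rslope
            eps = rng.normal(0.0, par["resid_sd"], size=config.n_visits)
            baseline_eps = rng.normal(0.0, par["resid_sd"])
            scores[exam] = par["baseline_mean"] + rint + slope * times + eps
            scores[f"baseline_{exam}"] = par["baseline_mean"] + rint + baseline_eps
            slopes[exam] = slope
        slope_records[subj] = slopes
        for v, t in enumerate(times):
            row = dict(
                sample_id=f"{subj}_v{v}", subject_id=subj,
                age_years=float(p["age_years"]) + t,
                baseline_age_years=float(p["age_years"]),
                sex=p["sex"], status=p["status"],
                ancestry_label=p.get("ancestry_label"),
                smoking=p.get("smoking"), wave=p.get("wave"),
                education=p.get("education"),
                pd_duration_years=p.get("pd_duration_years"),
                visit_time_years=float(t), accel_sd=a)
            for exam in config.exam_params:
                row[exam] = float(scores[exam][v])
                row[f"baseline_{exam}"] = float(scores[f"baseline_{exam}"])
            rows.append(row)
    visits = pd.DataFrame(rows)
    truth_out = replace(
        truth,
        true_slopes=pd.DataFrame(slope_records).T.rename_axis("subject_id"))
    return visits, truth_out


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config (for YAML round-tripping/manifests)."""
    d = asdict(config)
    d["age_range_years"] = list(d["age_range_years"])
    return d


def config_from_dict(data: Mapping) -> SimulationConfig:
    known = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(data)
    if "age_range_years" in d:
        d["age_range_years"] = tuple(d["age_range_years"])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
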