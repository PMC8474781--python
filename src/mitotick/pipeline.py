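"""End-to-end orchestration: simulate/import -> clocks -> deconvolve ->
associate/progress -> correlation panel, with a reproducibility manifest.

A single YAML config drives the run. Two input modes:

* ``simulate:`` — a block of :class:`SimulationConfig` overrides; the
  cohort, purified reference panel, longitudinal visits and ground truth
  are generated in-process.
* ``inputs:`` — paths to a beta matrix, sample sheet and (optionally)
  control probes plus a cell-type reference and clock file for real data.

Every numerical output is a tidy TSV in the output directory; the
manifest records the config hash, input digests, seed, package version,
per-stage timings and the output inventory. Identical config + seed
gives identical outputs (and manifest hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clocks import (
    build_accel_table,
    packaged_clock,
    read_clock_definition,
)
from .deconvolution import build_reference, estimate_proportions, read_reference
from .exceptions import ConfigError, DataError
from .inference import (
    ModelSpec,
    fit_lmm_progression,
    fit_logistic,
    pearson_corr_matrix,
)
from .io import (
    align,
    read_beta_matrix,
    read_control_probes,
    read_sample_sheet,
    technical_pcs,
    write_beta_matrix,
    write_control_probes,
    write_sample_sheet,
)
from .synthetic_data import (
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    simulate_cell_profiles,
    simulate_longitudinal_scores,
    simulate_purified_panel,
    simulate_whole_blood_cohort,
)

log = logging.getLogger("mitotick")


@dataclass
class RunManifest:
    """Provenance record; identical hash implies identical outputs."""

    config_hash: str
    seed: int
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def demo_config_path() -> Path:
    """Path of the packaged demo pipeline configuration."""
    return Path(__file__).parent / "data" / "demo_pipeline.yaml"


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Structural validation used by --dry-run and at run start."""
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ConfigError(
            "config needs exactly one of a 'simulate' block or an "
            "'inputs' block")
    if has_sim:
        config_from_dict({**cfg.get("simulate", {}),
                          "seed": int(cfg.get("seed", 0))})
    else:
        inputs = cfg["inputs"]
        for key in ("beta", "sheet"):
            if key not in inputs:
                raise ConfigError(f"inputs block lacks {key!r}")
            if not Path(inputs[key]).exists():
                raise DataError(f"input file not found: {inputs[key]}")
        if cfg.get("associate", {}).get("enabled", True):
            if "reference" not in inputs:
                raise ConfigError(
                    "stage 'associate' requires cell composition: provide "
                    "inputs.reference (purified-cell reference) or a "
                    "simulate block")
    if "associate" in cfg and "model" in cfg["associate"]:
        ModelSpec.from_dict(cfg["associate"]["model"])


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute the full analysis described by ``config`` into ``out_dir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest = RunManifest(
        config_hash=_sha256_text(
            json.dumps(config, sort_keys=True, default=str) + f"|seed={seed}"),
        seed=seed, package_version=__version__)

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=index, na_rep="NA")
        manifest.outputs.append(name)
        log.info("wrote %s (%d rows)", name, len(frame))

    try:
        t0 = time.perf_counter()
        sim_mode = "simulate" in config
        truth = None
        visits = None
        if sim_mode:
            sim_cfg = config_from_dict(
                {**config.get("simulate", {}), "seed": seed})
            beta, sheet, controls, truth = simulate_whole_blood_cohort(sim_cfg)
            pbeta, psheet, _ = simulate_purified_panel(sim_cfg)
            profiles = simulate_cell_profiles(sim_cfg)
            clock = profiles.clock_definition()
            reference = build_reference(
                pbeta, psheet, cell_types=sim_cfg.mixture_cell_types)
            visits, truth = simulate_longitudinal_scores(sim_cfg, truth, sheet)
            emit("truth_proportions.tsv", truth.proportions)
            (out / "resolved_simulation_config.yaml").write_text(
                yaml.safe_dump(config_to_dict(sim_cfg)))
            manifest.outputs.append("resolved_simulation_config.yaml")
            mixture_types = sim_cfg.mixture_cell_types
        else:
            inputs = config["inputs"]
            for key, path in inputs.items():
                manifest.input_digests[key] = _sha256_file(path)
            beta = read_beta_matrix(
                inputs["beta"], dialect=inputs.get("dialect", "plain"))
            sheet = read_sample_sheet(inputs["sheet"])
            beta, sheet = align(beta, sheet)
            controls = (read_control_probes(inputs["controls"])
                        if "controls" in inputs else None)
            clock = (read_clock_definition(inputs["clock"])
                     if "clock" in inputs else packaged_clock())
            reference = (read_reference(inputs["reference"])
                         if "reference" in inputs else None)
            mixture_types = list(reference.cell_types) if reference else []
        manifest.stage_seconds["import"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        composition = None
        if reference is not None:
            composition = estimate_proportions(
                beta, reference,
                mode=config.get("deconvolve", {}).get("mode", "sum-to-one"))
            emit("cell_composition.tsv", composition)
        manifest.stage_seconds["deconvolve"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        linear_clocks = []
        eeaa_name = None
        if sim_mode:
            linear_clocks = [profiles.linear_clock("horvath", "horvath_sim"),
                             profiles.linear_clock("hannum", "hannum_sim")]
            eeaa_name = "hannum_sim"
        cells_for_accel = (composition[mixture_types]
                           if composition is not None else None)
        accel = build_accel_table(
            beta, sheet, clock, linear_clocks=linear_clocks,
            cell_composition=cells_for_accel, eeaa_clock=eeaa_name)
        emit("accel_table.tsv", accel)
        manifest.stage_seconds["clocks"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        data = sheet.set_index(sheet["sample_id"].astype(str)).copy()
        data["accel_sd"] = accel["accel_epitoc_sd"]
        if composition is not None:
            for ct in mixture_types:
                data[ct.replace(" ", "_")] = composition[ct]
        if controls is not None:
            pcs = technical_pcs(controls, n_components=2)
            data[["PC1", "PC2"]] = pcs.scores
        emit("analysis_data.tsv", data, index=False)

        assoc_cfg = config.get("associate", {})
        if assoc_cfg.get("enabled", True) and "status" in data.columns \
                and data["status"].nunique() == 2 and composition is not None:
            cell_cols = [c.replace(" ", "_") for c in mixture_types][:-1]
            base_terms = ["accel_sd", "age_years", "sex"]
            if "PC1" in data.columns:
                base_terms += ["PC1", "PC2"]
            if "model" in assoc_cfg:
                spec = ModelSpec.from_dict(assoc_cfg["model"])
            else:
                spec = ModelSpec(outcome="status",
                                 terms=base_terms + cell_cols,
                                 per_sd=cell_cols)
            adjusted = fit_logistic(data.reset_index(drop=True), spec)
            emit("fit_association_adjusted.tsv", adjusted.table, index=False)
            unadj = fit_logistic(
                data.reset_index(drop=True),
                ModelSpec(outcome="status", terms=base_terms))
            emit("fit_association_unadjusted.tsv", unadj.table, index=False)
        manifest.stage_seconds["associate"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        if visits is not None:
            sim_cfg_exams = list(sim_cfg.exam_params)
            for exam in config.get("progress", {}).get("exams", sim_cfg_exams):
                spec = ModelSpec(
                    outcome=exam, family="gaussian",
                    terms=["accel_sd", "visit_time_years",
                           "baseline_age_years", "sex", f"baseline_{exam}"],
                    interactions=[("accel_sd", "visit_time_years")],
                    random=["intercept", "time"])
                fit = fit_lmm_progression(visits, spec)
                emit(f"fit_progression_{exam}.tsv", fit.table, index=False)
        manifest.stage_seconds["progress"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        corr_cols = ["pcgt_age", "accel_epitoc_raw"]
        panel = accel[corr_cols].copy()
        panel["age_years"] = data["age_years"]
        if composition is not None:
            for ct in mixture_types:
                panel[ct] = composition[ct]
        for extra in ("eeaa", "ieaa"):
            if extra in accel.columns:
                panel[extra] = accel[extra]
        R, P = pearson_corr_matrix(panel)
        emit("correlations.tsv", R)
        emit("correlation_pvalues.tsv", P)
        manifest.stage_seconds["corr"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest.write(out / "manifest.json")
    return manifest


def analyze_synthetic_cohort(sim_cfg: SimulationConfig, reference=None) -> dict:
    """Simulate a cohort and run the case-control analysis in memory.

    Returns the intermediate objects plus the composition-adjusted and
    unadjusted logistic fits (acceleration per SD). Used by higher-level
    reporting and by the validation suite; ``reference`` can be shared
    across replicates since in practice the purified-cell reference is an
    external input.
    """
    from .clocks import age_acceleration, pcgt_age, standardize_sd

    beta, sheet, controls, truth = simulate_whole_blood_cohort(sim_cfg)
    profiles = simulate_cell_profiles(sim_cfg)
    clock = profiles.clock_definition()
    if reference is None:
        pbeta, psheet, _ = simulate_purified_panel(sim_cfg)
        reference = build_reference(
            pbeta, psheet, cell_types=sim_cfg.mixture_cell_types)
    props = estimate_proportions(beta, reference)
    pcs = technical_pcs(controls, n_components=2)
    ages = pd.Series(sheet["age_years"].to_numpy(dtype=float),
                     index=sheet["sample_id"].astype(str))
    pa = pcgt_age(beta, clock)
    accel = age_acceleration(pa["pcgt_age"], ages)
    accel_sd = standardize_sd(accel.residuals)

    data = sheet.set_index(sheet["sample_id"].astype(str)).copy()
    data["pcgt_age"] = pa["pcgt_age"]
    data["accel_raw"] = accel.residuals
    data["accel_sd"] = accel_sd
    for ct in sim_cfg.mixture_cell_types:
        data[ct.replace(" ", "_")] = props[ct]
    data[["PC1", "PC2"]] = pcs.scores
    cell_cols = [c.replace(" ", "_")
                 for c in sim_cfg.mixture_cell_types][:-1]
    base_terms = ["accel_sd", "age_years", "sex", "PC1", "PC2"]
    adjusted = fit_logistic(
        data.reset_index(drop=True),
        ModelSpec(outcome="status", terms=base_terms + cell_cols,
                  per_sd=cell_cols))
    unadjusted = fit_logistic(
        data.reset_index(drop=True),
        ModelSpec(outcome="status", terms=base_terms))
    return dict(beta=beta, sheet=sheet, controls=controls, truth=truth,
                profiles=profiles, clock=clock, reference=reference,
                proportions=props, pcs=pcs, data=data,
                adjusted=adjusted, unadjusted=unadjusted)


def format_report(out_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {out}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"mitotick run report — {out}",
        f"package {manifest['package_version']}, seed {manifest['seed']}",
        f"config hash {manifest['config_hash'][:16]}…",
        "stage timings (s): " + ", ".join(
            f"{k}={v}" for k, v in manifest["stage_seconds"].items()),
        "",
    ]
    for name in manifest["outputs"]:
        path = out / name
        if not name.endswith(".tsv") or not path.exists():
            continue
        df = pd.read_csv(path, sep="\t")
        lines.append(f"== {name} ({len(df)} rows) ==")
        if name.startswith("fit_"):
            show = df[[c for c in ("term", "estimate", "standard_error",
                                   "odds_ratio", "p_value") if c in df.columns]]
            lines.append(show.to_string(index=False,
                                        float_format=lambda v: f"{v: .4g}"))
        else:
            lines.append(df.head(5).to_string(index=False))
        lines.append("")
    return "\n".join(lines)
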