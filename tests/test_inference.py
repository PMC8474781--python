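import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm
from dataclasses import replace

from mitotick import (
    ModelSpec,
    fit_lmm_celltype,
    fit_lmm_progression,
    fit_logistic,
    paired_difference,
    pearson_corr_matrix,
    simulate_longitudinal_scores,
    stepwise_aic,
    stratify,
)
from mitotick.exceptions import ConfigError, DataError, SeparationError


class TestCellTypeModel:
    def _sheet(self, n_subj, types, values):
        rows = []
        for s in range(n_subj):
            for t in types:
                rows.append(dict(
                    sample_id=f"d{s}_{t}", subject_id=f"d{s}",
                    cell_type_label=t,
                    lineage="myeloid" if t in ("gran", "mono") else "lymphoid"))
        sheet = pd.DataFrame(rows)
        vals = pd.Series(values, index=sheet["sample_id"])
        return sheet, vals

    def test_identical_celltypes_give_null_contrasts(self):
        types = ["gran", "mono", "cd8", "b"]
        sheet, vals = self._sheet(4, types, np.repeat(0.3, 16))
        fit = fit_lmm_celltype(vals, sheet, reference_level="cd8")
        contrasts = fit.table[fit.table["term"] != "intercept"]
        np.testing.assert_allclose(contrasts["estimate"], 0, atol=1e-10)

    def test_balanced_design_equals_group_mean_contrasts(self, rng):
        """On a complete balanced panel the mixed-model fixed effects are
        exactly the group-mean differences."""
        types = ["gran", "mono", "cd8", "b"]
        n_subj = 6
        subj_eff = rng.normal(0, 0.02, n_subj)
        type_eff = {"gran": 0.0, "mono": 0.01, "cd8": 0.08, "b": 0.06}
        values = [0.1 + subj_eff[s] + type_eff[t] + rng.normal(0, 0.005)
                  for s in range(n_subj) for t in types]
        sheet, vals = self._sheet(n_subj, types, values)
        fit = fit_lmm_celltype(vals, sheet, reference_level="cd8")
        df = sheet.assign(y=vals.to_numpy())
        means = df.groupby("cell_type_label")["y"].mean()
        for t in ("b", "gran", "mono"):
            assert fit.term(f"cell_type[{t}]")["estimate"] == pytest.approx(
                means[t] - means["cd8"], abs=1e-8)

    def test_lineage_contrast_sign(self, rng):
        types = ["gran", "mono", "cd8", "b"]
        values = [0.05 if t in ("gran", "mono") else 0.12 + rng.normal(0, 0.004)
                  for _ in range(5) for t in types]
        sheet, vals = self._sheet(5, types, values)
        fit = fit_lmm_celltype(vals, sheet, contrast="lineage")
        assert fit.term("lineage[myeloid]")["estimate"] < -0.05
        assert fit.n_subjects == 5

    def test_unknown_reference_rejected(self, rng):
        sheet, vals = self._sheet(3, ["gran", "cd8"], rng.uniform(0, 1, 6))
        with pytest.raises(ConfigError):
            fit_lmm_celltype(vals, sheet, reference_level="nope")


class TestPairedDifference:
    def test_identical_vectors(self):
        x = pd.Series([0.1, 0.2, 0.3])
        out = paired_difference(x, x)
        assert out["mean_difference"] == 0.0
        assert out["t"] == 0.0

    def test_two_pair_closed_form(self):
        a = pd.Series([0.16, 0.30])
        b = pd.Series([0.10, 0.20])
        out = paired_difference(a, b)
        d = np.array([0.06, 0.10])
        se = d.std(ddof=1) / np.sqrt(2)
        tq = st.t.ppf(0.975, 1)
        assert out["mean_difference"] == pytest.approx(0.08)
        assert out["ci_low"] == pytest.approx(0.08 - tq * se)
        assert out["ci_high"] == pytest.approx(0.08 + tq * se)

    def test_antisymmetry(self, rng):
        a = pd.Series(rng.uniform(0, 1, 12))
        b = pd.Series(rng.uniform(0, 1, 12))
        ab, ba = paired_difference(a, b), paired_difference(b, a)
        assert ab["mean_difference"] == pytest.approx(-ba["mean_difference"])
        assert ab["p_value"] == pytest.approx(ba["p_value"])

    def test_constant_nonzero_difference_flagged(self):
        a = pd.Series([1.0, 2.0, 3.0])
        out = paired_difference(a + 0.5, a)
        assert out["mean_difference"] == 0.5
        assert np.isnan(out["p_value"])


def _two_by_two(a, b, c, d):
    """exposed/unexposed x case/control counts -> long data frame."""
    rows = ([dict(status="case", x=1.0)] * a
            + [dict(status="control", x=1.0)] * b
            + [dict(status="case", x=0.0)] * c
            + [dict(status="control", x=0.0)] * d)
    return pd.DataFrame(rows)


class TestLogistic:
    def test_two_by_two_matches_cross_product_or(self):
        a, b, c, d = 20, 10, 10, 20
        fit = fit_logistic(_two_by_two(a, b, c, d),
                           ModelSpec(outcome="status", terms=["x"]))
        row = fit.term("x")
        assert row["odds_ratio"] == pytest.approx(a * d / (b * c), rel=1e-6)
        assert row["standard_error"] == pytest.approx(
            np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-6)

    def test_balanced_predictor_gives_unit_or(self):
        fit = fit_logistic(_two_by_two(15, 15, 15, 15),
                           ModelSpec(outcome="status", terms=["x"]))
        assert fit.term("x")["odds_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_per_sd_or_invariant_to_predictor_scale(self, rng):
        n = 400
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 * x)))
        y = (rng.uniform(size=n) < p).astype(float)
        base = pd.DataFrame({"status": y, "x": x})
        spec = ModelSpec(outcome="status", terms=["x"], per_sd=["x"])
        or1 = fit_logistic(base, spec).term("x")["odds_ratio"]
        scaled = base.assign(x=base["x"] * 37.5)
        or2 = fit_logistic(scaled, spec).term("x")["odds_ratio"]
        assert or1 == pytest.approx(or2, rel=1e-10)

    def test_perfect_separation_detected(self):
        data = pd.DataFrame({
            "status": ["case"] * 10 + ["control"] * 10,
            "x": np.concatenate([np.ones(10), np.zeros(10)])})
        with pytest.raises(SeparationError):
            fit_logistic(data, ModelSpec(outcome="status", terms=["x"]))

    def test_categorical_coding_against_modal_level(self, rng):
        n = 300
        sex = rng.choice(["female", "male"], size=n, p=[0.7, 0.3])
        y = (rng.uniform(size=n) < 0.4).astype(float)
        fit = fit_logistic(pd.DataFrame({"status": y, "sex": sex}),
                           ModelSpec(outcome="status", terms=["sex"]))
        assert "sex[male]" in set(fit.table["term"])


class TestStepwiseAIC:
    def _data(self, rng, n=300):
        x = rng.normal(size=(n, 5))
        lp = 0.8 * x[:, 0] - 0.6 * x[:, 1]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(float)
        df = pd.DataFrame(x, columns=[f"v{i}" for i in range(5)])
        df["status"] = y
        return df

    def test_empty_candidates_return_locked_model(self, rng):
        df = self._data(rng)
        spec = ModelSpec(outcome="status", terms=["v0"])
        selected, trace = stepwise_aic(df, spec, candidates=[])
        assert selected.terms == ["v0"]
        assert len(trace) == 1

    def test_trace_monotone_and_matches_independent_greedy(self, rng):
        """Greedy AIC path reproduced by an independent reimplementation;
        all-subsets enumeration bounds the selected AIC."""
        df = self._data(rng)
        candidates = [f"v{i}" for i in range(5)]
        spec = ModelSpec(outcome="status", terms=[])
        selected, trace = stepwise_aic(df, spec, candidates=candidates)
        aics = trace["aic"].to_numpy()
        assert (np.diff(aics) < 0).all()

        def aic_of(terms):
            X = sm.add_constant(df[sorted(terms)]) if terms else \
                pd.DataFrame({"const": np.ones(len(df))})
            return sm.Logit(df["status"], X).fit(disp=0).aic

        # independent greedy
        cur, cur_aic = set(), aic_of(set())
        while True:
            moves = []
            for c in candidates:
                nxt = cur - {c} if c in cur else cur | {c}
                moves.append((aic_of(nxt), c))
            moves.sort()
            if cur_aic - moves[0][0] <= 1e-6:
                break
            cur = cur - {moves[0][1]} if moves[0][1] in cur else cur | {moves[0][1]}
            cur_aic = moves[0][0]
        assert set(selected.terms) == cur
        assert trace["aic"].iloc[-1] == pytest.approx(cur_aic, abs=1e-6)
        # exhaustive all-subsets lower bound
        global_min = min(
            aic_of(set(sub)) for r in range(6)
            for sub in itertools.combinations(candidates, r))
        assert trace["aic"].iloc[-1] >= global_min - 1e-9

    def test_result_invariant_to_candidate_order(self, rng):
        df = self._data(rng)
        spec = ModelSpec(outcome="status", terms=[])
        cands = [f"v{i}" for i in range(5)]
        s1, _ = stepwise_aic(df, spec, candidates=cands)
        s2, _ = stepwise_aic(df, spec, candidates=list(reversed(cands)))
        assert s1.terms == s2.terms

    def test_selects_the_rate_divergent_cell_types(self):
        """On cohorts where only granulocytes (slow) and CD8 T (fast)
        deviate from the common division rate, stepwise AIC retains those
        two as the sufficient composition adjustment in >= 90% of seeds."""
        from mitotick import SimulationConfig
        from mitotick.pipeline import analyze_synthetic_cohort

        rates = {"granulocytes": 0.7, "neutrophils": 1.9, "eosinophils": 1.9,
                 "monocytes": 1.9, "B cells": 1.9, "CD4 T": 1.9,
                 "CD8 T": 4.0, "NK": 1.9}
        base = SimulationConfig(
            n_cpgs_total=1200, n_clock_cpgs=100,
            n_reference_cpgs_per_type=20, n_age_cpgs=20, n_control_probes=50,
            n_cases=300, n_controls=300, lineage_tick_rates=rates)
        cells = ["granulocytes", "monocytes", "B_cells", "CD4_T",
                 "CD8_T", "NK"]
        both = 0
        for s in range(50):
            cfg = replace(base, seed=3000 + s)
            data = analyze_synthetic_cohort(cfg)["data"].reset_index(drop=True)
            spec = ModelSpec(outcome="status",
                             terms=["accel_sd", "age_years", "sex"])
            selected, trace = stepwise_aic(data, spec, candidates=cells)
            assert (np.diff(trace["aic"]) < 0).all()
            if {"granulocytes", "CD8_T"} <= set(selected.terms):
                both += 1
        assert both >= 45

    def test_locked_terms_never_dropped(self, rng):
        df = self._data(rng)
        df["noise"] = rng.normal(size=len(df))
        spec = ModelSpec(outcome="status", terms=["noise"])
        selected, _ = stepwise_aic(df, spec, candidates=["v0", "v1"])
        assert "noise" in selected.terms


class TestProgressionModel:
    def _spec(self, outcome="MMSE"):
        return ModelSpec(
            outcome=outcome, family="gaussian",
            terms=["accel_sd", "visit_time_years", "baseline_age_years",
                   f"baseline_{outcome}"],
            interactions=[("accel_sd", "visit_time_years")],
            random=["intercept", "time"])

    def test_deterministic_limit_recovers_interaction_exactly(
            self, small_cfg, cohort):
        exams = {"MMSE": dict(baseline_mean=28.0, rint_sd=0.0,
                              time_slope=-0.2, slope_per_sd=-0.06,
                              rslope_sd=0.0, resid_sd=0.0)}
        cfg = replace(small_cfg, exam_params=exams)
        _, sheet, _, truth = cohort
        visits, _ = simulate_longitudinal_scores(cfg, truth, sheet)
        # baseline covariate is constant in the deterministic limit
        spec = ModelSpec(
            outcome="MMSE", family="gaussian",
            terms=["accel_sd", "visit_time_years", "baseline_age_years"],
            interactions=[("accel_sd", "visit_time_years")],
            random=["intercept", "time"])
        with pytest.warns(UserWarning):  # singular mixed fit -> OLS fallback
            fit = fit_lmm_progression(visits, spec)
        est = fit.term("accel_sd:visit_time_years")["estimate"]
        assert est == pytest.approx(-0.06, abs=1e-6)

    def test_null_interaction_when_slopes_independent(self, small_cfg, cohort):
        covered = 0
        _, sheet, _, truth = cohort
        for seed in range(6):
            exams = {"MMSE": dict(baseline_mean=28.0, rint_sd=1.5,
                                  time_slope=-0.2, slope_per_sd=0.0,
                                  rslope_sd=0.2, resid_sd=1.5)}
            cfg = replace(small_cfg, exam_params=exams, seed=100 + seed)
            visits, _ = simulate_longitudinal_scores(cfg, truth, sheet)
            fit = fit_lmm_progression(visits, self._spec())
            row = fit.term("accel_sd:visit_time_years")
            if row["ci_low"] <= 0.0 <= row["ci_high"]:
                covered += 1
        assert covered >= 5

    def test_single_visit_design_rejected(self, small_cfg, cohort):
        _, sheet, _, truth = cohort
        visits, _ = simulate_longitudinal_scores(small_cfg, truth, sheet)
        baseline_only = visits[visits["visit_time_years"] == 0.0]
        with pytest.raises(DataError):
            fit_lmm_progression(baseline_only, self._spec())


class TestCorrelationPanel:
    def test_affine_pair_perfectly_correlated(self):
        x = pd.Series(np.linspace(0, 1, 20))
        R, P = pearson_corr_matrix(pd.DataFrame({"x": x, "y": 2 * x + 1}))
        assert R.loc["x", "y"] == pytest.approx(1.0)
        assert P.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_permutation_near_zero(self, rng):
        x = rng.normal(size=1000)
        R, _ = pearson_corr_matrix(pd.DataFrame(
            {"x": x, "y": rng.permutation(x)}))
        assert abs(R.loc["x", "y"]) < 0.1

    def test_matches_covariance_formula_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 8)),
                          columns=[f"c{i}" for i in range(8)])
        R, _ = pearson_corr_matrix(df)
        for i in range(8):
            for j in range(8):
                xi, xj = df.iloc[:, i], df.iloc[:, j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean())**2).sum()
                              * ((xj - xj.mean())**2).sum())
                assert R.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_partial_correlation_removes_shared_covariate(self, rng):
        n = 2000
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = -z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        R_raw, _ = pearson_corr_matrix(df)
        R_part, _ = pearson_corr_matrix(df, partial_on=pd.DataFrame({"z": z}))
        assert R_raw.loc["x", "y"] < -0.3
        assert abs(R_part.loc["x", "y"]) < 0.08

    def test_zero_variance_column_flagged(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            R, _ = pearson_corr_matrix(df)
        assert np.isnan(R.loc["x", "c"])


class TestStratify:
    def test_identical_strata_give_identical_estimates(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(float)
        one = pd.DataFrame({"status": y, "x": x, "sex": "male"})
        two = one.assign(sex="female")
        data = pd.concat([one, two], ignore_index=True)
        spec = ModelSpec(outcome="status", terms=["x"])
        fits = stratify(data, "sex", lambda d: fit_logistic(d, spec))
        assert fits["male"].term("x")["estimate"] == pytest.approx(
            fits["female"].term("x")["estimate"], abs=1e-10)

    def test_strata_partition_the_sample(self, rng):
        n = 150
        data = pd.DataFrame({
            "status": rng.integers(0, 2, n).astype(float),
            "x": rng.normal(size=n),
            "sex": rng.choice(["male", "female"], n)})
        spec = ModelSpec(outcome="status", terms=["x"])
        fits = stratify(data, "sex", lambda d: fit_logistic(d, spec))
        assert sum(f.n_obs for f in fits.values()) == n

    def test_sex_modified_effect_ordering_recovered(self, rng):
        n = 3000
        sex = rng.choice(["male", "female"], n)
        x = rng.normal(size=n)
        slope = np.where(sex == "male", 1.2, 0.3)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-slope * x))).astype(float)
        data = pd.DataFrame({"status": y, "x": x, "sex": sex})
        spec = ModelSpec(outcome="status", terms=["x"])
        fits = stratify(data, "sex", lambda d: fit_logistic(d, spec))
        assert (fits["male"].term("x")["estimate"]
                > fits["female"].term("x")["estimate"])

    def test_small_stratum_skipped_with_warning(self, rng):
        data = pd.DataFrame({
            "status": rng.integers(0, 2, 60).astype(float),
            "x": rng.normal(size=60),
            "sex": ["male"] * 57 + ["female"] * 3})
        spec = ModelSpec(outcome="status", terms=["x"])
        with pytest.warns(UserWarning, match="skipped"):
            fits = stratify(data, "sex", lambda d: fit_logistic(d, spec))
        assert list(fits) == ["male"]
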