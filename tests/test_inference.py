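from __future__ import annotations

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from decadd import measurement as me
from decadd.inference import (
    ConvergenceError,
    DegenerateDataError,
    compare_models,
    fit_accuracy_model,
    fit_latency_model,
    run_study_analysis,
)
from decadd.simulate import SimParams, simulate_experiment


def _binary_panel(seed=7, n_groups=24, per_cell=14, betas=(-0.5, -1.0, -2.0),
                  sigma_u=0.8):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, n_groups)
    rows = []
    for g in range(n_groups):
        for lt, b in zip(("none", "one", "two"), betas):
            p = 1 / (1 + np.exp(-(b + u[g])))
            for _ in range(per_cell):
                rows.append(
                    {"participant_id": g, "list_type": lt,
                     "error": int(rng.random() < p)}
                )
    return pd.DataFrame(rows)


class TestAccuracyModel:
    def test_agrees_with_lme4_glmer_reference(self, tmp_path):
        """The Gauss-Hermite ML fit reproduces lme4::glmer (nAGQ=25) on the
        same data: coefficients, SEs, random-intercept SD and logLik."""
        data = _binary_panel()
        fit = fit_accuracy_model(data)
        csv = tmp_path / "panel.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(lme4)); library(jsonlite)
            d <- read.csv("{csv}")
            d$list_type <- factor(d$list_type, levels=c("none","one","two"))
            m <- glmer(error ~ 0 + list_type + (1|participant_id),
                       data=d, family=binomial, nAGQ=25)
            cat(toJSON(list(beta=unname(fixef(m)),
                            se=unname(sqrt(diag(as.matrix(vcov(m))))),
                            sigma=unname(sqrt(unlist(VarCorr(m)))),
                            llf=as.numeric(logLik(m))), digits=10))
            """
        )
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript reference not on PATH"
        out = subprocess.run(
            [rscript, "--vanilla", str(script)], capture_output=True, text=True,
            check=True,
        )
        ref = json.loads(out.stdout)
        np.testing.assert_allclose(fit.params.to_numpy(), ref["beta"], atol=2e-3)
        np.testing.assert_allclose(fit.se.to_numpy(), ref["se"], atol=2e-3)
        assert np.sqrt(fit.re_var) == pytest.approx(ref["sigma"][0], abs=5e-3)
        assert fit.llf == pytest.approx(ref["llf"][0], abs=1e-3)

    def test_contrasts_report_odds_ratios_and_tukey_adjustment(self):
        fit = fit_accuracy_model(_binary_panel())
        c = fit.contrasts.set_index("contrast")
        assert c.loc["two vs none", "odds_ratio"] < 1  # fewer errors
        assert (c["p_tukey"] >= c["p_unadjusted"] - 1e-12).all()

    def test_zero_variance_outcome_raises_structured_error(self):
        data = _binary_panel()
        data["error"] = 0
        with pytest.raises(DegenerateDataError):
            fit_accuracy_model(data)


def _latency_panel(seed=3, n_groups=18, per_cell=25, means=(900.0, 900.0, 900.0),
                   sigma_u=120.0, sigma_e=180.0, factor="list_type"):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, n_groups)
    rows = []
    for g in range(n_groups):
        for lvl, m in zip(("none", "one", "two"), means):
            for _ in range(per_cell):
                rows.append(
                    {"participant_id": g, factor: lvl,
                     "latency": m + u[g] + rng.normal(0, sigma_e)}
                )
    return pd.DataFrame(rows)


class TestLatencyModel:
    def test_null_data_gives_contrasts_centred_on_zero(self):
        fit = fit_latency_model(_latency_panel(), outcome="latency",
                                factor="list_type")
        c = fit.contrasts
        assert (c["estimate"].abs() < 4 * c["se"]).all()
        assert (c["p_tukey"] >= c["p_unadjusted"] - 1e-12).all()

    def test_recovers_the_post_vs_super_gap_within_its_interval(self, study1_sets):
        """Simulated with the default 638/1298 ms bases (size slope off), the
        supercomplement-vs-post-complement contrast recovers ~660 ms."""
        params = SimParams(addend_slope=0.0)
        log = simulate_experiment(21, params, 1, study1_sets, seed=77)
        data = log[log["list_correct"] & ~log["late_entry"]]
        fit = fit_latency_model(data, outcome="latency_ms", factor="step_type")
        c = fit.contrasts.set_index("contrast")
        row = c.loc["[>] vs [-]"]
        true_gap = 1298.0 - 638.0
        assert abs(row["estimate"] - true_gap) < 3 * row["se"]
        assert 0 < row["eta_p2"] < 1

    def test_single_participant_warns_and_reports_near_zero_variance(self):
        data = _latency_panel(n_groups=1, per_cell=60)
        with pytest.warns(UserWarning):
            fit = fit_latency_model(data, outcome="latency", factor="list_type")
        assert fit.re_var < 1e-2 * fit.scale


class TestCompareModels:
    def test_comparing_a_model_with_itself_is_null(self):
        data = _latency_panel()
        res = compare_models(data, "latency", ["list_type"], None)
        assert res.chi2 == 0.0 and res.df == 0 and res.p == 1.0

    def test_refuses_non_nested_comparison(self):
        data = _latency_panel()
        with pytest.raises(ValueError):
            compare_models(data, "latency", ["list_type"], "list_type")

    def test_likelihood_never_decreases_when_adding_a_factor(self):
        data = _latency_panel(means=(800.0, 900.0, 1000.0))
        data["size"] = np.random.default_rng(0).normal(size=len(data))
        res = compare_models(data, "latency", ["size"], "list_type")
        assert res.chi2 >= 0 and res.llf_full >= res.llf_base
        assert res.df == 2

    def test_null_added_factor_gives_chi2_near_df(self):
        """Likelihood-ratio calibration: with a truly inert added factor the
        LR statistic has mean ~ df across replications."""
        chis = []
        for rep in range(60):
            data = _latency_panel(seed=100 + rep, n_groups=10, per_cell=12)
            res = compare_models(data, "latency", [], "list_type")
            chis.append(res.chi2)
        mean = float(np.mean(chis))
        # chi2(2): mean 2, var 4 -> SE over 60 reps ~ 0.26
        assert abs(mean - 2.0) < 1.0

    def test_addition_type_explains_more_than_addend_size(self, study1_log):
        data = me.screened_addition_data(study1_log)
        by_type = compare_models(data, "latency_ms", ["addend"], "category")
        by_size = compare_models(data, "latency_ms", ["category"], "addend")
        assert by_type.pseudo_r2 > by_size.pseudo_r2
        assert by_type.p < 0.001 and by_size.p < 0.001


class TestRunStudyAnalysis:
    def test_report_contains_all_panels(self, study1_log):
        rep = run_study_analysis(study1_log)
        assert rep["study"] == 1 and rep["n_participants"] == 21
        assert len(rep["accuracy"]["contrasts"]) == 3
        assert len(rep["list_latency"]["contrasts"]) == 3
        assert len(rep["additions"]["contrasts"]) == 6  # 4 categories pairwise
        mc = rep["model_comparison"]
        assert set(mc) == {"addition_type_over_size", "size_over_addition_type"}
        assert mc["addition_type_over_size"]["df"] == 3
        assert mc["size_over_addition_type"]["df"] == 1

    def test_study2_report_adds_the_fine_type_table(self, study2_log):
        rep = run_study_analysis(study2_log)
        labels = {r["step_type"] for r in rep["additions"]["fine_table"]}
        assert {"1", "6a", "6b", "6c", "9"} <= labels
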