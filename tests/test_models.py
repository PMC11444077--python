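"""Mixed-model association fitting: parameter recovery against the
generator, degenerate-variance behaviour, an independent GLMM oracle
(R lme4 via Rscript), stratification, leave-one-out, and sensitivity
arithmetic."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import attach_truth_exposure
from phthalburden import SynthConfig, derive_outcomes, generate_cohort_dyads
from phthalburden.models import (
    ModelSpec,
    _build_design,
    covariate_sensitivity,
    fit_association,
    fit_logistic_random_intercept,
    join_analysis_table,
    leave_one_out,
    percent_change,
    run_model_grid,
    stratified_models,
)

GA_SPEC = ModelSpec(outcome="gestational_age", exposure_group="DEHP")
PT_SPEC = ModelSpec(outcome="preterm", exposure_group="DEHP")


def _linear_dataset(slope, seed, n_cohorts=13, dyads=385, cohort_sd=0.30):
    cfg = SynthConfig(
        n_cohorts=n_cohorts, dyads_per_cohort=dyads, cohort_intercept_sd=cohort_sd,
        true_slopes_ga={"DEHP": slope}, include_urine=False, seed=seed,
    )
    d, _ = generate_cohort_dyads(cfg)
    return attach_truth_exposure(d)


def _binary_dataset(log_or, seed, n_cohorts=13, dyads=385):
    cfg = SynthConfig(
        n_cohorts=n_cohorts, dyads_per_cohort=dyads,
        true_log_or={"DEHP": log_or}, include_urine=False, seed=seed,
    )
    d, _ = generate_cohort_dyads(cfg)
    d = attach_truth_exposure(d)
    d["preterm"] = (d["gestational_age"] < 37.0).astype(float)
    return d


class TestLinearRecovery:
    @pytest.mark.parametrize("slope", [-1.0, -0.253, 1.0])
    def test_slope_recovered_within_three_se(self, slope):
        biases = []
        for seed in range(5):
            d = _linear_dataset(slope, seed=300 + seed, dyads=200)
            r = fit_association(GA_SPEC, d)
            assert r.converged
            assert abs(r.beta - slope) < 3.0 * r.se, (slope, seed, r.beta, r.se)
            biases.append((r.beta - slope, r.se))
        mean_abs_bias = abs(np.mean([b for b, _ in biases]))
        assert mean_abs_bias < np.mean([s for _, s in biases])

    def test_degenerate_variance_matches_ordinary_fit(self):
        d = _linear_dataset(-0.25, seed=3, cohort_sd=1e-9)
        r = fit_association(GA_SPEC, d)
        X, y, _, _ = _build_design(d, GA_SPEC)
        ols = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        assert r.beta == pytest.approx(ols.params[1], rel=1e-3)

    def test_n_accounting(self):
        d = _linear_dataset(-0.25, seed=8, n_cohorts=4, dyads=100)
        d.loc[d.index[:17], "maternal_age"] = np.nan      # continuous -> dropped
        d.loc[d.index[20:25], "gestational_age"] = np.nan # outcome -> dropped
        r = fit_association(GA_SPEC, d)
        expected = (
            d["maternal_age"].notna()
            & d["gestational_age"].notna()
            & d["log10_pregnancy_average_DEHP"].notna()
            & d["child_sex"].notna()
        ).sum()
        assert r.n_dyads == expected

    def test_single_cohort_degrades_to_fixed_intercept(self, caplog):
        d = _linear_dataset(-0.25, seed=8, n_cohorts=1, dyads=300)
        with caplog.at_level("WARNING"):
            r = fit_association(GA_SPEC, d)
        assert r.method == "ols"
        assert r.n_cohorts == 1


class TestLogisticRecovery:
    def test_odds_ratio_recovered(self):
        true = math.log(2.0)
        d = _binary_dataset(true, seed=5)
        r = fit_association(PT_SPEC, d)
        assert r.converged
        assert abs(r.beta - true) < 3.0 * r.se
        assert r.odds_ratio == pytest.approx(math.exp(r.beta))
        assert r.or_ci_low < r.odds_ratio < r.or_ci_high

    def test_agrees_with_lme4_oracle(self, tmp_path):
        """Independent cross-check: the same marginal likelihood maximised
        by R's glmer (adaptive Gauss-Hermite, nAGQ=25)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the GLMM oracle")
        d = _binary_dataset(math.log(2.0), seed=5, n_cohorts=8, dyads=250)
        X, y, cohorts, names = _build_design(d, PT_SPEC)
        df = X.copy()
        df["y"], df["cohort"] = y.to_numpy(), cohorts.to_numpy()
        fixture = tmp_path / "glmm.csv"
        df.to_csv(fixture, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f'd <- read.csv("{fixture}")\n'
            'fixed <- setdiff(names(d), c("y", "cohort", "const"))\n'
            'form <- as.formula(paste("y ~", paste(fixed, collapse="+"), "+ (1|cohort)"))\n'
            "m <- glmer(form, data=d, family=binomial, nAGQ=25)\n"
            's <- summary(m)$coefficients\n'
            'cat(s["exposure", 1], s["exposure", 2], "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        oracle_beta, oracle_se = map(float, out.stdout.split())
        beta, se, _, conv = fit_logistic_random_intercept(
            X.to_numpy(), y.to_numpy(), cohorts.to_numpy()
        )
        j = names.index("exposure")
        assert conv
        assert beta[j] == pytest.approx(oracle_beta, rel=0.01)
        assert se[j] == pytest.approx(oracle_se, rel=0.02)


class TestModelGrid:
    def test_grid_size_continuous(self, small_cohorts, population_dyads):
        d = attach_truth_exposure(
            population_dyads,
            groups=("LMW", "HMW", "DEHP", "DnOP", "DiNP", "DiDP", "phthalic_acid"),
        )
        d = d.merge(derive_outcomes(d), on="dyad_id")
        grid = run_model_grid(
            d,
            ["LMW", "HMW", "DEHP", "DnOP", "DiNP", "DiDP", "phthalic_acid"],
            ["gestational_age", "birthweight", "birth_length", "bw_for_ga_z"],
        )
        assert len(grid) == 28
        assert grid["converged"].all()

    def test_unavailable_group_skipped(self):
        d = _linear_dataset(-0.25, seed=2, n_cohorts=3, dyads=80)
        d["log10_pregnancy_average_GHOST"] = np.nan
        grid = run_model_grid(d, ["DEHP", "GHOST"], ["gestational_age"])
        assert set(grid["exposure_group"]) == {"DEHP"}


class TestStratified:
    def test_sex_specific_effects_ordered(self):
        """Simulated sex-specific preterm odds ratios (4.8 for females vs
        2.3 for males) separate in the fitted strata."""
        d_f = _binary_dataset(math.log(4.8), seed=41, dyads=250)
        d_m = _binary_dataset(math.log(2.3), seed=42, dyads=250)
        d = pd.concat(
            [d_f[d_f["child_sex"] == "female"], d_m[d_m["child_sex"] == "male"]],
            ignore_index=True,
        )
        res = stratified_models(PT_SPEC, d, "child_sex")
        by = res.set_index("stratum")["beta"]
        assert by["female"] > by["male"]

    def test_homogeneous_truth_strata_cover_full_estimate(self):
        d = _linear_dataset(-0.5, seed=13, dyads=300)
        full = fit_association(GA_SPEC, d)
        res = stratified_models(GA_SPEC, d, "child_sex")
        assert len(res) == 2
        for _, row in res.iterrows():
            assert row["ci_low"] - 0.05 <= full.beta <= row["ci_high"] + 0.05

    def test_single_cohort_stratum_skipped(self):
        d = _linear_dataset(-0.25, seed=14, n_cohorts=3, dyads=60)
        d["region"] = "north"
        d.loc[d["cohort"] == "C01", "region"] = "south"  # one-cohort stratum
        res = stratified_models(GA_SPEC, d, "region")
        assert list(res["stratum"]) == ["north"]


class TestLeaveOneOut:
    def test_refit_count_matches_cohorts(self):
        d = _linear_dataset(-0.4, seed=21, n_cohorts=6, dyads=150)
        res = leave_one_out(GA_SPEC, d)
        assert len(res) == 6

    def test_outlying_cohort_flagged_and_direction_stable(self):
        d = _linear_dataset(-0.4, seed=22, n_cohorts=6, dyads=150)
        mask = d["cohort"] == "C01"
        x = d.loc[mask, "log10_pregnancy_average_DEHP"]
        d.loc[mask, "gestational_age"] += 6.0 * (x - x.mean())  # strong reversal
        res = leave_one_out(GA_SPEC, d)
        flagged = res.loc[res["influential"], "excluded_cohort"]
        assert "C01" in set(flagged)
        others = res[res["excluded_cohort"] != "C01"]
        assert (np.sign(others["beta"]) == np.sign(others["full_beta"])).all()

    def test_homogeneous_cohorts_unflagged(self):
        d = _linear_dataset(-0.8, seed=23, n_cohorts=6, dyads=250)
        res = leave_one_out(GA_SPEC, d)
        assert not res["influential"].any()

    def test_cohort_without_exposure_leaves_estimate_unchanged(self):
        d = _linear_dataset(-0.4, seed=24, n_cohorts=6, dyads=150)
        d.loc[d["cohort"] == "C06", "log10_pregnancy_average_DEHP"] = np.nan
        full = fit_association(GA_SPEC, d)
        res = leave_one_out(GA_SPEC, d)
        row = res[res["excluded_cohort"] == "C06"].iloc[0]
        assert row["beta"] == pytest.approx(full.beta, abs=1e-12)

    def test_requires_three_cohorts(self):
        d = _linear_dataset(-0.4, seed=25, n_cohorts=2, dyads=100)
        with pytest.raises(ValueError):
            leave_one_out(GA_SPEC, d)


class TestCovariateSensitivity:
    @pytest.mark.parametrize(
        "base, new, expected, flagged",
        [(-0.20, -0.22, 10.0, False), (-0.20, -0.20, 0.0, False), (-0.20, -0.24, 20.0, True)],
    )
    def test_percent_change_arithmetic(self, base, new, expected, flagged):
        change = percent_change(base, new)
        assert change == pytest.approx(expected)
        assert (change > 15.0) is flagged

    def test_zero_base_is_not_applicable(self):
        assert percent_change(0.0, 0.1) is None

    def test_uninformative_extra_covariate_changes_little(self):
        d = _linear_dataset(-0.5, seed=31, n_cohorts=5, dyads=200)
        rng = np.random.default_rng(0)
        d["prepreg_bmi"] = rng.normal(26.0, 4.0, len(d))  # independent of all
        rep = covariate_sensitivity(GA_SPEC, d, "prepreg_bmi")
        assert rep["percent_change"] < 15.0
        assert not rep["exceeds_threshold"]


class TestJoin:
    def test_exposure_columns_wide(self, small_cohorts):
        from phthalburden import eligibility_filter, process_exposures

        dyads, urine = small_cohorts
        summary = process_exposures(urine, min_detected_participants=50)
        eligible = eligibility_filter(dyads, urine)
        outcomes = derive_outcomes(eligible)
        joined = join_analysis_table(eligible, summary, outcomes)
        assert "log10_pregnancy_average_DEHP" in joined.columns
        assert "log10_t3_DEHP" in joined.columns
        assert len(joined) == len(eligible)
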