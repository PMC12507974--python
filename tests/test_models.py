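"""Mixed-effects models and Tukey-adjusted contrasts."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swaylab.models import (
    ModelSpec,
    build_report,
    fit_error_model,
    fit_lme,
    pairwise_contrasts,
)
from swaylab.simulate import make_design

STIM_EFFECTS = {"Sham": 0.0, "RDLPFC": 0.4, "LDLPFC": 0.6}
COND_EFFECTS = {"Silent": 0.0, "Easy": 0.4, "Hard": 1.5}


def simulate_table(
    n_subjects=12,
    intercept=5.0,
    stim_effects=STIM_EFFECTS,
    cond_effects=COND_EFFECTS,
    subject_sd=1.0,
    slope_sd=0.02,
    resid_sd=1.5,
    seed=0,
):
    """Gaussian trial table on the study's layout (direct linear model)."""
    rng = np.random.default_rng(seed)
    design = make_design(n_subjects=n_subjects, seed=seed).table.copy()
    b0 = {s: rng.normal(0, subject_sd) for s in design["subject"].unique()}
    b1 = {s: rng.normal(0, slope_sd) for s in design["subject"].unique()}
    mu = (
        intercept
        + design["stim"].map(stim_effects)
        + design["condition"].map(cond_effects)
        + design["subject"].map(b0)
        + design["subject"].map(b1) * design["trial"]
    )
    design["mean_rs"] = mu + rng.normal(0, resid_sd, size=len(design))
    return design


class TestFitLme:
    def test_noise_free_balanced_design_recovers_cell_contrasts(self):
        """With (near-)zero random variance and residual noise, the fixed
        estimates equal the additive cell-mean contrasts."""
        df = simulate_table(
            n_subjects=6, subject_sd=0.0, slope_sd=0.0, resid_sd=1e-8, seed=3
        )
        fit = fit_lme(df, "mean_rs", spec=ModelSpec(response="mean_rs", random_slope=False))
        assert fit.coef("Intercept") == pytest.approx(5.0, abs=1e-6)
        assert fit.coef("Hard") == pytest.approx(1.5, abs=1e-6)
        assert fit.coef("Easy") == pytest.approx(0.4, abs=1e-6)
        assert fit.coef("LDLPFC") == pytest.approx(0.6, abs=1e-6)
        assert fit.coef("RDLPFC") == pytest.approx(0.4, abs=1e-6)

    def test_recovers_injected_effects_with_noise(self):
        df = simulate_table(n_subjects=24, seed=11)
        fit = fit_lme(df, "mean_rs")
        assert fit.converged
        for term, truth in [("Hard", 1.5), ("Easy", 0.4), ("LDLPFC", 0.6)]:
            assert abs(fit.coef(term) - truth) < 3 * fit.se(term)
        vc = fit.variance_components
        assert vc["residual_sd"] == pytest.approx(1.5, rel=0.15)
        assert vc["subject_intercept_sd"] == pytest.approx(1.0, rel=0.6)

    def test_zero_effect_false_positive_rate(self):
        """Null generator: each coefficient stays within 3 SE in >=95% of
        seeded replicates (type-I calibration of the reported SEs)."""
        n_reps = 100
        within = {t: 0 for t in ("RDLPFC", "LDLPFC", "Easy", "Hard")}
        for rep in range(n_reps):
            df = simulate_table(
                n_subjects=8,
                stim_effects={k: 0.0 for k in STIM_EFFECTS},
                cond_effects={k: 0.0 for k in COND_EFFECTS},
                seed=1000 + rep,
            )
            fit = fit_lme(
                df, "mean_rs", spec=ModelSpec(response="mean_rs", random_slope=False)
            )
            for term in within:
                if abs(fit.coef(term)) < 3 * fit.se(term):
                    within[term] += 1
        for term, n_ok in within.items():
            assert n_ok >= 0.95 * n_reps, f"{term}: {n_ok}/{n_reps}"

    def test_se_shrinks_with_sqrt_subjects(self):
        se_small = fit_lme(simulate_table(n_subjects=10, seed=5), "mean_rs").se("Hard")
        se_large = fit_lme(simulate_table(n_subjects=40, seed=6), "mean_rs").se("Hard")
        assert se_small / se_large == pytest.approx(2.0, rel=0.35)

    def test_estimates_concentrate_with_more_subjects(self):
        """Consistency: quadrupling subjects shrinks the recovery error."""
        def rmse(n_subjects, seeds):
            errs = []
            for s in seeds:
                df = simulate_table(n_subjects=n_subjects, seed=s)
                fit = fit_lme(
                    df, "mean_rs", spec=ModelSpec(response="mean_rs", random_slope=False)
                )
                errs.append(fit.coef("Hard") - 1.5)
            return float(np.sqrt(np.mean(np.square(errs))))

        assert rmse(112, range(300, 308)) < rmse(28, range(200, 208))

    def test_excluded_rows_are_dropped(self):
        df = simulate_table(n_subjects=6, seed=9)
        df["excluded"] = False
        df.loc[df.index[:30], "excluded"] = True
        fit = fit_lme(df, "mean_rs")
        assert fit.result.nobs == len(df) - 30

    def test_missing_column_and_single_subject_rejected(self):
        df = simulate_table(n_subjects=4, seed=2)
        with pytest.raises(ValueError):
            fit_lme(df.drop(columns=["condition"]), "mean_rs")
        with pytest.raises(ValueError):
            fit_lme(df[df["subject"] == "S01"], "mean_rs")

    def test_agrees_with_lme4_oracle(self, tmp_path):
        """Independent cross-check: R lme4 fits the same REML model."""
        df = simulate_table(n_subjects=16, slope_sd=0.08, seed=21)
        csv = tmp_path / "trials.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "coef.csv"
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$stim <- relevel(factor(d$stim), ref = "Sham")
                d$condition <- relevel(factor(d$condition), ref = "Silent")
                m <- lmer(mean_rs ~ stim + condition + (1 + trial | subject),
                          data = d, REML = TRUE)
                cf <- summary(m)$coefficients
                write.csv(data.frame(term = rownames(cf), est = cf[, 1], se = cf[, 2]),
                          "{out}", row.names = FALSE)
                """
            )
        )
        subprocess.run(
            ["Rscript", "--vanilla", str(rscript)], check=True, capture_output=True
        )
        ref = pd.read_csv(out)
        ref["term"] = (
            ref["term"]
            .str.replace("(Intercept)", "Intercept", regex=False)
            .str.replace("stim", "", regex=False)
            .str.replace("condition", "", regex=False)
        )
        fit = fit_lme(df, "mean_rs")
        for _, row in ref.iterrows():
            assert fit.coef(row["term"]) == pytest.approx(row["est"], abs=2e-3)
            assert fit.se(row["term"]) == pytest.approx(row["se"], rel=0.02)


class TestErrorModel:
    def test_difficulty_only_generator_recovery(self):
        """Stimulation-null generator: stim coefficients ~0, Hard ~truth."""
        rng = np.random.default_rng(4)
        design = make_design(n_subjects=20, seed=4).table
        task = design[design["condition"] != "Silent"].copy()
        b0 = {s: rng.normal(0, 0.8) for s in task["subject"].unique()}
        lam = np.maximum(
            2.0 + 1.5 * (task["condition"] == "Hard") + task["subject"].map(b0), 0.05
        )
        task["abs_error"] = rng.poisson(lam)
        fit = fit_error_model(task)
        assert abs(fit.coef("Hard") - 1.5) < 3 * fit.se("Hard")
        for term in ("RDLPFC", "LDLPFC"):
            assert abs(fit.coef(term)) < 3 * fit.se(term)

    def test_uses_easy_reference_and_random_intercept(self, small_sim):
        fit = fit_error_model(small_sim.responses)
        terms = set(fit.params["term"])
        assert "Hard" in terms and "Easy" not in terms
        assert "trial_slope_sd" not in fit.variance_components


@pytest.fixture(scope="module")
def fitted():
    df = simulate_table(n_subjects=12, seed=8)
    fit = fit_lme(df, "mean_rs")
    return fit, pairwise_contrasts(fit)


class TestContrasts:

    def test_full_cell_family_size(self, fitted):
        _, table = fitted
        assert len(table) == 36  # C(9, 2)

    def test_adjusted_p_at_least_unadjusted(self, fitted):
        _, table = fitted
        p_unadj = 2 * stats.t.sf(np.abs(table["t_ratio"]), table["df"])
        assert np.all(table["p_value"] >= p_unadj - 1e-12)

    def test_two_cell_family_reduces_to_plain_t_test(self, fitted):
        fit, _ = fitted
        pair = pairwise_contrasts(fit, cells=[("Sham", "Silent"), ("Sham", "Hard")])
        assert len(pair) == 1
        row = pair.iloc[0]
        p_t = 2 * stats.t.sf(abs(row["t_ratio"]), row["df"])
        assert row["p_value"] == pytest.approx(p_t, rel=1e-6)

    def test_antisymmetric_under_label_reversal(self, fitted):
        fit, _ = fitted
        ab = pairwise_contrasts(fit, cells=[("Sham", "Silent"), ("LDLPFC", "Hard")])
        ba = pairwise_contrasts(fit, cells=[("LDLPFC", "Hard"), ("Sham", "Silent")])
        assert ab["estimate"].iloc[0] == pytest.approx(-ba["estimate"].iloc[0])
        assert ab["se"].iloc[0] == pytest.approx(ba["se"].iloc[0])

    def test_contrast_equals_cell_mean_difference_in_clean_data(self):
        df = simulate_table(n_subjects=6, subject_sd=0.0, slope_sd=0.0, resid_sd=1e-8, seed=13)
        fit = fit_lme(df, "mean_rs", spec=ModelSpec(response="mean_rs", random_slope=False))
        table = pairwise_contrasts(fit, cells=[("Sham", "Silent"), ("Sham", "Hard")])
        cell = df.groupby(["stim", "condition"])["mean_rs"].mean()
        diff = cell[("Sham", "Silent")] - cell[("Sham", "Hard")]
        assert table["estimate"].iloc[0] == pytest.approx(diff, abs=1e-6)

    def test_labels_follow_condition_stim_convention(self, fitted):
        _, table = fitted
        assert table["contrast"].iloc[0].startswith("Silent SHAM - ")


class TestReport:
    def test_empty_report_has_header_only(self, tmp_path):
        written = build_report({}, {"mean_rs": pd.DataFrame()}, tmp_path)
        contrast_files = [p for p in written if p.name.startswith("contrasts")]
        lines = contrast_files[0].read_text().strip().splitlines()
        assert lines[-1].startswith("contrast,")

    def test_fit_and_contrasts_written_with_matching_rows(self, tmp_path):
        df = simulate_table(n_subjects=6, seed=15)
        fit = fit_lme(df, "mean_rs")
        table = pairwise_contrasts(fit)
        written = build_report({"mean_rs": fit}, {"mean_rs": table}, tmp_path)
        coef = pd.read_csv(tmp_path / "coefficients_mean_rs.csv", comment="#")
        ctr = pd.read_csv(tmp_path / "contrasts_mean_rs.csv", comment="#")
        assert len(coef) == len(fit.params)
        assert len(ctr) == len(table)
        assert all(p.exists() for p in written)

    def test_missing_model_noted(self, tmp_path):
        df = simulate_table(n_subjects=6, seed=16)
        fit = fit_lme(df, "mean_rs")
        build_report({"mean_rs": fit}, {"mean_rs": pairwise_contrasts(fit), "alpha": pd.DataFrame()}, tmp_path)
        assert "no fitted model for alpha" in (tmp_path / "report_notes.txt").read_text()
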