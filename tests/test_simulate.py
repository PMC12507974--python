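"""Synthetic study generator: design, fractional CoP trials, error counts."""

import numpy as np
import pandas as pd
import pytest

from swaylab.calibration import (
    build_calibration_table,
    hurst_for_alpha,
    load_calibration,
    unit_mean_rs,
)
from swaylab.dfa import estimate_alpha
from swaylab.simulate import (
    CTBS_DEFAULT,
    SILENT_POSITIONS,
    EffectConfig,
    TemporalConfig,
    gen_cop_trial,
    gen_error_counts,
    make_design,
    simulate_study,
)
from swaylab.sway import radial_sway


class TestDesign:
    def test_default_study_has_1260_trial_slots(self):
        design = make_design(n_subjects=28, seed=0)
        assert design.n_trials == 1260

    def test_two_subjects_give_90_slots(self):
        assert make_design(n_subjects=2, seed=0).n_trials == 90

    def test_silent_trials_at_fixed_positions(self):
        design = make_design(n_subjects=5, seed=3)
        for (_, _), grp in design.table.groupby(["subject", "stim"]):
            silent = set(grp.loc[grp["condition"] == "Silent", "trial"])
            assert silent == set(SILENT_POSITIONS)
            for cond in ("Easy", "Hard"):
                assert (grp["condition"] == cond).sum() == 5

    def test_blocked_easy_hard_sets(self):
        design = make_design(n_subjects=4, seed=1)
        for (_, _), grp in design.table.groupby(["subject", "stim"]):
            block1 = set(grp.loc[grp["trial"].between(3, 7), "condition"])
            block2 = set(grp.loc[grp["trial"].between(9, 13), "condition"])
            assert len(block1) == len(block2) == 1
            assert block1 != block2

    def test_each_subject_gets_all_three_sessions(self):
        design = make_design(n_subjects=6, seed=2)
        per = design.table.groupby("subject")["stim"].nunique()
        assert (per == 3).all()

    def test_session_order_varies_across_subjects(self):
        design = make_design(n_subjects=28, seed=0)
        orders = design.table.groupby("subject").apply(
            lambda g: tuple(g.sort_values(["day", "trial"])["stim"].unique()),
            include_groups=False,
        )
        assert orders.nunique() > 1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_design(n_subjects=1, seed=0)


class TestCTBSProtocol:
    def test_600_pulses(self):
        # 3-pulse bursts every 200 ms for 40 s
        assert CTBS_DEFAULT.n_bursts == 200
        assert CTBS_DEFAULT.total_pulses == 600


class TestErrorCounts:
    def test_reproducible(self):
        a = gen_error_counts("Sham", "Easy", seed=5)
        assert a == gen_error_counts("Sham", "Easy", seed=5)
        assert a >= 0

    def test_sample_mean_matches_linear_predictor(self):
        rng = np.random.default_rng(0)
        cfg = EffectConfig().error
        draws = [
            gen_error_counts("LDLPFC", "Hard", config=cfg, seed=rng)
            for _ in range(100_000)
        ]
        lam = cfg.intercept + cfg.ldlpfc + cfg.hard
        assert np.mean(draws) == pytest.approx(lam, rel=0.02)

    def test_floored_predictor_gives_mostly_zero(self):
        rng = np.random.default_rng(1)
        from swaylab.simulate import ResponseEffects

        cfg = ResponseEffects(intercept=-5.0)
        draws = [gen_error_counts("Sham", "Easy", config=cfg, seed=rng) for _ in range(500)]
        assert min(draws) >= 0
        assert np.mean(np.asarray(draws) == 0) > 0.9

    def test_rejects_silent_difficulty(self):
        with pytest.raises(ValueError):
            gen_error_counts("Sham", "Silent", seed=0)


class TestCalibration:
    def test_shipped_table_is_monotone(self):
        table = load_calibration()
        assert np.all(np.diff(table["alpha_rs"]) > 0)
        assert np.all(np.diff(table["unit_mean_rs"]) > 0)
        assert np.all((table["hurst"] > 0) & (table["hurst"] < 1))

    def test_interpolation_round_trip(self):
        table = load_calibration()
        for alpha in (1.1, 1.275, 1.36):
            h = hurst_for_alpha(alpha, table)
            assert table["hurst"].min() <= h <= table["hurst"].max()
        assert unit_mean_rs(0.35, table) == pytest.approx(
            float(table.set_index("hurst")["unit_mean_rs"][0.35]), rel=1e-9
        )

    def test_regeneration_reproduces_stored_values(self):
        """Re-measuring two grid points reproduces the stored mapping
        within Monte-Carlo tolerance (stability of the calibration)."""
        stored = load_calibration().set_index("hurst")
        fresh = build_calibration_table([0.30, 0.45], n_reps=60, seed=777)
        for _, row in fresh.iterrows():
            assert row["alpha_rs"] == pytest.approx(
                stored.loc[row["hurst"], "alpha_rs"], abs=0.02
            )


class TestGenCopTrial:
    def test_output_shape_and_labels(self):
        t = gen_cop_trial("Sham", "Silent", trial_index=1, seed=0)
        assert t.n_samples == 18000
        assert t.fs == 200.0
        assert t.session == "Sham" and t.condition == "Silent"

    def test_amplitude_homogeneity(self):
        a = gen_cop_trial("Sham", "Silent", 1, rs_target=5.0, seed=3)
        b = gen_cop_trial("Sham", "Silent", 1, rs_target=10.0, seed=3)
        np.testing.assert_allclose(b.x, 2 * a.x, rtol=1e-12)

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            gen_cop_trial("M1", "Silent", 1, seed=0)

    def test_nonpositive_target_clipped_to_floor(self):
        t = gen_cop_trial("Sham", "Silent", 1, rs_target=-3.0, seed=2)
        rs = np.hypot(t.x, t.y)[800:]
        assert 0 < rs.mean() < 1.0

    def test_mean_rs_and_alpha_hit_targets(self):
        """Monte-Carlo check of the generator calibration on the baseline
        cell: mean of trial-mean RS within 3% of target; mean DFA alpha
        within 0.03 of target."""
        target_rs, target_alpha = 4.921, 1.36
        means, alphas = [], []
        for s in range(300):
            t = gen_cop_trial(
                "Sham", "Silent", 1,
                rs_target=target_rs, alpha_target=target_alpha, seed=s,
            )
            rs = np.hypot(t.x, t.y)[800:]
            means.append(rs.mean())
            if s < 120:
                alphas.append(estimate_alpha(rs).alpha)
        assert np.mean(means) == pytest.approx(target_rs, rel=0.03)
        assert np.mean(alphas) == pytest.approx(target_alpha, abs=0.03)

    def test_baseline_alpha_in_antipersistent_band(self):
        """Generated baseline sway scales in the 1 < alpha < 1.5 regime."""
        alphas = []
        for s in range(30):
            t = gen_cop_trial("Sham", "Silent", 1, seed=s)
            alphas.append(estimate_alpha(np.hypot(t.x, t.y)[800:]).alpha)
        assert 1.0 < np.mean(alphas) < 1.5


class TestSimulateStudy:
    def test_trial_and_response_counts(self, small_sim):
        # 2 subjects x 3 sessions x 15 trials; responses only for task trials
        assert small_sim.design.n_trials == 90
        assert len(small_sim.responses) == 60

    def test_default_design_counts(self):
        sim = simulate_study(seed=1)  # metadata only; trials stay lazy
        assert sim.design.n_trials == 1260
        assert len(sim.responses) == 840

    def test_same_seed_identical_different_seed_differs(self):
        a = simulate_study(seed=9, n_subjects=2)
        b = simulate_study(seed=9, n_subjects=2)
        c = simulate_study(seed=10, n_subjects=2)
        pd.testing.assert_frame_equal(a.responses, b.responses)
        ta, tb = next(a.iter_trials()), next(b.iter_trials())
        np.testing.assert_array_equal(ta.x, tb.x)
        tc = next(c.iter_trials())
        assert not np.array_equal(ta.x, tc.x)

    def test_iterating_twice_reproduces_trials(self, small_sim):
        first = next(small_sim.iter_trials())
        again = next(small_sim.iter_trials())
        np.testing.assert_array_equal(first.x, again.x)

    def test_responses_consistent_with_stream_scoring(self, small_sim):
        from swaylab.nback import StimulusSequence, count_easy_repeats, count_hard_repeats

        merged = small_sim.responses.merge(
            small_sim.sequences, on=["subject", "stim", "trial"]
        )
        for _, row in merged.iterrows():
            seq = StimulusSequence.from_line(row["letters"])
            score = (
                count_easy_repeats(seq.letters)
                if row["condition"] == "Easy"
                else count_hard_repeats(seq.letters)
            )
            assert score == row["expected"]
            assert row["abs_error"] == abs(row["expected"] - row["reported"])

    def test_silent_trials_have_no_response(self, small_sim):
        meta = small_sim.metadata
        silent = meta[meta["condition"] == "Silent"]
        assert silent["reported_count"].isna().all()
        task = meta[meta["condition"] != "Silent"]
        assert task["reported_count"].notna().all()
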