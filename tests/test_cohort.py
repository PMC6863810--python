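"""Synthetic cohort: allocation balance, RT model calibration, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from abmprobe.cohort import (
    GROUPS,
    CohortConfig,
    allocate_groups,
    draw_participant_params,
    simulate_cohort,
    simulate_lsas,
    simulate_response,
    simulate_responses,
)
from abmprobe.schedule import TrialSpec, generate_measurement_schedule


def make_params(**kw):
    base = dict(
        id="P001", group="2D-active", rt_mu=450.0, rt_sigma=50.0, rt_tau=100.0,
        bias_delta=0.0, error_rate=0.0, fast_guess_rate=0.0, lapse_rate=0.0,
        lsas_intercept=70.0, lsas_slope=-5.9,
    )
    base.update(kw)
    from abmprobe.cohort import ParticipantParams
    return ParticipantParams(**base)


class TestAllocation:
    def test_single_block_of_eight_gives_each_group_twice(self):
        labels = allocate_groups(8, [8], seed=1)
        assert pd.Series(labels).value_counts().to_dict() == {g: 2 for g in GROUPS}

    def test_study_blocking_gives_25_per_group(self):
        labels = allocate_groups(100, [12] * 7 + [8, 8], seed=2)
        assert pd.Series(labels).value_counts().to_dict() == {g: 25 for g in GROUPS}

    def test_minimal_block_is_a_permutation(self):
        assert sorted(allocate_groups(4, [4], seed=123)) == sorted(GROUPS)

    def test_block_not_divisible_by_four_raises(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            allocate_groups(6, [6], seed=0)

    def test_blocks_must_partition_n(self):
        with pytest.raises(ValueError, match="sum"):
            allocate_groups(10, [8], seed=0)


class TestResponseModel:
    def test_true_bias_effect_is_recovered_in_the_mean(self):
        # 10^4 trials per type: mean(incongruent) - mean(congruent) = delta +/- 3 SE
        params = make_params(bias_delta=30.0)
        rng = np.random.default_rng(42)
        n = 10_000
        frame = pd.DataFrame({
            "congruency": ["congruent"] * n + ["incongruent"] * n,
            "probe_letter": ["E"] * (2 * n),
        })
        out = simulate_responses(frame, params, rng)
        diff = (out.loc[out["congruency"] == "incongruent", "rt_ms"].mean()
                - out.loc[out["congruency"] == "congruent", "rt_ms"].mean())
        se = np.sqrt(2 * (params.rt_sigma**2 + params.rt_tau**2) / n)
        assert abs(diff - 30.0) < 3 * se

    def test_null_effect_leaves_types_exchangeable(self):
        params = make_params(bias_delta=0.0)
        rng = np.random.default_rng(7)
        n = 20_000
        frame = pd.DataFrame({
            "congruency": ["congruent"] * n + ["incongruent"] * n,
            "probe_letter": ["E"] * (2 * n),
        })
        out = simulate_responses(frame, params, rng)
        diff = (out.loc[out["congruency"] == "incongruent", "rt_ms"].mean()
                - out.loc[out["congruency"] == "congruent", "rt_ms"].mean())
        se = np.sqrt(2 * (params.rt_sigma**2 + params.rt_tau**2) / n)
        assert abs(diff) < 3 * se

    def test_fast_guess_rate_calibration(self):
        params = make_params(fast_guess_rate=0.05)
        rng = np.random.default_rng(3)
        n = 10_000
        frame = pd.DataFrame({"congruency": ["filler"] * n, "probe_letter": ["F"] * n})
        out = simulate_responses(frame, params, rng)
        frac = (out["rt_ms"] < 200).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        # all fast guesses land in U(50,200); the ex-Gaussian part rarely does
        assert abs(frac - 0.05) < 3 * se + 0.005

    def test_error_trials_carry_the_wrong_letter(self):
        params = make_params(error_rate=1.0)
        trial = TrialSpec(1, "threat-neutral", "top", "top", "E", "congruent")
        result = simulate_response(trial, params, np.random.default_rng(0))
        assert not result.correct and result.response_letter == "F"


class TestLsas:
    def test_flat_noiseless_trajectory(self):
        params = make_params(lsas_slope=0.0)
        config = CohortConfig(lsas_residual_sd=0.0)
        recs = simulate_lsas(params, config, np.random.default_rng(0))
        assert recs["total"].tolist() == [70, 70, 70, 70]

    def test_linear_decline_matches_generating_slope(self):
        params = make_params(lsas_intercept=70.0, lsas_slope=-5.9)
        config = CohortConfig(lsas_residual_sd=0.0)
        recs = simulate_lsas(params, config, np.random.default_rng(0))
        assert recs["total"].tolist() == [round(70 - 5.9 * t) for t in range(4)]

    def test_scale_bound_clips_totals(self):
        params = make_params(lsas_intercept=200.0, lsas_slope=0.0)
        config = CohortConfig(lsas_residual_sd=0.0)
        recs = simulate_lsas(params, config, np.random.default_rng(0))
        assert (recs["total"] == 144).all()

    def test_items_sum_exactly_to_totals_and_stay_in_range(self):
        params = make_params()
        config = CohortConfig(lsas_residual_sd=7.0)
        recs = simulate_lsas(params, config, np.random.default_rng(5))
        items = recs[[c for c in recs.columns if c.startswith("item_")]]
        assert items.shape[1] == 48
        assert (items.sum(axis=1) == recs["total"]).all()
        assert items.to_numpy().min() >= 0 and items.to_numpy().max() <= 3

    def test_dropout_flags_remove_followups(self):
        params = make_params(dropout_1wk=True, dropout_3mo=True)
        recs = simulate_lsas(params, CohortConfig(), np.random.default_rng(0))
        assert recs["timepoint"].tolist() == [0, 1]


class TestCohort:
    def test_structure_of_small_cohort(self, small_cohort):
        trials = small_cohort.trials
        assert trials["participant_id"].nunique() == 24
        per = trials.groupby(["participant_id", "phase"]).size().unstack()
        assert (per["pre"] == 40).all() and (per["post"] == 40).all()
        assert (per["training1"] == 20).all() and (per["training2"] == 20).all()
        assert len(small_cohort.ground_truth) == 24

    def test_active_training_has_no_congruent_trials(self, small_cohort):
        trials = small_cohort.trials
        active = trials[trials["group"].str.endswith("active")]
        training = active[active["phase"].str.startswith("training")]
        assert (training["congruency"] != "congruent").all()
        mock_training = trials[
            trials["group"].str.endswith("mock") & trials["phase"].str.startswith("training")
        ]
        assert (mock_training["congruency"] == "congruent").any()

    def test_same_seed_gives_identical_exports(self):
        config = CohortConfig(n_participants=8, block_sizes=(8,),
                              n_measurement_trials=20, include_training=False, seed=3)
        a, b = simulate_cohort(config), simulate_cohort(config)
        assert a.trials.equals(b.trials)
        assert a.questionnaires.equals(b.questionnaires)
        assert a.ground_truth.equals(b.ground_truth)

    def test_first_trial_loss_drops_one_pre_trial_per_group(self):
        config = CohortConfig(n_participants=16, block_sizes=(8, 8),
                              n_measurement_trials=20, include_training=False,
                              first_trial_loss=True, seed=9)
        data = simulate_cohort(config)
        pre_counts = data.trials[data.trials["phase"] == "pre"].groupby("participant_id").size()
        assert (pre_counts == 19).sum() == 4 and (pre_counts == 20).sum() == 12

    def test_dropout_rates_are_emulated_in_expectation(self):
        config = CohortConfig(n_participants=400, block_sizes=(8,) * 50,
                              n_measurement_trials=8, filler_rate=0.0,
                              include_training=False, seed=21)
        data = simulate_cohort(config)
        present = data.questionnaires.groupby("timepoint").size()
        # binomial 3-sigma bands around 0.06 / 0.11
        assert abs(400 - present[2] - 0.06 * 400) < 3 * np.sqrt(400 * 0.06 * 0.94)
        assert abs(400 - present[3] - 0.11 * 400) < 3 * np.sqrt(400 * 0.11 * 0.89)
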