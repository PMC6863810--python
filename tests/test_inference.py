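"""Correlations, mixed-design ANOVA, and the mixed-model ladder."""

import numpy as np
import pandas as pd
import pytest

from abmprobe.inference import (
    correlate,
    fit_lmm,
    fit_lmm_set,
    likelihood_ratio,
    make_long_scores,
    model_comparison_table,
    rm_anova_bias,
)


class TestCorrelate:
    def test_identity_gives_r_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_matches_closed_form_on_printed_pairs(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 5.0])
        r, _ = correlate(x, y)
        # hand formula: cov / (sd_x sd_y)
        expect = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expect)

    def test_pairwise_deletion_of_missing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.2]
        r, _ = correlate(x, y)
        r_complete, _ = correlate([1.0, 2.0, 5.0], [1.1, 2.2, 5.2])
        assert r == pytest.approx(r_complete)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def bias_table_from(values):
    """values: dict participant -> (group, pre, post)."""
    rows = []
    for pid, (group, pre, post) in values.items():
        for phase, v in (("pre", pre), ("post", post)):
            rows.append({"participant_id": pid, "group": group, "phase": phase,
                         "bias_ms": v, "excluded": False})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_strong_interaction_is_detected(self):
        rng = np.random.default_rng(0)
        values = {}
        for i in range(60):
            group = ["2D-mock", "2D-active", "3D-mock", "3D-active"][i % 4]
            pre = rng.normal(0, 5)
            shift = -40.0 if group.endswith("active") else 0.0
            values[f"P{i}"] = (group, pre, pre + shift + rng.normal(0, 5))
        aov = rm_anova_bias(bias_table_from(values))
        p_int = aov.loc[aov["effect"] == "time x group", "p"].item()
        assert p_int < 0.001

    def test_excluded_participants_are_removed(self):
        values = {f"P{i}": ("2D-mock" if i % 2 else "3D-active", float(i), float(i) + 1)
                  for i in range(12)}
        table = bias_table_from(values)
        table.loc[table["participant_id"] == "P0", "excluded"] = True
        aov = rm_anova_bias(table)
        assert len(aov) == 3  # group, time, interaction rows

    def test_degenerate_identical_values_flagged(self):
        values = {f"P{i}": ("2D-mock" if i % 2 else "3D-active", 5.0, 5.0) for i in range(8)}
        with pytest.raises(ValueError, match="degenerate"):
            rm_anova_bias(bias_table_from(values))

    def test_tiny_groups_rejected(self):
        values = {"P0": ("2D-mock", 1.0, 2.0), "P1": ("3D-active", 2.0, 1.0)}
        with pytest.raises(ValueError, match=">= 2"):
            rm_anova_bias(bias_table_from(values))


def exact_linear_long(n=40, intercept=70.0, slope=-5.9):
    """Deterministic trajectories with participant intercept offsets only."""
    rows = []
    for i in range(n):
        offset = (i - n / 2) * 0.8
        condition, stimuli = i % 2, (i // 2) % 2
        for t in range(4):
            rows.append({"participant_id": f"P{i}", "time": t,
                         "condition": condition, "stimuli": stimuli,
                         "score": intercept + offset + slope * t})
    return pd.DataFrame(rows)


class TestLmm:
    def test_noiseless_data_recovers_the_generating_slope_exactly(self):
        fit = fit_lmm(exact_linear_long(), "time")
        est = fit.fixed_effects.set_index("term")["estimate"]
        # the likelihood is singular without residual noise, so the iterative
        # fit stops at optimizer precision rather than machine precision
        assert est["time"] == pytest.approx(-5.9, abs=1e-3)
        assert est["Intercept"] == pytest.approx(70.0 - 0.4, abs=1e-3)

    def test_aic_identity_holds_for_every_fit(self, small_scores):
        groups = small_scores.drop_duplicates("participant_id").set_index(
            "participant_id")["group"]
        long = make_long_scores(small_scores, groups)
        fits = fit_lmm_set(long)
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.log_likelihood)
        # ML logLik never decreases as fixed effects are added
        by_id = {f.model_id: f for f in fits}
        assert by_id["time"].log_likelihood >= by_id["null"].log_likelihood - 1e-6
        assert by_id["full"].log_likelihood >= by_id["time*condition"].log_likelihood - 1e-6
        comparison = model_comparison_table(fits)
        assert comparison["AIC"].is_monotonic_increasing

    def test_containment_df_pattern(self, small_scores):
        groups = small_scores.drop_duplicates("participant_id").set_index(
            "participant_id")["group"]
        long = make_long_scores(small_scores, groups)
        fit = fit_lmm(long, "time * condition * stimuli", "full")
        df = fit.fixed_effects.set_index("term")["df"]
        n_obs, n_subj = len(long), long["participant_id"].nunique()
        # within-participant terms share one df; between terms another
        assert df["time"] == n_obs - n_subj - 4
        assert df["condition"] == n_subj - 1 - 3
        assert df["time:condition:stimuli"] == df["time"]

    def test_likelihood_ratio_of_identical_models_is_null(self, small_scores):
        groups = small_scores.drop_duplicates("participant_id").set_index(
            "participant_id")["group"]
        long = make_long_scores(small_scores, groups)
        fit = fit_lmm(long, "time")
        stat, df, p = likelihood_ratio(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_likelihood_ratio_matches_loglik_arithmetic(self, small_scores):
        groups = small_scores.drop_duplicates("participant_id").set_index(
            "participant_id")["group"]
        long = make_long_scores(small_scores, groups)
        nested = fit_lmm(long, "time * condition", "time*condition")
        full = fit_lmm(long, "time * condition * stimuli", "full")
        stat, df, _ = likelihood_ratio(nested, full)
        assert stat == pytest.approx(
            max(2 * (full.log_likelihood - nested.log_likelihood), 0.0))
        assert df == full.n_params - nested.n_params == 4

    def test_non_nested_models_rejected(self, small_scores):
        groups = small_scores.drop_duplicates("participant_id").set_index(
            "participant_id")["group"]
        long = make_long_scores(small_scores, groups)
        a = fit_lmm(long, "condition", "condition")
        b = fit_lmm(long, "time", "time")
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio(a, b)

    def test_unknown_group_label_raises(self, small_cohort):
        groups = pd.Series(dtype=object)
        with pytest.raises(ValueError, match="group label"):
            make_long_scores(small_cohort.questionnaires, groups)
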