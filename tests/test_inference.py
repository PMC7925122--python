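import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from selfblind.inference import (
    ACCUMULATIVE_COVARIATE_CANDIDATES,
    InsufficientDataError,
    cohen_d,
    fit_accumulative,
    fit_acute,
    power_sample_size,
    screen_covariates,
    strata_analysis,
)

from conftest import accumulative_dataset, acute_dataset


class TestCohenD:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        assert cohen_d(x, x) == 0.0

    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50_000)
        y = rng.normal(1, 1, 50_000)
        assert cohen_d(x, y) == pytest.approx(1.0, abs=0.02)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 2, 13)
        y = rng.normal(1, 3, 17)
        pooled = np.sqrt(
            (12 * x.var(ddof=1) + 16 * y.var(ddof=1)) / 28
        )
        assert cohen_d(x, y) == pytest.approx((y.mean() - x.mean()) / pooled)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohen_d([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            cohen_d([1.0, 1.0], [1.0, 1.0])


class TestPower:
    def test_small_effect_closed_form(self):
        # d = 0.3, 90% power, alpha 0.05 -> 234 per group
        assert power_sample_size(delta=3.0, sd=10.0) == 468

    def test_huge_effect_minimal_n(self):
        assert power_sample_size(delta=10.0, sd=1.0) <= 6

    def test_inverse_square_scaling(self):
        n1 = power_sample_size(delta=2.0, sd=10.0)
        n2 = power_sample_size(delta=1.0, sd=10.0)
        assert n2 == pytest.approx(4 * n1, rel=0.02)

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            power_sample_size(delta=0.0, sd=1.0)


class TestScreening:
    def test_candidate_list_has_twelve_entries(self):
        assert len(ACCUMULATIVE_COVARIATE_CANDIDATES) == 12

    def test_outcome_identical_candidate_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(40), 2),
                "y": rng.normal(0, 1, 80),
            }
        )
        df["self"] = df["y"]
        df["noise"] = rng.normal(0, 1, 80)
        retained = screen_covariates(df, "y", ["self", "noise"])
        assert "self" in retained

    def test_missing_candidate_column_rejected(self):
        df = pd.DataFrame({"participant_id": [1, 2], "y": [0.0, 1.0]})
        with pytest.raises(KeyError):
            screen_covariates(df, "y", ["absent"])

    def test_null_candidate_retention_near_alpha(self):
        # a pure-noise candidate should be retained in roughly 5% of trials
        rng = np.random.default_rng(2)
        hits = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "participant_id": np.arange(60),
                    "y": rng.normal(0, 1, 60),
                    "noise": rng.normal(0, 1, 60),
                }
            )
            hits += "noise" in screen_covariates(df, "y", ["noise"])
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestAcuteModel:
    def test_all_one_condition_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b"],
                "value": [1.0, 2.0, 3.0, 4.0],
                "condition": ["PL"] * 4,
                "guess": ["PL"] * 4,
            }
        )
        with pytest.raises(InsufficientDataError):
            fit_acute(df)

    def test_expectancy_only_effect_absorbed_by_guess(self):
        # planted beta_cond = 0, beta_guess > 0: the condition contrast is
        # significant without the guess term and loses significance with it
        df = acute_dataset(191, beta_cond=0.0, beta_guess=6.0, seed=3)
        plain = fit_acute(df)
        adj = fit_acute(df, include_guess=True)
        p_plain = plain.contrasts.iloc[0]["p"]
        p_adj = adj.contrasts.iloc[0]["p"]
        assert p_plain < 0.05
        assert p_adj > 0.05

    def test_true_drug_effect_survives_guess_adjustment(self):
        df = acute_dataset(191, beta_cond=6.0, beta_guess=6.0, seed=4)
        adj = fit_acute(df, include_guess=True)
        row = adj.contrasts.iloc[0]
        assert row["p"] < 0.01
        assert row["ci_low"] < 6.0 < row["ci_high"]


class TestAccumulativeModel:
    def test_single_subject_per_group_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b"],
                "group": ["PL", "PL", "MD", "MD"],
                "timepoint": ["week5", "week9"] * 2,
                "change": [0.1, 0.2, 0.3, 0.4],
            }
        )
        with pytest.raises(InsufficientDataError):
            fit_accumulative(df)

    def test_shared_improvement_with_expectancy_only(self):
        # everyone improves; the extra drift is expectancy-driven, so
        # within-group changes are significant while between-group
        # contrasts stay null
        df = accumulative_dataset(
            220, gamma_time=3.0, gamma_expect=0.3, gamma_drug=0.0,
            subject_sd=2.0, resid_sd=3.0, seed=5,
        )
        res = fit_accumulative(df)
        within = res.contrasts[
            res.contrasts["label"].str.contains("change at week5")
        ]
        between = res.contrasts[res.contrasts["label"].str.contains(" vs ")]
        assert (within["p"] < 0.05).all()
        assert (between["p"] > 0.05).all()

    def test_md_guess_covariate_shrinks_between_group_difference(self):
        df = accumulative_dataset(
            240, gamma_time=2.0, gamma_expect=0.5, gamma_drug=0.0,
            subject_sd=2.0, resid_sd=3.0, seed=6,
        )
        plain = fit_accumulative(df)
        adj = fit_accumulative(df, include_md_guess=True)

        def md_contrast(res):
            row = res.contrasts[res.contrasts["label"] == "PL vs MD at week5"]
            return abs(row["estimate"].iloc[0])

        assert md_contrast(adj) < md_contrast(plain)


class TestStrata:
    def test_four_comparisons_and_occupancy(self):
        df = acute_dataset(80, beta_guess=4.0, seed=7)
        means, comps = strata_analysis({"vas_mood": df})
        assert len(comps) == 4
        assert sorted(comps["comparison_type"].value_counts().to_dict().items()) == [
            ("fixed_condition", 2),
            ("fixed_guess", 2),
        ]
        assert means["occupancy"].sum() == pytest.approx(1.0)

    def test_empty_stratum_flagged_unavailable(self):
        df = acute_dataset(60, seed=8)
        # force guess == condition: perfect blind breaking empties the
        # discordant strata
        df["guess"] = df["condition"]
        means, comps = strata_analysis({"x": df})
        assert not comps["available"].all()
        unavailable = comps[~comps["available"]]
        assert unavailable[["estimate", "p"]].isna().all().all()


class TestDegenerateLimit:
    def test_mixed_model_matches_ols_without_subject_variance(self):
        # balanced conditions within subject and zero subject variance:
        # the mixed-model fixed effects must agree with OLS to 6 decimals
        rng = np.random.default_rng(10)
        rows = []
        for i in range(60):
            for j, cond in enumerate(["PL", "PL", "MD", "MD"]):
                rows.append(
                    {
                        "participant_id": f"s{i}",
                        "value": 10 + 2.0 * (cond == "MD") + rng.normal(0, 1),
                        "condition": cond,
                        "guess": "PL",
                    }
                )
        df = pd.DataFrame(rows)
        mixed = fit_acute(df)
        X = sm.add_constant((df["condition"] == "MD").astype(float).to_numpy())
        ols = sm.OLS(df["value"].to_numpy(), X).fit()
        assert mixed.params["cond"] == pytest.approx(ols.params[1], abs=1e-6)
        assert mixed.params["Intercept"] == pytest.approx(ols.params[0], abs=1e-6)
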