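import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from miccea.costing import COST_GROUPS, price_resource_use
from miccea.errors import ValidationError
from miccea.synthetic_data import (
    ClusterSD,
    DropoutModel,
    TrialConfig,
    TrialDataset,
    generate_trial,
    impose_missingness,
    simulate,
)


class TestReproducibility:
    def test_same_config_and_seed_bit_identical(self, small_config):
        d1 = simulate(small_config)
        d2 = simulate(small_config)
        pd.testing.assert_frame_equal(d1.patients, d2.patients, check_exact=True)
        pd.testing.assert_frame_equal(d1.resource_use, d2.resource_use, check_exact=True)

    def test_different_seed_differs(self, small_config):
        d1 = simulate(small_config)
        d2 = simulate(small_config.replace(seed=small_config.seed + 1))
        assert not d1.patients["age"].equals(d2.patients["age"])

    def test_roundtrip_through_files(self, small_trial, tmp_path):
        small_trial.write(tmp_path)
        back = TrialDataset.read(tmp_path)
        assert back.config == small_trial.config
        pd.testing.assert_frame_equal(
            back.patients, small_trial.patients, check_exact=False, rtol=1e-9,
            check_dtype=False,
        )


class TestStructure:
    def test_every_patient_one_home_every_home_one_arm(self, small_trial):
        p = small_trial.patients
        assert p["home_id"].notna().all()
        arm_per_home = p.groupby("home_id")["arm"].nunique()
        assert (arm_per_home == 1).all()
        assert p.groupby("arm")["home_id"].nunique().eq(2).all()

    def test_utilities_truncated_to_unit_interval(self, small_trial):
        p = small_trial.patients
        for col in ("utility_baseline_true", "utility_6m_true"):
            assert p[col].between(0, 1).all()

    def test_panel_present_implies_applicable(self, clean_trial):
        p = clean_trial.patients
        for k in range(1, 33):
            assert (p[f"ind_pres_{k}"] <= p[f"ind_app_{k}"]).all()

    def test_truth_columns_retained_after_masking(self, small_trial):
        p = small_trial.patients
        assert p["utility_6m_true"].notna().all()
        lost = p["dropout"] | p["died"]
        if lost.any():
            assert p.loc[lost, "utility_6m"].isna().all()


class TestDegenerateMechanisms:
    def test_no_mechanisms_no_missingness(self, clean_trial):
        p = clean_trial.patients
        assert p["died"].sum() == 0
        assert p["dropout"].sum() == 0
        assert p["utility_6m"].notna().all()
        assert clean_trial.resource_use["quantity"].notna().all()

    def test_zero_probability_intercept_leaves_dataset_unchanged(self, clean_config):
        cfg = clean_config.replace(
            dropout_model=DropoutModel(intercept=-np.inf, beta_age=0.01, beta_gars=0.0)
        )
        ds = simulate(cfg)
        assert ds.patients["dropout"].sum() == 0


@pytest.fixture(scope="module")
def big():
    cfg = TrialConfig(
        residents_per_home_mean=1000,
        participation_prob=1.0,
        mortality_prob=0.0,
        no_baseline_prob=0.0,
        cost_missing_prob=0.0,
        cluster_sd=ClusterSD(0, 0, 0, 0),
        seed=29,
    )
    return cfg, generate_trial(cfg)


@pytest.fixture(scope="module")
def big_missing():
    cfg = TrialConfig(
        residents_per_home_mean=1000,
        participation_prob=1.0,
        mortality_prob=0.0,
        no_baseline_prob=0.0,
        cluster_sd=ClusterSD(0, 0, 0, 0),
        seed=37,
    )
    return cfg, simulate(cfg)


class TestCalibration:
    """Configured moments are recovered at large n (clustering off so the
    Monte-Carlo error is the patient-level one)."""

    def test_baseline_utility_mean(self, big):
        cfg, ds = big
        u = ds.patients["utility_baseline"]
        se = cfg.utility_sd / np.sqrt(len(u))
        assert abs(u.mean() - cfg.utility_mean) < 3 * se

    def test_group_cost_means_per_arm(self, big):
        cfg, ds = big
        costs = price_resource_use(ds.resource_use, ds.prices)
        costs = costs.join(ds.patients.set_index("patient_id")["arm"])
        for g in COST_GROUPS:
            sd = cfg.uc_cost_means[g] / np.sqrt(cfg.cost_shapes[g])
            for arm in ("MIC", "UC"):
                target = cfg.uc_cost_means[g] + (
                    cfg.effect_cost * cfg.cost_effect_shares[g] if arm == "MIC" else 0.0
                )
                v = costs.loc[costs["arm"] == arm, g]
                # loose x1.5 factor: the GARS cost loading inflates variance
                assert abs(v.mean() - target) < 3 * 1.5 * sd / np.sqrt(len(v))

    def test_quality_score_margins_and_effect(self, big):
        cfg, ds = big
        from miccea.outcomes import build_outcomes

        out = build_outcomes(ds.patients, indicator_count=32)
        m = out.groupby("arm")["qoc_score"].agg(["mean", "std", "count"])
        prev_mean = 100 * np.mean(cfg.indicator_prevalences)
        se_uc = m.loc["UC", "std"] / np.sqrt(m.loc["UC", "count"])
        assert abs(m.loc["UC", "mean"] - prev_mean) < 3 * se_uc
        diff = m.loc["MIC", "mean"] - m.loc["UC", "mean"]
        se_diff = np.sqrt(
            m.loc["MIC", "std"] ** 2 / m.loc["MIC", "count"]
            + m.loc["UC", "std"] ** 2 / m.loc["UC", "count"]
        )
        assert abs(diff - cfg.effect_qoc) < 3 * se_diff

    def test_null_effects_balanced_arms(self):
        cfg = TrialConfig(
            residents_per_home_mean=600,
            participation_prob=1.0,
            mortality_prob=0.0,
            no_baseline_prob=0.0,
            cost_missing_prob=0.0,
            effect_qoc=0.0,
            effect_cost=0.0,
            effect_utility=0.0,
            effect_coopwonca=0.0,
            cluster_sd=ClusterSD(0, 0, 0, 0),
            seed=31,
        )
        ds = generate_trial(cfg)
        costs = price_resource_use(ds.resource_use, ds.prices)
        costs = costs.join(ds.patients.set_index("patient_id")["arm"])
        g = costs.groupby("arm")["total"]
        diff = g.mean().loc["MIC"] - g.mean().loc["UC"]
        se = np.sqrt(sum(g.var() / g.count()))
        assert abs(diff) < 3 * se
        u = ds.patients.groupby("arm")["utility_6m"]
        assert abs(u.mean().loc["MIC"] - u.mean().loc["UC"]) < 3 * np.sqrt(
            sum(u.var() / u.count())
        )


class TestDropout:
    def test_dropout_rate_matches_mean_predicted_probability(self, big_missing):
        cfg, ds = big_missing
        p = ds.patients
        rate = p["dropout"].mean()
        expected = p["dropout_prob"].mean()
        se = np.sqrt(expected * (1 - expected) / len(p))
        assert abs(rate - expected) < 3 * se

    def test_noncompleters_older_by_about_two_years(self, big_missing):
        _, ds = big_missing
        p = ds.patients
        gap = p.loc[p["dropout"], "age"].mean() - p.loc[~p["dropout"], "age"].mean()
        assert gap == pytest.approx(2.0, abs=0.5)

    def test_noncompleters_better_adl_by_about_minus_3_4(self, big_missing):
        _, ds = big_missing
        p = ds.patients
        g = "gars_baseline_true"
        gap = p.loc[p["dropout"], g].mean() - p.loc[~p["dropout"], g].mean()
        assert gap == pytest.approx(-3.4, abs=0.6)

    def test_missingness_monotone_in_age_decile_and_tracks_logistic(self):
        cfg = TrialConfig(
            residents_per_home_mean=2000,
            homes_per_arm=2,
            participation_prob=1.0,
            mortality_prob=0.0,
            no_baseline_prob=0.0,
            dropout_model=DropoutModel(intercept=-1.0, beta_age=0.15, beta_gars=0.0),
            cluster_sd=ClusterSD(0, 0, 0, 0),
            seed=41,
        )
        ds = simulate(cfg)
        p = ds.patients
        dec = pd.qcut(p["age"], 10, labels=False)
        rates = p.groupby(dec)["dropout"].mean()
        # monotone non-decreasing in age decile (tiny wiggle tolerated)
        assert np.all(np.diff(rates.to_numpy()) > -0.02)
        # empirical rate per decile tracks the logistic curve at decile means
        mean_age = p.groupby(dec)["age"].mean()
        pred = expit(-1.0 + 0.15 * (mean_age - 86.0))
        n_per = p.groupby(dec).size()
        se = np.sqrt(pred * (1 - pred) / n_per)
        assert (np.abs(rates - pred) < 4 * se).all()

    def test_masking_is_mar_given_retained_covariates(self, big_missing):
        # masked columns depend on dropout which is a function of observed
        # age and gars only: within a fine (age, gars) cell, the dropout
        # indicator must be independent of the (retained) true outcome
        _, ds = big_missing
        p = ds.patients.copy()
        p["cell"] = pd.qcut(p["age"], 6, labels=False) * 10 + pd.qcut(
            p["gars_baseline_true"], 6, labels=False
        )
        corrs = []
        for _, grp in p.groupby("cell"):
            if grp["dropout"].nunique() == 2 and len(grp) > 50:
                corrs.append(grp["dropout"].astype(float).corr(grp["utility_6m_true"]))
        assert abs(np.mean(corrs)) < 0.05


class TestValidation:
    @pytest.mark.parametrize(
        "kw,msg",
        [
            (dict(mortality_prob=1.5), "mortality_prob"),
            (dict(homes_per_arm=0), "homes_per_arm"),
            (dict(utility_sd=-0.1), "utility_sd"),
            (dict(cost_family="weibull"), "cost_family"),
            (dict(indicator_prevalences=(0.5, 0.5)), "indicator_prevalences"),
            (dict(cost_shapes={"primary_care": -1}), "cost_shapes"),
        ],
    )
    def test_invalid_field_named_in_error(self, kw, msg):
        with pytest.raises(ValidationError, match=msg):
            generate_trial(TrialConfig(**kw))

    def test_lognormal_family_matches_gamma_mean(self):
        cfg = TrialConfig(
            residents_per_home_mean=800,
            participation_prob=1.0,
            cost_family="lognormal",
            cluster_sd=ClusterSD(0, 0, 0, 0),
            seed=43,
        )
        ds = generate_trial(cfg)
        costs = price_resource_use(ds.resource_use, ds.prices)
        costs = costs.join(ds.patients.set_index("patient_id")["arm"])
        uc = costs.loc[costs["arm"] == "UC", "medication"]
        se = uc.std() / np.sqrt(len(uc))
        assert abs(uc.mean() - cfg.uc_cost_means["medication"]) < 4 * se
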