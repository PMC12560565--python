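"""Treatment-effect strategies: structure, recovery, collapse, counterfactuals."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from psapredict.design import ARMS
from psapredict.penalized import PenaltySpec
from psapredict.simulate import (ARM_STRATUM, SimulationConfig,
                                 default_trial_config, simulate_cohort)
from psapredict.strategies import (fit_effect_model, fit_homogeneous,
                                   fit_risk_model, predict_counterfactuals,
                                   summarize_impact)

SELECTED = ("haq", "lei", "tjc68", "vas_phys_global", "tnfi_history")


def _lp_cohort(seed, n_per_arm, gamma_etn=0.0):
    """Cohort whose outcome depends on treatment through a shared LP only.

    Two standard-normal predictors form lp = 0.9 z1 − 0.6 z2; the etanercept
    arm modifies the LP slope by ``gamma_etn``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for arm in ARMS:
        z1 = rng.normal(size=n_per_arm)
        z2 = rng.normal(size=n_per_arm)
        lp = 0.9 * z1 - 0.6 * z2
        eta = 0.1 + lp + (gamma_etn * lp if arm == "ETN_DF" else 0.0)
        y = rng.binomial(1, expit(eta))
        for i in range(n_per_arm):
            pid += 1
            rows.append({
                "patient_id": f"P{pid}", "arm": arm,
                "stratum": ARM_STRATUM[arm],
                "z1": z1[i], "z2": z2[i], "mda_week16": int(y[i]),
            })
    return pd.DataFrame(rows)


class TestHomogeneous:
    def test_arm_contrast_recovery_near_zero_penalty(self):
        cfg = default_trial_config(n_per_arm=500)
        cohort = simulate_cohort(cfg, seed=21)
        model = fit_homogeneous(cohort, SELECTED, lam=1e-6)
        truth = cfg.true_treatment_effects
        for arm in ("TOFA_DN", "ETN_DF", "TOFA_DF"):
            est = model.fit.coef[f"arm_{arm}"]
            assert est == pytest.approx(truth[arm] - truth["MTX_DN"], abs=0.15)

    def test_arm_swap_shifts_log_odds_by_coefficient_difference(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_homogeneous(trial_cohort, ("haq", "lei"))
        row = trial_cohort.iloc[[0]]
        assert row["stratum"].iloc[0] == "DN"
        p_mtx = model.predict_proba(row, arm="MTX_DN")[0]
        p_tofa = model.predict_proba(row, arm="TOFA_DN")[0]
        lo = np.log(p_tofa / (1 - p_tofa)) - np.log(p_mtx / (1 - p_mtx))
        assert lo == pytest.approx(model.fit.coef["arm_TOFA_DN"], abs=1e-10)

    def test_reference_patient_probability_is_expit_intercept(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_homogeneous(trial_cohort, ("haq", "crp"))
        ref = trial_cohort[trial_cohort.arm == "MTX_DN"].iloc[[0]].copy()
        # a patient sitting at the training mean of every predictor
        for name in ("haq", "crp"):
            ref[name] = model.design.center[name]
        p = model.predict_proba(ref)[0]
        assert p == pytest.approx(expit(model.fit.intercept), abs=1e-12)

    def test_requires_all_arms_and_a_predictor(self, trial_cohort):
        with pytest.raises(ValueError, match="predictor"):
            fit_homogeneous(trial_cohort, ())
        dn_only = trial_cohort[trial_cohort.stratum == "DN"]
        with pytest.raises(ValueError, match="arm"):
            fit_homogeneous(dn_only, ("haq",))


class TestRiskModel:
    def test_lp_excludes_intercept_and_is_zero_at_training_mean(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_risk_model(trial_cohort, ("haq", "lei"))
        ref = trial_cohort.iloc[[0]].copy()
        dm1 = model.stage1_design
        for name in dm1.predictor_columns:
            # raw value whose standardized version is exactly 0
            ref[name] = dm1.center.get(name, 0.0)
        if "lei" not in dm1.center:  # counts standardized too; guard regardless
            ref["lei"] = dm1.center.get("lei", 0.0)
        assert model.linear_predictor(ref)[0] == pytest.approx(0.0, abs=1e-12)

    def test_lp_invariant_to_stage1_intercept_shift(self, trial_cohort):
        from dataclasses import replace

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_risk_model(trial_cohort, ("haq", "lei"))
        lp = model.linear_predictor(trial_cohort)
        model.stage1_fit = replace(model.stage1_fit,
                                   intercept=model.stage1_fit.intercept + 5.0)
        np.testing.assert_array_equal(lp, model.linear_predictor(trial_cohort))

    def test_stage2_structure(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_risk_model(trial_cohort, ("haq", "lei"))
        assert len(model.stage2_columns) == 7  # 3 dummies + LP + 3 interactions
        assert "stratum_DF" not in model.lp_coefficients

    def test_interaction_recovery_from_lp_generative_model(self):
        """Stage 2 recovers a shared LP×treatment interaction at λ→0."""
        errs = []
        for seed in range(3):
            cohort = _lp_cohort(seed, n_per_arm=1000, gamma_etn=0.5)
            model = fit_risk_model(cohort, ("z1", "z2"),
                                   stage1_lam=1e-7, stage2_lam=1e-7)
            est = model.stage2_fit.coef["lp_x_ETN_DF"]
            errs.append(est - 0.5)
        assert np.max(np.abs(errs)) < 0.2
        # arms without generative interaction stay near zero
        assert abs(model.stage2_fit.coef["lp_x_TOFA_DN"]) < 0.2

    def test_zeroed_interactions_give_constant_arm_contrast(self, trial_cohort):
        from dataclasses import replace

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_risk_model(trial_cohort, ("haq", "lei"))
        coef = dict(model.stage2_fit.coef)
        for a in ("TOFA_DN", "ETN_DF", "TOFA_DF"):
            coef[f"lp_x_{a}"] = 0.0
        model.stage2_fit = replace(model.stage2_fit, coef=coef)
        pairs = predict_counterfactuals(model, trial_cohort)
        for _, grp in pairs.groupby("stratum"):
            lo = (np.log(grp.p_tofacitinib / (1 - grp.p_tofacitinib))
                  - np.log(grp.p_comparator / (1 - grp.p_comparator)))
            assert np.ptp(lo.to_numpy()) < 1e-9

    def test_too_few_tofacitinib_patients_rejected(self, trial_cohort):
        small = pd.concat([
            trial_cohort[trial_cohort.arm == a].head(5 if "TOFA" in a else 20)
            for a in ARMS
        ])
        with pytest.raises(ValueError, match="tofacitinib"):
            fit_risk_model(small, ("haq",))


class TestEffectModel:
    def test_no_generative_interactions_collapse_to_homogeneous(self):
        cfg = default_trial_config(n_per_arm=250)
        cohort = simulate_cohort(cfg, seed=17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            effect = fit_effect_model(cohort, SELECTED, cv=10)
            homog = fit_homogeneous(cohort, SELECTED, cv=10)
        assert effect.selected_interactions == ()
        np.testing.assert_allclose(effect.predict_proba(cohort),
                                   homog.predict_proba(cohort), atol=1e-6)

    def test_strong_true_interaction_is_selected(self):
        cfg = default_trial_config(n_per_arm=500)
        base = SimulationConfig(
            n_per_arm=500, covariate_specs=cfg.covariate_specs,
            true_intercept=cfg.true_intercept, true_beta=cfg.true_beta,
            true_treatment_effects=cfg.true_treatment_effects,
            true_interactions={("haq", "TOFA_DN"): 1.4, ("haq", "TOFA_DF"): 1.4},
        )
        cohort = simulate_cohort(base, seed=23)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_effect_model(cohort, SELECTED, cv=10)
        selected_preds = {p for p, _ in model.selected_interactions}
        assert "haq" in selected_preds

    def test_reference_arm_interactions_never_constructed(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_effect_model(trial_cohort, ("haq", "lei"), cv=10)
        assert all(arm != "MTX_DN" for _, arm in model.selected_interactions)
        assert not any(c.endswith("_x_MTX_DN") for c in model.fit.coef)


class TestCounterfactuals:
    def test_homogeneous_delta_sign_constant_within_stratum(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_homogeneous(trial_cohort, ("haq", "lei"))
        pairs = predict_counterfactuals(model, trial_cohort)
        for _, grp in pairs.groupby("stratum"):
            signs = np.sign(grp["delta"].to_numpy())
            assert len(set(signs[signs != 0])) == 1

    def test_homogeneous_delta_peaks_near_half_probability(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_homogeneous(trial_cohort, ("haq", "lei", "tjc68"))
        pairs = predict_counterfactuals(model, trial_cohort)
        grp = pairs[pairs.stratum == "DN"]
        dist = np.abs(grp["p_comparator"] - 0.5).to_numpy()
        mag = np.abs(grp["delta"].to_numpy())
        assert mag[np.argmin(dist)] >= mag[np.argmax(dist)]

    def test_cross_stratum_counterfactual_rejected(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_homogeneous(trial_cohort, ("haq",))
        dn = trial_cohort[trial_cohort.stratum == "DN"]
        with pytest.raises(ValueError, match="cross-stratum"):
            model.predict_proba(dn, arm="ETN_DF")

    def test_probabilities_and_favored_are_consistent(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_risk_model(trial_cohort, ("haq", "lei"))
        pairs = predict_counterfactuals(model, trial_cohort)
        assert pairs["p_tofacitinib"].between(0, 1, inclusive="neither").all()
        assert pairs["delta"].between(-1, 1, inclusive="neither").all()
        fav = np.where(pairs.delta > 0, "tofacitinib",
                       np.where(pairs.stratum == "DN", "mtx", "etn"))
        assert (pairs.loc[pairs.delta != 0, "favored"]
                == fav[pairs.delta != 0]).all()


class TestImpactSummary:
    def test_summary_matches_direct_aggregation(self, trial_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_homogeneous(trial_cohort, ("haq", "lei"))
        pairs = predict_counterfactuals(model, trial_cohort)
        table = summarize_impact(pairs).set_index("stratum")
        for stratum, grp in pairs.groupby("stratum"):
            d = grp["delta"].to_numpy()
            assert table.loc[stratum, "delta_min"] == pytest.approx(d.min())
            assert table.loc[stratum, "delta_max"] == pytest.approx(d.max())
            assert table.loc[stratum, "delta_median"] == pytest.approx(np.median(d))

    def test_all_negative_deltas_give_full_comparator_preference(self):
        pairs = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(4)],
            "stratum": ["DF"] * 4,
            "p_tofacitinib": [0.3, 0.4, 0.2, 0.35],
            "p_comparator": [0.4, 0.45, 0.3, 0.5],
            "delta": [-0.1, -0.05, -0.1, -0.15],
            "favored": ["etn"] * 4,
        })
        table = summarize_impact(pairs)
        assert table.loc[0, "pct_favor_comparator"] == 100.0

    def test_exact_tie_reported_and_excluded(self):
        pairs = pd.DataFrame({
            "patient_id": ["P1", "P2"], "stratum": ["DN", "DN"],
            "p_tofacitinib": [0.5, 0.6], "p_comparator": [0.5, 0.4],
            "delta": [0.0, 0.2], "favored": ["tie", "tofacitinib"],
        })
        with pytest.warns(RuntimeWarning, match="tie"):
            table = summarize_impact(pairs)
        assert table.loc[0, "n_ties"] == 1
        assert table.loc[0, "pct_favor_tofacitinib"] == 100.0
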