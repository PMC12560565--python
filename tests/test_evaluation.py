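"""AUC / ROC correctness and the nested-LOOCV evaluation loop."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psapredict.evaluation import auc, nested_loocv, roc_curve
from psapredict.penalized import PenaltySpec
from psapredict.strategies import fit_homogeneous


def brute_force_auc(p, y):
    """O(n²) pairwise concordance with 0.5 for ties."""
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_simple_cases(self):
        assert auc([0.9, 0.1], [1, 0]) == 1.0
        assert auc([0.1, 0.9], [1, 0]) == 0.0
        assert auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(0)
        p = np.round(rng.uniform(size=200), 2)  # rounding forces ties
        y = rng.binomial(1, 0.5, 200)
        assert auc(p, y) == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        p = rng.uniform(size=300)
        y = rng.binomial(1, p)
        assert auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.8], [1, 1])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=40))
    def test_invariant_under_monotone_transform(self, probs):
        p = np.asarray(probs)
        y = (np.arange(len(p)) % 2).astype(float)
        a = auc(p, y)
        assert auc(np.log(p / (1 - p)), y) == pytest.approx(a, abs=1e-12)
        assert auc(p**3, y) == pytest.approx(a, abs=1e-12)


class TestRoc:
    def test_perfect_classifier_passes_through_top_left(self):
        pts = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any(np.allclose(pt, [0.0, 1.0]) for pt in pts)

    def test_trapezoid_area_equals_auc(self):
        rng = np.random.default_rng(2)
        p = np.round(rng.uniform(size=150), 2)
        y = rng.binomial(1, 0.5, 150)
        pts = roc_curve(p, y)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc(p, y), abs=1e-12)

    def test_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=80)
        y = rng.binomial(1, 0.5, 80)
        pts = roc_curve(p, y)
        assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_probability_reversal_flips_auc(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=60)
        y = rng.binomial(1, p)
        assert auc(1 - p, y) == pytest.approx(1 - auc(p, y), abs=1e-12)


class _ConstantModel:
    lam = 1.0

    def predict_proba(self, rows, arm=None):
        return np.full(len(rows), 0.5)


class TestNestedLoocv:
    def test_constant_half_prediction_gives_auc_half(self, trial_cohort):
        res = nested_loocv(lambda train: _ConstantModel(), trial_cohort)
        assert res.auc_outer == 0.5
        assert res.auc_inner == 0.5

    def test_separable_signal_reaches_auc_one(self, trial_cohort):
        cohort = trial_cohort.copy()
        rng = np.random.default_rng(0)
        # bimodal disability with a wide margin: no noise near the boundary
        group = np.arange(len(cohort)) % 2
        cohort["haq"] = np.where(group, 2.8, 0.2) + rng.normal(0, 0.02, len(cohort))
        cohort["mda_week16"] = group

        def recipe(train):
            return fit_homogeneous(train, ("haq",),
                                   spec=PenaltySpec(alpha=0.0, n_lambda=30))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = nested_loocv(recipe, cohort)
        assert res.auc_outer == 1.0

    def test_fixed_lambda_recipe_equals_plain_loocv(self, trial_cohort):
        """With λ frozen, the nested loop degenerates to plain LOOCV."""
        lam = 0.2

        def recipe(train):
            return fit_homogeneous(train, ("haq", "lei"), lam=lam)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = nested_loocv(recipe, trial_cohort)
            manual = np.empty(len(trial_cohort))
            for i in range(len(trial_cohort)):
                train = trial_cohort.drop(index=trial_cohort.index[i])
                model = fit_homogeneous(train, ("haq", "lei"), lam=lam)
                manual[i] = model.predict_proba(trial_cohort.iloc[[i]])[0]
        np.testing.assert_allclose(res.held_out_prob, manual, atol=1e-12)

    def test_outer_lambdas_and_roc_reported(self, trial_cohort):
        def recipe(train):
            return fit_homogeneous(train, ("haq",),
                                   spec=PenaltySpec(alpha=0.0, n_lambda=20))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = nested_loocv(recipe, trial_cohort)
        assert np.isfinite(res.outer_lambdas).sum() == len(trial_cohort)
        assert res.final_lambda > 0
        area = np.trapezoid(res.roc_points[:, 1], res.roc_points[:, 0])
        assert area == pytest.approx(res.auc_outer, abs=1e-12)

    def test_small_cohort_rejected(self, trial_cohort):
        with pytest.raises(ValueError, match="n ≥ 20"):
            nested_loocv(lambda t: _ConstantModel(), trial_cohort.head(10))
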