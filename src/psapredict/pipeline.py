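"""End-to-end analysis pipeline: screen → select → fit → evaluate → impact.

This module glues the stages together the way the trial analysis runs them:
transformation screening and elastic-net predictor selection on the full
cohort, then the three Ridge-based treatment-effect strategies, nested LOOCV
evaluation, and per-patient counterfactual comparison under the two
stratum-consistent treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import partial

import pandas as pd

from .design import BASELINE_PREDICTORS, screen_transforms
from .evaluation import NestedCvResult, nested_loocv
from .penalized import PenaltySpec
from .selection import SelectionReport, select_union
from .strategies import (fit_effect_model, fit_homogeneous, fit_risk_model,
                         predict_counterfactuals, summarize_impact)

__all__ = ["AnalysisSettings", "AnalysisResult", "make_recipe", "run_analysis"]

log = logging.getLogger("psapredict")

STRATEGIES = ("homogeneous", "risk", "effect")


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunable pipeline settings (α, λ grid, CV flavour, evaluation scope)."""

    alpha_select: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    #: selection grids stop higher (the convention for p comparable to n):
    #: below ~λ_max/100 the elastic net saturates small cohorts outright and
    #: λ_1se never lands there
    select_lambda_min_ratio: float = 1e-2
    skewness_threshold: float = 1.0
    cv: int | None = None          # None = leave-one-out
    #: when the elastic net selects nothing: "error" (the default, matching
    #: the selection contract) or "all_candidates" — keep every candidate
    #: and rely on Ridge shrinkage, the pragmatic analyst fallback
    on_empty_selection: str = "error"
    strategies: tuple[str, ...] = STRATEGIES
    evaluate: tuple[str, ...] = ("homogeneous", "risk")
    reselect_in_outer_loop: bool = False
    candidate_predictors: tuple[str, ...] = BASELINE_PREDICTORS

    def select_spec(self) -> PenaltySpec:
        return PenaltySpec(alpha=self.alpha_select, n_lambda=self.n_lambda,
                           lambda_min_ratio=self.select_lambda_min_ratio)

    def ridge_spec(self) -> PenaltySpec:
        return PenaltySpec(alpha=0.0, n_lambda=self.n_lambda,
                           lambda_min_ratio=self.lambda_min_ratio)


@dataclass
class AnalysisResult:
    transforms: dict
    selection: SelectionReport
    models: dict[str, object]
    evaluations: dict[str, NestedCvResult]
    counterfactuals: dict[str, pd.DataFrame]
    impact: dict[str, pd.DataFrame]


def _fit_one(strategy: str, cohort: pd.DataFrame, selected, transforms,
             settings: AnalysisSettings):
    if strategy == "homogeneous":
        return fit_homogeneous(cohort, selected, transforms,
                               spec=settings.ridge_spec(), cv=settings.cv)
    if strategy == "risk":
        return fit_risk_model(cohort, selected, transforms,
                              spec=settings.ridge_spec(), cv=settings.cv)
    if strategy == "effect":
        return fit_effect_model(cohort, selected, transforms,
                                select_spec=settings.select_spec(),
                                ridge_spec=settings.ridge_spec(), cv=settings.cv)
    raise ValueError(f"unknown strategy {strategy!r}")


def _recipe_fixed(strategy, selected, transforms, settings, train):
    return _fit_one(strategy, train, selected, transforms, settings)


def _recipe_reselect(strategy, settings, train):
    transforms = screen_transforms(train, "mda_week16",
                                   skewness_threshold=settings.skewness_threshold)
    report = select_union(train, settings.candidate_predictors,
                          settings.select_spec(), transforms, cv=settings.cv,
                          require_nonempty=settings.on_empty_selection == "error")
    selected = report.union or settings.candidate_predictors
    return _fit_one(strategy, train, selected, transforms, settings)


def make_recipe(strategy: str, selected, transforms, settings: AnalysisSettings):
    """A callable ``cohort → fitted model`` for nested-CV evaluation.

    With ``reselect_in_outer_loop`` the recipe repeats transformation
    screening and predictor selection on every outer training set (fully
    honest evaluation); otherwise selection is done once on the full data
    and only λ is retuned per fold, matching the two-phase presentation of
    the trial analysis.
    """
    if settings.reselect_in_outer_loop:
        return partial(_recipe_reselect, strategy, settings)
    return partial(_recipe_fixed, strategy, selected, transforms, settings)


def run_analysis(cohort: pd.DataFrame,
                 settings: AnalysisSettings | None = None) -> AnalysisResult:
    """Run the full pipeline on a cohort with the week-16 outcome attached."""
    settings = settings or AnalysisSettings()
    transforms = screen_transforms(cohort, "mda_week16",
                                   skewness_threshold=settings.skewness_threshold)
    chosen = {k: v.chosen for k, v in transforms.items() if v.chosen != "identity"}
    log.info("transform choices (non-identity): %s", chosen or "none")

    selection = select_union(cohort, settings.candidate_predictors,
                             settings.select_spec(), transforms, cv=settings.cv,
                             require_nonempty=settings.on_empty_selection == "error")
    selected = selection.union
    if not selected:
        log.warning("empty selection union; keeping all %d candidates under "
                    "Ridge shrinkage", len(settings.candidate_predictors))
        selected = settings.candidate_predictors
    log.info("selected predictors (union): %s", list(selection.union))
    for name, fit in selection.fits.items():
        if not fit.skipped:
            log.info("  %s (n=%d): λ_1se=%.4g selected=%s",
                     name, fit.n, fit.lambda_1se, list(fit.selected))

    models: dict[str, object] = {}
    for s in settings.strategies:
        models[s] = _fit_one(s, cohort, selected, transforms, settings)
        log.info("fitted %s model (λ=%.4g)", s, models[s].lam)

    evaluations: dict[str, NestedCvResult] = {}
    for s in settings.evaluate:
        recipe = make_recipe(s, selected, transforms, settings)
        evaluations[s] = nested_loocv(recipe, cohort)
        log.info("nested LOOCV %s: AUC outer=%.3f inner=%.3f final λ=%.4g",
                 s, evaluations[s].auc_outer, evaluations[s].auc_inner,
                 evaluations[s].final_lambda)

    counterfactuals = {s: predict_counterfactuals(m, cohort) for s, m in models.items()}
    impact = {s: summarize_impact(cf) for s, cf in counterfactuals.items()}
    return AnalysisResult(
        transforms=transforms, selection=selection, models=models,
        evaluations=evaluations, counterfactuals=counterfactuals, impact=impact,
    )
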