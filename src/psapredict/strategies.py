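"""The three treatment-effect prediction strategies and counterfactual prediction.

* **Homogeneous** — one Ridge logistic model on the selected predictors plus
  treatment dummies; the treatment effect is constant on the log-odds scale.
* **Risk modelling** — a two-stage heterogeneous-effect model: stage 1 fits a
  general response model on tofacitinib-treated patients only (selected
  predictors + DN/DF stratum indicator); a linear predictor (LP) is computed
  for every patient from the stage-1 predictor coefficients, excluding the
  intercept and the stratum/treatment terms; stage 2 regresses the outcome
  on treatment dummies, the LP, and LP×treatment interactions.
* **Effect modelling** — all predictor×treatment interaction columns are
  offered to an elastic net (main effects and treatment forced, only
  interactions selectable); the final Ridge model keeps the selected
  interactions.  With an empty selection this collapses exactly to the
  homogeneous model.

Counterfactual prediction evaluates a fitted model twice per patient — under
the stratum-consistent tofacitinib arm and under the stratum comparator
(methotrexate for DN, etanercept for DF) — holding covariates fixed; the
difference in predicted response probability drives treatment preference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (ARMS, REFERENCE_ARM, TransformChoice, DesignMatrix,
                     build_design_matrix)
from .penalized import CvPath, PenaltySpec, PenalizedFit, fit_penalized, loocv_path

__all__ = [
    "HomogeneousModel",
    "RiskModel",
    "EffectModel",
    "fit_homogeneous",
    "fit_risk_model",
    "fit_effect_model",
    "predict_counterfactuals",
    "summarize_impact",
    "TOFA_ARM",
    "COMPARATOR_ARM",
]

TOFA_ARM = {"DN": "TOFA_DN", "DF": "TOFA_DF"}
COMPARATOR_ARM = {"DN": "MTX_DN", "DF": "ETN_DF"}
_ARM_STRATUM = {"MTX_DN": "DN", "TOFA_DN": "DN", "ETN_DF": "DF", "TOFA_DF": "DF"}


def _check_arm_consistent(rows: pd.DataFrame, arm: str) -> None:
    strata = set(rows["stratum"])
    want = _ARM_STRATUM[arm]
    if strata - {want}:
        raise ValueError(
            f"cross-stratum counterfactual requested: arm {arm} is a {want} arm "
            f"but rows include stratum {sorted(strata - {want})}"
        )


@dataclass
class HomogeneousModel:
    """Ridge model with a constant treatment effect on the log-odds scale."""

    design: DesignMatrix
    fit: PenalizedFit
    cv_path: CvPath | None = field(default=None, repr=False)

    @property
    def lam(self) -> float:
        return self.fit.lam

    def predict_proba(self, cohort: pd.DataFrame, arm: str | None = None) -> np.ndarray:
        if arm is not None:
            _check_arm_consistent(cohort, arm)
        X = self.design.transform(cohort, arm_override=arm)
        return self.fit.predict_proba(X.to_numpy(dtype=float), list(X.columns))


def fit_homogeneous(
    cohort: pd.DataFrame,
    selected_predictors: tuple[str, ...],
    transforms: dict[str, TransformChoice] | dict[str, str] | None = None,
    outcome: str = "mda_week16",
    spec: PenaltySpec | None = None,
    cv: int | None = None,
    lam: float | None = None,
) -> HomogeneousModel:
    """Fit the homogeneous treatment-effect model (Ridge, LOOCV λ_1se)."""
    if len(selected_predictors) == 0:
        raise ValueError("at least one selected predictor is required")
    missing = [a for a in ARMS if a not in set(cohort["arm"])]
    if missing:
        raise ValueError(f"cohort lacks treatment arm(s): {missing}")
    spec = spec or PenaltySpec(alpha=0.0)
    dm = build_design_matrix(
        cohort, selected_predictors, transforms,
        include_treatment=True, standardize=True,
    )
    y = cohort[outcome].to_numpy(dtype=float)
    path = None
    if lam is None:
        path = loocv_path(dm.values, y, dm.columns, spec, cv=cv)
        lam = path.lambda_1se
    fit = fit_penalized(dm.values, y, dm.columns, spec, lam)
    return HomogeneousModel(design=dm, fit=fit, cv_path=path)


@dataclass
class RiskModel:
    """Two-stage risk-modelling strategy: tofacitinib LP × treatment."""

    stage1_design: DesignMatrix
    stage1_fit: PenalizedFit
    lp_coefficients: dict[str, float]
    stage2_fit: PenalizedFit
    stage2_columns: tuple[str, ...]
    stage1_path: CvPath | None = field(default=None, repr=False)
    stage2_path: CvPath | None = field(default=None, repr=False)

    @property
    def lam(self) -> float:
        return self.stage2_fit.lam

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        """LP = Σ stage-1 predictor coefficients × predictor values.

        No intercept and no stratum/treatment contribution: adding any
        constant to the stage-1 intercept leaves every patient's LP
        unchanged.
        """
        X = self.stage1_design.transform(cohort)
        lp = np.zeros(len(cohort))
        for name, b in self.lp_coefficients.items():
            lp += b * X[name].to_numpy(dtype=float)
        return lp

    def _stage2_matrix(self, cohort: pd.DataFrame, arm: str | None) -> np.ndarray:
        lp = self.linear_predictor(cohort)
        arms = np.full(len(cohort), arm) if arm else cohort["arm"].to_numpy()
        cols = []
        for a in ARMS:
            if a == REFERENCE_ARM:
                continue
            cols.append((arms == a).astype(float))
        cols.append(lp)
        for a in ARMS:
            if a == REFERENCE_ARM:
                continue
            cols.append(lp * (arms == a))
        return np.column_stack(cols)

    def predict_proba(self, cohort: pd.DataFrame, arm: str | None = None) -> np.ndarray:
        if arm is not None:
            _check_arm_consistent(cohort, arm)
        X2 = self._stage2_matrix(cohort, arm)
        return self.stage2_fit.predict_proba(X2, list(self.stage2_columns))


def fit_risk_model(
    cohort: pd.DataFrame,
    selected_predictors: tuple[str, ...],
    transforms: dict[str, TransformChoice] | dict[str, str] | None = None,
    outcome: str = "mda_week16",
    spec: PenaltySpec | None = None,
    cv: int | None = None,
    stage1_lam: float | None = None,
    stage2_lam: float | None = None,
    stage2_unpenalized: bool = False,
    min_stage1_n: int = 20,
) -> RiskModel:
    """Fit the two-stage risk model (both stages Ridge with LOOCV λ_1se).

    ``stage2_unpenalized`` replaces the stage-2 penalty with a numerically
    negligible one (λ = 1e−8) for sensitivity analyses.
    """
    if len(selected_predictors) == 0:
        raise ValueError("at least one selected predictor is required")
    spec = spec or PenaltySpec(alpha=0.0)
    tofa = cohort[cohort["arm"].isin(["TOFA_DN", "TOFA_DF"])]
    if len(tofa) < min_stage1_n:
        raise ValueError(
            f"risk modelling needs ≥{min_stage1_n} tofacitinib patients, got {len(tofa)}"
        )
    dm1 = build_design_matrix(
        tofa, selected_predictors, transforms,
        include_treatment=False, include_stratum=True,
        standardize=True, drop_constant=True,
    )
    y1 = tofa[outcome].to_numpy(dtype=float)
    path1 = None
    if stage1_lam is None:
        path1 = loocv_path(dm1.values, y1, dm1.columns, spec, cv=cv)
        stage1_lam = path1.lambda_1se
    fit1 = fit_penalized(dm1.values, y1, dm1.columns, spec, stage1_lam)
    lp_coef = {c: fit1.coef[c] for c in dm1.predictor_columns}
    if all(v == 0.0 for v in lp_coef.values()):
        raise RuntimeError(
            "stage-1 coefficients are all zero (over-shrunk); inspect the λ path"
        )

    stage2_columns = tuple(
        [f"arm_{a}" for a in ARMS if a != REFERENCE_ARM]
        + ["lp"]
        + [f"lp_x_{a}" for a in ARMS if a != REFERENCE_ARM]
    )
    model = RiskModel(
        stage1_design=dm1, stage1_fit=fit1, lp_coefficients=lp_coef,
        stage2_fit=None, stage2_columns=stage2_columns, stage1_path=path1,
    )
    lp = model.linear_predictor(cohort)
    if np.var(lp) == 0.0:
        raise RuntimeError("degenerate linear predictor (zero variance across cohort)")
    X2 = model._stage2_matrix(cohort, None)
    y = cohort[outcome].to_numpy(dtype=float)
    path2 = None
    if stage2_unpenalized:
        stage2_lam = 1e-8
    elif stage2_lam is None:
        path2 = loocv_path(X2, y, list(stage2_columns), spec, cv=cv)
        stage2_lam = path2.lambda_1se
    fit2 = fit_penalized(X2, y, list(stage2_columns), spec, stage2_lam)
    model.stage2_fit = fit2
    model.stage2_path = path2
    return model


@dataclass
class EffectModel:
    """Effect-modelling strategy: selected predictor×treatment interactions."""

    design: DesignMatrix
    selected_interactions: tuple[tuple[str, str], ...]  # (predictor, arm)
    fit: PenalizedFit
    cv_path: CvPath | None = field(default=None, repr=False)
    selection_path: CvPath | None = field(default=None, repr=False)

    @property
    def lam(self) -> float:
        return self.fit.lam

    def _matrix(self, cohort: pd.DataFrame, arm: str | None) -> tuple[np.ndarray, list[str]]:
        X = self.design.transform(cohort, arm_override=arm)
        cols = list(X.columns)
        mat = [X.to_numpy(dtype=float)]
        for pred, a in self.selected_interactions:
            mat.append((X[pred] * X[f"arm_{a}"]).to_numpy(dtype=float)[:, None])
            cols.append(f"{pred}_x_{a}")
        return np.hstack(mat), cols

    def predict_proba(self, cohort: pd.DataFrame, arm: str | None = None) -> np.ndarray:
        if arm is not None:
            _check_arm_consistent(cohort, arm)
        X, cols = self._matrix(cohort, arm)
        return self.fit.predict_proba(X, cols)


def fit_effect_model(
    cohort: pd.DataFrame,
    selected_predictors: tuple[str, ...],
    transforms: dict[str, TransformChoice] | dict[str, str] | None = None,
    outcome: str = "mda_week16",
    select_spec: PenaltySpec | None = None,
    ridge_spec: PenaltySpec | None = None,
    cv: int | None = None,
    lam: float | None = None,
) -> EffectModel:
    """Fit the effect model: elastic-net interaction selection, then Ridge.

    Interaction columns are products of the (standardized) predictor and the
    arm dummy, for the three non-reference arms; only interactions are
    eligible for selection — main effects and treatment are forced.
    """
    if len(selected_predictors) == 0:
        raise ValueError("at least one selected predictor is required")
    dm = build_design_matrix(
        cohort, selected_predictors, transforms,
        include_treatment=True, standardize=True,
    )
    y = cohort[outcome].to_numpy(dtype=float)
    base_cols = dm.columns
    X_base = dm.values

    inter_cols: list[str] = []
    inter_pairs: list[tuple[str, str]] = []
    mats = [X_base]
    for pred in dm.predictor_columns:
        for a in ARMS:
            if a == REFERENCE_ARM:
                continue
            col = dm.X[pred].to_numpy(dtype=float) * dm.X[f"arm_{a}"].to_numpy(dtype=float)
            if col.std() == 0.0:
                continue  # predictor constant within that arm
            mats.append(col[:, None])
            inter_cols.append(f"{pred}_x_{a}")
            inter_pairs.append((pred, a))
    X_all = np.hstack(mats)
    all_cols = base_cols + inter_cols

    sel_spec = select_spec or PenaltySpec(alpha=0.5, lambda_min_ratio=1e-2)
    sel_spec = PenaltySpec(
        alpha=sel_spec.alpha, n_lambda=sel_spec.n_lambda,
        lambda_min_ratio=sel_spec.lambda_min_ratio,
        ridge_lambda_max=sel_spec.ridge_lambda_max,
        lambda_grid=sel_spec.lambda_grid,
        unpenalized=tuple(base_cols),
    )
    sel_path = loocv_path(X_all, y, all_cols, sel_spec, cv=cv)
    sel_fit = fit_penalized(X_all, y, all_cols, sel_spec, sel_path.lambda_1se)
    selected = tuple(
        pair for pair, col in zip(inter_pairs, inter_cols) if sel_fit.coef[col] != 0.0
    )

    ridge_spec = ridge_spec or PenaltySpec(alpha=0.0)
    model = EffectModel(design=dm, selected_interactions=selected, fit=None,
                        selection_path=sel_path)
    X_final, cols_final = model._matrix(cohort, None)
    path = None
    if lam is None:
        path = loocv_path(X_final, y, cols_final, ridge_spec, cv=cv)
        lam = path.lambda_1se
    model.fit = fit_penalized(X_final, y, cols_final, ridge_spec, lam)
    model.cv_path = path
    return model


# ----------------------------------------------------------- counterfactuals


def predict_counterfactuals(model, cohort: pd.DataFrame) -> pd.DataFrame:
    """Predicted response probability under tofacitinib vs the stratum comparator.

    For each patient the fitted model is evaluated twice, holding covariates
    (and, for the risk model, the LP) fixed: once under the
    stratum-consistent tofacitinib arm, once under the comparator arm
    (methotrexate for DN, etanercept for DF).  Returns one row per patient
    with ``p_tofacitinib``, ``p_comparator``, ``delta`` and ``favored``.
    """
    pieces = []
    for stratum, rows in cohort.groupby("stratum", sort=False):
        p_tofa = model.predict_proba(rows, arm=TOFA_ARM[stratum])
        p_comp = model.predict_proba(rows, arm=COMPARATOR_ARM[stratum])
        delta = p_tofa - p_comp
        favored = np.where(
            delta > 0, "tofacitinib",
            np.where(delta < 0, COMPARATOR_ARM[stratum].split("_")[0].lower(), "tie"),
        )
        pieces.append(pd.DataFrame({
            "patient_id": rows["patient_id"].to_numpy(),
            "stratum": stratum,
            "p_tofacitinib": p_tofa,
            "p_comparator": p_comp,
            "delta": delta,
            "favored": favored,
        }, index=rows.index))
    out = pd.concat(pieces).loc[cohort.index]
    return out


_COMPARATOR_NAME = {"DN": "mtx", "DF": "etn"}


def summarize_impact(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum summary of counterfactual differences (impact table).

    Reports the range and median of delta (tofacitinib minus comparator) and
    the percentage of patients favoring each treatment; exact ties are
    reported separately and excluded from the percentages.
    """
    rows = []
    for stratum, grp in pairs.groupby("stratum", sort=False):
        if len(grp) == 0:
            continue
        delta = grp["delta"].to_numpy()
        ties = int(np.sum(delta == 0.0))
        n_eff = len(grp) - ties
        rows.append({
            "stratum": stratum,
            "n": len(grp),
            "comparator": _COMPARATOR_NAME[stratum],
            "delta_min": float(delta.min()),
            "delta_max": float(delta.max()),
            "delta_median": float(np.median(delta)),
            "pct_favor_tofacitinib": 100.0 * np.sum(delta > 0) / n_eff if n_eff else float("nan"),
            "pct_favor_comparator": 100.0 * np.sum(delta < 0) / n_eff if n_eff else float("nan"),
            "n_ties": ties,
        })
        if ties:
            warnings.warn(
                f"{ties} exact tie(s) in stratum {stratum} excluded from percentages",
                RuntimeWarning, stacklevel=2,
            )
    return pd.DataFrame(rows)
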