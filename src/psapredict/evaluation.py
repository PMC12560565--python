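"""Nested leave-one-out cross-validated performance (AUC-ROC) and ROC curves.

AUC is the Mann–Whitney concordance probability (ties count 0.5), so it is
invariant under any strictly monotone transform of the predicted
probabilities.  Nested LOOCV wraps the entire model-fitting recipe —
including, for the risk model, the stage-1 refit and LP recomputation — in
an outer leave-one-out loop; λ is tuned by the recipe's own inner LOOCV on
each outer training set, and the outer held-out predictions give an
optimism-corrected AUC.  The inner-tuned refit on the full data provides
the (optimistic) resubstitution AUC for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["NestedCvResult", "auc", "roc_curve", "nested_loocv"]


def auc(probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann–Whitney AUC: U / (n₁·n₀), with tied predictions counting 0.5."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = rankdata(p)  # average ranks handle ties as 0.5 concordance
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_curve(probabilities: np.ndarray, outcomes: np.ndarray) -> np.ndarray:
    """ROC points, one per distinct threshold, from (0,0) to (1,1).

    Returns an array of (FPR, TPR) rows, monotone non-decreasing in both
    coordinates; the trapezoidal area under these points equals :func:`auc`
    (tied predictions contribute the diagonal segment).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n1 = np.sum(y == 1)
    n0 = np.sum(y == 0)
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC requires both outcome classes")
    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    distinct = np.nonzero(np.diff(p_sorted))[0]  # last index of each tie block
    idx = np.concatenate([distinct, [len(p) - 1]])
    tpr = np.concatenate([[0.0], tp[idx] / n1])
    fpr = np.concatenate([[0.0], fp[idx] / n0])
    return np.column_stack([fpr, tpr])


@dataclass
class NestedCvResult:
    """Outcome of a nested leave-one-out evaluation of one strategy."""

    held_out_prob: np.ndarray
    outcomes: np.ndarray
    outer_lambdas: np.ndarray
    auc_outer: float
    auc_inner: float
    final_lambda: float
    auc_outer_centered: float = float("nan")
    roc_points: np.ndarray = field(repr=False, default=None)
    skipped_folds: tuple[int, ...] = ()


def nested_loocv(
    fit_strategy: Callable[[pd.DataFrame], object],
    cohort: pd.DataFrame,
    outcome: str = "mda_week16",
) -> NestedCvResult:
    """Nested LOOCV evaluation of a model-fitting recipe.

    ``fit_strategy`` must accept a training cohort (DataFrame) and return a
    fitted model exposing ``predict_proba(rows)`` and a ``lam`` attribute
    (the λ its inner LOOCV chose).  The outer loop leaves each patient out
    and reruns the entire recipe on the remaining patients; the recipe
    decides itself whether predictor selection is repeated (pass a recipe
    that reselects for a fully honest evaluation).

    ``auc_outer`` pools the n held-out predicted probabilities — the
    standard nested-LOOCV performance estimate.  Pooled leave-one-out
    predictions carry a known pessimistic artifact: the fitted intercept
    tracks the training prevalence, which moves by ∓1/(n−1) depending on the
    left-out outcome, so a heavily shrunk (near-null) model ranks responders
    systematically *below* non-responders and its pooled AUC falls below
    0.5 even on pure noise.  ``auc_outer_centered`` removes exactly that
    artifact by ranking the held-out log-odds minus the logit of each
    fold's training prevalence; for an exactly-null model every centered
    score is 0 and the AUC is 0.5.  ``auc_inner`` is the resubstitution AUC
    of the recipe refitted on the full data; ``final_lambda`` is that
    full-data fit's inner-LOOCV λ — the λ reported for the final model.
    """
    n = len(cohort)
    if n < 20:
        raise ValueError("nested LOOCV requires n ≥ 20")
    y = cohort[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes are required")

    held = np.full(n, np.nan)
    centered = np.full(n, np.nan)
    lams = np.full(n, np.nan)
    skipped = []
    for i in range(n):
        train = cohort.drop(index=cohort.index[i])
        if train[outcome].nunique() < 2:
            skipped.append(i)
            warnings.warn(
                f"outer fold {i}: single outcome class in training set; skipped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        model = fit_strategy(train)
        p = float(model.predict_proba(cohort.iloc[[i]])[0])
        held[i] = p
        ybar = float(train[outcome].mean())
        p_c = min(max(p, 1e-12), 1 - 1e-12)
        centered[i] = np.log(p_c / (1 - p_c)) - np.log(ybar / (1 - ybar))
        lams[i] = float(getattr(model, "lam", np.nan))

    valid = ~np.isnan(held)
    auc_outer = auc(held[valid], y[valid])
    auc_centered = auc(centered[valid], y[valid])
    final_model = fit_strategy(cohort)
    auc_inner = auc(final_model.predict_proba(cohort), y)
    return NestedCvResult(
        held_out_prob=held,
        outcomes=y,
        outer_lambdas=lams,
        auc_outer=auc_outer,
        auc_inner=auc_inner,
        auc_outer_centered=auc_centered,
        final_lambda=float(getattr(final_model, "lam", np.nan)),
        roc_points=roc_curve(held[valid], y[valid]),
        skipped_folds=tuple(skipped),
    )
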