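"""Baseline predictor selection: elastic net in the full cohort and subgroups.

Elastic-net selection is run four times — in the full cohort, in all
tofacitinib-treated patients (both strata), in the methotrexate arm and in
the etanercept arm — each with a leave-one-out cross-validated λ path and the
λ_1se rule.  A candidate predictor is selected by a fit when its coefficient
is non-zero at λ_1se; the final relevant set is the union over the four
fits, with provenance recording which fits selected each predictor.

Design variables (treatment dummies in the full-cohort fit, the DN/DF
stratum indicator in the tofacitinib fit) are included as penalized
covariates but are never themselves eligible for selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .design import TransformChoice, build_design_matrix
from .penalized import CvPath, PenaltySpec, fit_penalized, loocv_path

__all__ = ["SelectionError", "SubgroupFit", "SelectionReport", "select_union"]

_SUBGROUPS = ("full_cohort", "tofacitinib", "methotrexate", "etanercept")


class SelectionError(RuntimeError):
    """No predictor was selected in any fit; inspect the CV paths."""


@dataclass(frozen=True)
class SubgroupFit:
    """Result of one elastic-net selection fit."""

    name: str
    n: int
    selected: tuple[str, ...]
    lambda_1se: float
    cv_path: CvPath = field(repr=False)
    coef: dict[str, float] = field(repr=False, default_factory=dict)
    dropped_constant: tuple[str, ...] = ()
    skipped: bool = False
    skip_reason: str = ""


@dataclass(frozen=True)
class SelectionReport:
    """Union of predictors selected across the full cohort and subgroups."""

    fits: dict[str, SubgroupFit]
    union: tuple[str, ...]
    provenance: dict[str, tuple[str, ...]]

    def provenance_table(self) -> pd.DataFrame:
        rows = [
            {"predictor": p, "selected_in": ", ".join(fits), "n_fits": len(fits)}
            for p, fits in self.provenance.items()
        ]
        return pd.DataFrame(rows, columns=["predictor", "selected_in", "n_fits"])


def _subgroup_rows(cohort: pd.DataFrame, name: str) -> pd.DataFrame:
    if name == "full_cohort":
        return cohort
    if name == "tofacitinib":
        return cohort[cohort["arm"].isin(["TOFA_DN", "TOFA_DF"])]
    if name == "methotrexate":
        return cohort[cohort["arm"] == "MTX_DN"]
    if name == "etanercept":
        return cohort[cohort["arm"] == "ETN_DF"]
    raise ValueError(name)


def _run_fit(
    name: str,
    rows: pd.DataFrame,
    outcome: str,
    candidates: tuple[str, ...],
    transforms,
    spec: PenaltySpec,
    cv: int | None,
) -> SubgroupFit:
    y = rows[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        return SubgroupFit(
            name=name, n=len(rows), selected=(), lambda_1se=float("nan"),
            cv_path=None, skipped=True,
            skip_reason="single outcome class in subgroup",
        )
    dm = build_design_matrix(
        rows,
        predictors=candidates,
        transforms=transforms,
        include_treatment=(name == "full_cohort"),
        include_stratum=(name == "tofacitinib"),
        standardize=True,
        drop_constant=True,
    )
    path = loocv_path(dm.values, y, dm.columns, spec, cv=cv)
    fit = fit_penalized(dm.values, y, dm.columns, spec, path.lambda_1se)
    eligible = set(dm.predictor_columns)  # design variables never "selected"
    selected = tuple(c for c in dm.predictor_columns
                     if c in eligible and fit.coef[c] != 0.0)
    return SubgroupFit(
        name=name, n=len(rows), selected=selected, lambda_1se=path.lambda_1se,
        cv_path=path, coef=dict(fit.coef), dropped_constant=dm.dropped_constant,
    )


def select_union(
    cohort: pd.DataFrame,
    candidate_predictors: tuple[str, ...],
    spec: PenaltySpec | None = None,
    transforms: dict[str, TransformChoice] | dict[str, str] | None = None,
    outcome: str = "mda_week16",
    cv: int | None = None,
    require_nonempty: bool = True,
) -> SelectionReport:
    """Run the four elastic-net selection fits and take the union.

    Parameters
    ----------
    cohort
        Patient-level table with the candidate predictor columns, ``arm``,
        ``stratum`` and the binary outcome column.
    candidate_predictors
        Baseline covariates eligible for selection.  Candidates that are
        constant within a subgroup (e.g. TNFi history among DMARD-naïve
        patients) are dropped from that fit only.
    spec
        Elastic-net penalty settings; defaults to α = 0.5 with the standard
        100-point λ grid.
    cv
        ``None`` for leave-one-out (the trial-scale default); an integer for
        k-fold on large simulated cohorts.
    require_nonempty
        When true (default), an empty union raises :class:`SelectionError`
        since downstream models need at least one predictor.
    """
    # selection grid stops at λ_max/100: with p comparable to n the deeper
    # tail only saturates the fits, and λ_1se never lands there
    spec = spec or PenaltySpec(alpha=0.5, lambda_min_ratio=1e-2)
    if spec.alpha <= 0:
        raise ValueError("selection requires an L1 component: alpha must be > 0")
    fits: dict[str, SubgroupFit] = {}
    for name in _SUBGROUPS:
        rows = _subgroup_rows(cohort, name)
        fit = _run_fit(name, rows, outcome, tuple(candidate_predictors),
                       transforms, spec, cv)
        if fit.skipped:
            warnings.warn(
                f"selection fit {name!r} skipped: {fit.skip_reason}",
                RuntimeWarning, stacklevel=2,
            )
        fits[name] = fit

    provenance: dict[str, list[str]] = {}
    for name, fit in fits.items():
        for pred in fit.selected:
            provenance.setdefault(pred, []).append(name)
    union = tuple(sorted(provenance))
    if not union and require_nonempty:
        raise SelectionError(
            "elastic net selected no predictors in any fit; inspect the CV "
            "paths (λ_1se may sit at the null model) or relax α/λ settings"
        )
    return SelectionReport(
        fits=fits,
        union=union,
        provenance={p: tuple(v) for p, v in provenance.items()},
    )
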