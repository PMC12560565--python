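"""Predictor design matrices: transformation screening, encoding, standardization.

Skewed continuous predictors are screened against natural-log and square-root
transformations by univariable logistic fit (lowest deviance wins, one degree
of freedom per candidate); treatment enters as three dummy columns against
the methotrexate DMARD-naïve reference arm; continuous columns are
standardized (mean 0, SD 1 on the training rows) before penalized fitting,
with the standardization parameters stored so new patients project onto the
same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ARMS",
    "REFERENCE_ARM",
    "CONTINUOUS_PREDICTORS",
    "BINARY_PREDICTORS",
    "BASELINE_PREDICTORS",
    "TransformChoice",
    "DesignMatrix",
    "screen_transforms",
    "build_design_matrix",
]

ARMS = ("MTX_DN", "TOFA_DN", "ETN_DF", "TOFA_DF")
REFERENCE_ARM = "MTX_DN"
TREATMENT_DUMMIES = tuple(f"arm_{a}" for a in ARMS if a != REFERENCE_ARM)

CONTINUOUS_PREDICTORS = (
    "haq", "tjc68", "sjc66", "lei", "vas_phys_global", "vas_pain",
    "vas_pat_global", "bsa", "crp", "bmi", "age", "disease_duration",
)
BINARY_PREDICTORS = ("sex", "tnfi_history", "nail_psoriasis", "dactylitis")
BASELINE_PREDICTORS = CONTINUOUS_PREDICTORS + BINARY_PREDICTORS

#: predictors where zero is a legitimate value, so the log candidate uses log(x+1)
_ZERO_LEGITIMATE = {"tjc68", "sjc66", "lei", "bsa", "crp", "disease_duration",
                    "vas_phys_global", "vas_pain", "vas_pat_global"}

_TRANSFORMS = {
    "identity": lambda x: x,
    "natural_log": None,  # resolved per predictor (offset for legitimate zeros)
    "square_root": np.sqrt,
}


def _log_fn(predictor: str):
    if predictor in _ZERO_LEGITIMATE:
        return np.log1p
    return np.log


def apply_transform(x: pd.Series | np.ndarray, predictor: str, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if name == "identity":
        return x
    if name == "natural_log":
        return _log_fn(predictor)(x)
    if name == "square_root":
        return np.sqrt(x)
    raise ValueError(f"unknown transform {name!r}")


@dataclass(frozen=True)
class TransformChoice:
    """Outcome of transformation screening for one continuous predictor."""

    predictor: str
    candidates: tuple[str, ...]
    chosen: str
    fit_criterion_values: dict[str, float] = field(default_factory=dict)
    skewness: float = float("nan")


def _univariable_deviance(x: np.ndarray, y: np.ndarray) -> float:
    """Deviance of an unpenalized univariable logistic fit (IRLS via statsmodels)."""
    import statsmodels.api as sm

    X = sm.add_constant((x - x.mean()) / (x.std() if x.std() > 0 else 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(res.deviance)


def screen_transforms(
    cohort: pd.DataFrame,
    outcome: str | np.ndarray,
    predictors: tuple[str, ...] = CONTINUOUS_PREDICTORS,
    skewness_threshold: float = 1.0,
) -> dict[str, TransformChoice]:
    """Choose a working scale for each continuous predictor.

    Predictors with |sample skewness| above the threshold are fitted
    univariably on the identity, natural-log and square-root scales; the
    lowest-deviance candidate wins (all candidates have one degree of
    freedom, so this is an AIC comparison).  Non-skewed predictors keep the
    identity scale without any fitting.  Candidates that would take the log
    or root of a negative value are skipped with a warning.
    """
    y = np.asarray(cohort[outcome] if isinstance(outcome, str) else outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    choices: dict[str, TransformChoice] = {}
    for name in predictors:
        x = np.asarray(cohort[name], dtype=float)
        skew = float(stats.skew(x)) if x.std() > 0 else 0.0
        if abs(skew) <= skewness_threshold:
            choices[name] = TransformChoice(
                predictor=name, candidates=("identity",), chosen="identity",
                skewness=skew,
            )
            continue
        devs: dict[str, float] = {}
        for cand in ("identity", "natural_log", "square_root"):
            if cand != "identity" and np.any(x < 0):
                warnings.warn(
                    f"{name}: negative values; skipping {cand} candidate",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            if cand == "natural_log" and name not in _ZERO_LEGITIMATE and np.any(x == 0):
                warnings.warn(
                    f"{name}: zero values without a log offset; skipping natural_log",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            xt = apply_transform(x, name, cand)
            if xt.std() == 0:
                continue
            devs[cand] = _univariable_deviance(xt, y)
        chosen = min(devs, key=devs.get)
        choices[name] = TransformChoice(
            predictor=name, candidates=tuple(devs), chosen=chosen,
            fit_criterion_values=devs, skewness=skew,
        )
    return choices


@dataclass
class DesignMatrix:
    """A numeric predictor matrix plus everything needed to project new patients."""

    X: pd.DataFrame
    predictor_columns: tuple[str, ...]
    treatment_columns: tuple[str, ...]
    extra_columns: tuple[str, ...]
    transforms: dict[str, str]
    center: dict[str, float]
    scale: dict[str, float]
    reference_arm: str = REFERENCE_ARM
    dropped_constant: tuple[str, ...] = ()

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def transform(self, cohort: pd.DataFrame, arm_override: str | None = None) -> pd.DataFrame:
        """Project new patient rows onto the stored training scale."""
        return _assemble(
            cohort,
            predictors=self.predictor_columns,
            transforms=self.transforms,
            include_treatment=bool(self.treatment_columns),
            include_stratum="stratum_DF" in self.extra_columns,
            center=self.center,
            scale=self.scale,
            arm_override=arm_override,
            reference_arm=self.reference_arm,
        )


def _assemble(cohort, predictors, transforms, include_treatment, include_stratum,
              center, scale, arm_override, reference_arm):
    cols: dict[str, np.ndarray] = {}
    for name in predictors:
        if name not in cohort.columns:
            raise ValueError(f"predictor column missing from cohort: {name!r}")
        t = transforms.get(name, "identity")
        xt = apply_transform(cohort[name], name, t)
        if name in center:
            xt = (xt - center[name]) / scale[name]
        cols[name] = xt
    if include_treatment:
        arms = np.full(len(cohort), arm_override) if arm_override else cohort["arm"].to_numpy()
        unseen = set(arms) - set(ARMS)
        if unseen:
            raise ValueError(f"unseen treatment arm label(s): {sorted(unseen)}")
        for dummy in TREATMENT_DUMMIES:
            arm = dummy.removeprefix("arm_")
            cols[dummy] = (arms == arm).astype(float)
    if include_stratum:
        cols["stratum_DF"] = (cohort["stratum"].to_numpy() == "DF").astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def build_design_matrix(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...],
    transforms: dict[str, TransformChoice] | dict[str, str] | None = None,
    include_treatment: bool = True,
    include_stratum: bool = False,
    standardize: bool = True,
    drop_constant: bool = False,
) -> DesignMatrix:
    """Build the numeric design matrix from patient records.

    Continuous predictors are transformed per the screening choices and
    standardized; binary predictors, treatment dummies and the optional
    DN/DF stratum indicator stay on their 0/1 scale.  A zero-variance
    predictor column raises unless ``drop_constant`` is set (subgroup fits
    where e.g. TNFi history is structurally constant), in which case it is
    dropped with a warning and recorded.
    """
    tmap: dict[str, str] = {}
    if transforms:
        for k, v in transforms.items():
            tmap[k] = v.chosen if isinstance(v, TransformChoice) else v

    predictors = tuple(predictors)
    kept = []
    dropped = []
    for name in predictors:
        if name not in cohort.columns:
            raise ValueError(f"predictor column missing from cohort: {name!r}")
        if np.asarray(cohort[name], dtype=float).std() == 0.0:
            if drop_constant:
                dropped.append(name)
                warnings.warn(
                    f"dropping constant predictor column {name!r}", RuntimeWarning,
                    stacklevel=2,
                )
                continue
            raise ValueError(f"zero-variance predictor column: {name!r}")
        kept.append(name)
    if not kept:
        raise ValueError("no non-constant predictors remain")

    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    if standardize:
        for name in kept:
            if name in BINARY_PREDICTORS or set(pd.unique(cohort[name])) <= {0, 1}:
                continue
            xt = apply_transform(cohort[name], name, tmap.get(name, "identity"))
            center[name] = float(xt.mean())
            scale[name] = float(xt.std(ddof=0))

    X = _assemble(
        cohort, kept, tmap, include_treatment, include_stratum,
        center, scale, arm_override=None, reference_arm=REFERENCE_ARM,
    )
    treatment_cols = tuple(c for c in X.columns if c.startswith("arm_"))
    extra = tuple(c for c in X.columns if c == "stratum_DF")
    return DesignMatrix(
        X=X,
        predictor_columns=tuple(kept),
        treatment_columns=treatment_cols,
        extra_columns=extra,
        transforms={k: tmap.get(k, "identity") for k in kept},
        center=center,
        scale=scale,
        dropped_constant=tuple(dropped),
    )
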