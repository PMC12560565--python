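"""File I/O: cohort CSV validation, model JSON export/import, run metadata.

All artifacts are plain text: cohorts as UTF-8 comma-separated CSV with a
header row and empty cells for missing values, models and reports as JSON.
Model JSON carries the intercept, coefficient map, penalty settings,
standardization parameters and transform choices — enough to reproduce
predictions bit-for-bit.  Every output embeds the seed and a hash of the
generating configuration; no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ARMS, BASELINE_PREDICTORS, DesignMatrix
from .mda import MDA_FIELDS
from .penalized import PenalizedFit
from .strategies import EffectModel, HomogeneousModel, RiskModel

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "config_hash",
    "write_json",
    "read_json",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

REQUIRED_COLUMNS = ("patient_id", "stratum", "arm") + BASELINE_PREDICTORS

_RANGE_CHECKS = {
    "haq": (0, 3), "tjc68": (0, 68), "sjc66": (0, 66), "lei": (0, 6),
    "vas_phys_global": (0, 100), "vas_pain": (0, 100), "vas_pat_global": (0, 100),
    "bsa": (0, 100), "crp": (0, np.inf), "bmi": (10, 80), "age": (18, 100),
    "disease_duration": (0, 80), "sex": (0, 1), "tnfi_history": (0, 1),
    "nail_psoriasis": (0, 1), "dactylitis": (0, 1),
}


class CohortValidationError(ValueError):
    """Cohort CSV violates the column dictionary; message carries line numbers."""


def validate_cohort(df: pd.DataFrame, require_outcome: bool = False) -> None:
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    known = set(REQUIRED_COLUMNS) | {f"w16_{f}" for f in MDA_FIELDS} | {
        "mda_week16", "mda_criteria_met", "mda_imputed", "true_p_response",
    }
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown cohort column(s) ignored: {unknown}", stacklevel=2)
    if require_outcome and "mda_week16" not in df.columns:
        raise CohortValidationError("missing outcome column 'mda_week16'")
    for i, (idx, row) in enumerate(df.iterrows()):
        line = i + 2  # header is line 1
        if row["stratum"] not in ("DN", "DF"):
            problems.append(f"line {line}: stratum {row['stratum']!r} not in {{DN, DF}}")
        if row["arm"] not in ARMS:
            problems.append(f"line {line}: arm {row['arm']!r} not in {ARMS}")
        for col, (lo, hi) in _RANGE_CHECKS.items():
            v = row[col]
            if pd.isna(v):
                problems.append(f"line {line}: missing value in {col!r}")
            elif not (lo <= v <= hi):
                problems.append(f"line {line}: {col}={v!r} outside [{lo}, {hi}]")
        if row["stratum"] == "DN" and row.get("tnfi_history", 0) == 1:
            problems.append(f"line {line}: DMARD-naïve patient with tnfi_history=1")
        if len(problems) > 20:
            problems.append("... further problems suppressed")
            break
    if problems:
        raise CohortValidationError("\n".join(problems))


def read_cohort(path: str | Path, require_outcome: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_cohort(df, require_outcome=require_outcome)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


# ------------------------------------------------------------- JSON helpers


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_canonical(v) for v in obj.tolist()]
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(_canonical(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_canonical(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------- model round-trip


def _design_to_dict(dm: DesignMatrix) -> dict:
    return {
        "predictor_columns": list(dm.predictor_columns),
        "treatment_columns": list(dm.treatment_columns),
        "extra_columns": list(dm.extra_columns),
        "transforms": dm.transforms,
        "center": dm.center,
        "scale": dm.scale,
        "reference_arm": dm.reference_arm,
        "dropped_constant": list(dm.dropped_constant),
    }


def _design_from_dict(d: dict) -> DesignMatrix:
    return DesignMatrix(
        X=pd.DataFrame(),
        predictor_columns=tuple(d["predictor_columns"]),
        treatment_columns=tuple(d["treatment_columns"]),
        extra_columns=tuple(d["extra_columns"]),
        transforms=dict(d["transforms"]),
        center={k: float(v) for k, v in d["center"].items()},
        scale={k: float(v) for k, v in d["scale"].items()},
        reference_arm=d["reference_arm"],
        dropped_constant=tuple(d.get("dropped_constant", ())),
    )


def _fit_to_dict(fit: PenalizedFit) -> dict:
    return {
        "intercept": fit.intercept, "coef": fit.coef, "alpha": fit.alpha,
        "lam": fit.lam, "converged": fit.converged, "n_iter": fit.n_iter,
    }


def _fit_from_dict(d: dict) -> PenalizedFit:
    return PenalizedFit(
        intercept=float(d["intercept"]),
        coef={k: float(v) for k, v in d["coef"].items()},
        alpha=float(d["alpha"]), lam=float(d["lam"]),
        converged=bool(d["converged"]), n_iter=int(d["n_iter"]),
    )


def model_to_dict(model) -> dict:
    if isinstance(model, HomogeneousModel):
        return {"strategy": "homogeneous",
                "design": _design_to_dict(model.design),
                "fit": _fit_to_dict(model.fit)}
    if isinstance(model, RiskModel):
        return {"strategy": "risk",
                "stage1_design": _design_to_dict(model.stage1_design),
                "stage1_fit": _fit_to_dict(model.stage1_fit),
                "lp_coefficients": model.lp_coefficients,
                "stage2_fit": _fit_to_dict(model.stage2_fit),
                "stage2_columns": list(model.stage2_columns)}
    if isinstance(model, EffectModel):
        return {"strategy": "effect",
                "design": _design_to_dict(model.design),
                "selected_interactions": [list(p) for p in model.selected_interactions],
                "fit": _fit_to_dict(model.fit)}
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def model_from_dict(d: dict):
    strategy = d["strategy"]
    if strategy == "homogeneous":
        return HomogeneousModel(design=_design_from_dict(d["design"]),
                                fit=_fit_from_dict(d["fit"]))
    if strategy == "risk":
        return RiskModel(
            stage1_design=_design_from_dict(d["stage1_design"]),
            stage1_fit=_fit_from_dict(d["stage1_fit"]),
            lp_coefficients={k: float(v) for k, v in d["lp_coefficients"].items()},
            stage2_fit=_fit_from_dict(d["stage2_fit"]),
            stage2_columns=tuple(d["stage2_columns"]),
        )
    if strategy == "effect":
        return EffectModel(
            design=_design_from_dict(d["design"]),
            selected_interactions=tuple((p, a) for p, a in d["selected_interactions"]),
            fit=_fit_from_dict(d["fit"]),
        )
    raise ValueError(f"unknown strategy in model JSON: {strategy!r}")


def save_model(model, path: str | Path, meta: dict | None = None) -> None:
    d = model_to_dict(model)
    if meta:
        d["meta"] = meta
    write_json(d, path)


def load_model(path: str | Path):
    return model_from_dict(read_json(path))
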