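"""Minimal Disease Activity (MDA): the binary treatment-response outcome.

MDA is the standard composite responder state for psoriatic arthritis: a
patient is in MDA when at least 5 of 7 criteria are met, spanning joints
(tender and swollen joint counts), skin (psoriasis extent as body surface
area), pain and patient global assessment (visual analogue scales), physical
function (HAQ disability index) and entheses (tender entheseal points, here
the Leeds Enthesitis Index).

All thresholds are inclusive (``<=``).  VAS scales are 0-100 mm; a 0-10 cm
dialect can be accommodated by passing custom thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "MDA_THRESHOLDS",
    "MDA_FIELDS",
    "MdaResult",
    "MdaValidationError",
    "compute_mda",
    "compute_mda_with_fallback",
    "add_mda_columns",
]

#: Criterion thresholds, all inclusive. Keys are the component field names.
MDA_THRESHOLDS: dict[str, float] = {
    "tjc68": 1,            # tender joint count (68 joints)
    "sjc66": 1,            # swollen joint count (66 joints)
    "bsa": 3.0,            # body surface area with psoriasis, %
    "vas_pain": 15.0,      # pain VAS, mm
    "vas_pat_global": 20.0,  # patient global disease activity VAS, mm
    "haq": 0.5,            # HAQ disability index
    "lei": 1,              # tender entheseal points (Leeds Enthesitis Index)
}

MDA_FIELDS = tuple(MDA_THRESHOLDS)

#: Patient-reported fields, available at week 16 even when the physical
#: examination is missing; the remaining fields require an examination.
PATIENT_REPORTED_FIELDS = ("haq", "vas_pain", "vas_pat_global")
EXAMINATION_FIELDS = ("tjc68", "sjc66", "bsa", "lei")

# instrument ranges used for validation: (low, high)
_RANGES: dict[str, tuple[float, float]] = {
    "tjc68": (0, 68),
    "sjc66": (0, 66),
    "bsa": (0.0, 100.0),
    "vas_pain": (0.0, 100.0),
    "vas_pat_global": (0.0, 100.0),
    "haq": (0.0, 3.0),
    "lei": (0, 6),
}


class MdaValidationError(ValueError):
    """A component is missing or outside its instrument range."""


@dataclass(frozen=True)
class MdaResult:
    """Outcome of the 7-criterion MDA evaluation for one patient."""

    criteria_met: int
    is_mda: bool
    per_criterion: dict[str, bool] = field(repr=False)
    imputed_from_later_visit: bool = False


def _validate(components: Mapping[str, float]) -> dict[str, float]:
    clean: dict[str, float] = {}
    for name in MDA_FIELDS:
        if name not in components or components[name] is None:
            raise MdaValidationError(f"missing MDA component: {name!r}")
        value = components[name]
        if pd.isna(value):
            raise MdaValidationError(f"missing MDA component: {name!r}")
        low, high = _RANGES[name]
        if not (low <= value <= high):
            raise MdaValidationError(
                f"MDA component {name!r}={value!r} outside instrument range [{low}, {high}]"
            )
        clean[name] = float(value)
    return clean


def compute_mda(
    components: Mapping[str, float],
    thresholds: Mapping[str, float] = MDA_THRESHOLDS,
    *,
    _imputed: bool = False,
) -> MdaResult:
    """Evaluate the 7 MDA criteria and return the responder state.

    Parameters
    ----------
    components
        Mapping with the seven component measurements (keys as in
        :data:`MDA_THRESHOLDS`). Extra keys are ignored.
    thresholds
        Criterion thresholds; override for non-default scale dialects.

    Returns
    -------
    MdaResult
        ``is_mda`` is true iff at least 5 of the 7 criteria are met.
    """
    clean = _validate(components)
    per_criterion = {name: clean[name] <= thresholds[name] for name in MDA_FIELDS}
    met = sum(per_criterion.values())
    return MdaResult(
        criteria_met=met,
        is_mda=met >= 5,
        per_criterion=per_criterion,
        imputed_from_later_visit=_imputed,
    )


def compute_mda_with_fallback(
    week16_patient_reported: Mapping[str, float],
    later_visit_exam: Mapping[str, float] | None = None,
    thresholds: Mapping[str, float] = MDA_THRESHOLDS,
) -> MdaResult:
    """Compute MDA combining week-16 patient-reported outcomes with a later exam.

    When the week-16 physical examination is missing (e.g. a pandemic-era
    skipped visit), the examination components (joint counts, BSA, entheseal
    count) are taken from the first subsequent visit while the week-16
    patient-reported components (HAQ, pain VAS, patient global VAS) are kept.

    If ``week16_patient_reported`` already carries a complete component set,
    the result is identical to :func:`compute_mda` and the imputation flag
    stays false.
    """
    merged: dict[str, float] = {}
    imputed = False
    later = later_visit_exam or {}
    for name in MDA_FIELDS:
        wk = week16_patient_reported.get(name)
        if wk is not None and not pd.isna(wk):
            merged[name] = wk
        elif name in later and not pd.isna(later[name]):
            merged[name] = later[name]
            imputed = True
        else:
            raise MdaValidationError(
                f"MDA component {name!r} missing from both week 16 and the later visit"
            )
    return compute_mda(merged, thresholds, _imputed=imputed)


def add_mda_columns(cohort: pd.DataFrame, prefix: str = "w16_") -> pd.DataFrame:
    """Attach ``mda_week16``, ``mda_criteria_met`` and ``mda_imputed`` columns.

    Expects week-16 component columns named ``<prefix><field>`` (e.g.
    ``w16_tjc68``). Returns a copy; the input frame is not modified.
    """
    out = cohort.copy()
    flags, counts, imput = [], [], []
    for _, row in cohort.iterrows():
        comps = {name: row[f"{prefix}{name}"] for name in MDA_FIELDS}
        res = compute_mda(comps)
        flags.append(int(res.is_mda))
        counts.append(res.criteria_met)
        imput.append(int(bool(row.get("mda_imputed", 0))))
    out["mda_week16"] = flags
    out["mda_criteria_met"] = counts
    out["mda_imputed"] = imput
    return out
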