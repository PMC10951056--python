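"""Clinical derivations: eGFR, daily proteinuria, and treatment-response labels.

Response at six months follows remission-style criteria: proteinuria below
3.5 g/day (measured, or estimated from the urinary total protein to
creatinine ratio) together with stable serum creatinine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

from podometry.errors import FormatError, UnclassifiableError, ValidationError

Sex = Literal["male", "female"]
Timepoint = Literal["biopsy", "month6"]

UMOL_PER_L_TO_MG_PER_DL = 1.0 / 88.42

#: Remission cut-off for daily protein excretion, g/day.
PROTEINURIA_REMISSION_G_DAY = 3.5
#: Equivalent cut-off for the urinary total protein/creatinine ratio, mg/mmol.
UPCR_REMISSION_MG_MMOL = 350.0
#: ACR fallback: values below this are treated as roughly < 0.5 g/day.
ACR_REMISSION_MG_MMOL = 50.0

CLINICAL_COLUMNS = [
    "patient_id",
    "timepoint",
    "age_years",
    "sex",
    "scr_umol_l",
    "proteinuria_g24h",
    "upcr_mg_mmol",
    "acr_mg_mmol",
]

# CKD-EPI creatinine coefficients: kappa (mg/dL), alpha, sex factor, scale,
# age base per vintage.
_CKD_EPI = {
    "2021": {
        "scale": 142.0,
        "age_base": 0.9938,
        "female": {"kappa": 0.7, "alpha": -0.241, "factor": 1.012},
        "male": {"kappa": 0.9, "alpha": -0.302, "factor": 1.0},
    },
    "2009": {
        "scale": 141.0,
        "age_base": 0.993,
        "female": {"kappa": 0.7, "alpha": -0.329, "factor": 1.018},
        "male": {"kappa": 0.9, "alpha": -0.411, "factor": 1.0},
    },
}

_2009_MAX_EXP = -1.209
_2021_MAX_EXP = -1.200


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    timepoint: Timepoint
    age_years: float
    sex: Sex
    scr_umol_l: Optional[float] = None
    proteinuria_g24h: Optional[float] = None
    upcr_mg_mmol: Optional[float] = None
    acr_mg_mmol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timepoint not in ("biopsy", "month6"):
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.age_years <= 0:
            raise ValidationError("age must be > 0")
        for name in ("scr_umol_l", "proteinuria_g24h", "upcr_mg_mmol", "acr_mg_mmol"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be >= 0")


def egfr_ckd_epi(
    scr_umol_l: float,
    age_years: float,
    sex: Sex,
    version: str = "2021",
) -> float:
    """Estimated GFR (mL/min/1.73 m^2) from serum creatinine, age and sex.

    Uses the race-free creatinine CKD-EPI equation (2021 coefficients by
    default; the 2009 coefficients are available via ``version="2009"``).
    Refuses ages below 18, since the adult equation does not apply to
    pediatric patients.
    """
    if age_years < 18:
        raise ValidationError("adult CKD-EPI equation cannot be used below age 18")
    if scr_umol_l <= 0:
        raise ValidationError("serum creatinine must be > 0")
    if version not in _CKD_EPI:
        raise ValidationError(f"unknown CKD-EPI version {version!r}")
    coef = _CKD_EPI[version]
    sex_coef = coef[sex]
    scr_mg_dl = scr_umol_l * UMOL_PER_L_TO_MG_PER_DL
    ratio = scr_mg_dl / sex_coef["kappa"]
    max_exp = _2021_MAX_EXP if version == "2021" else _2009_MAX_EXP
    return (
        coef["scale"]
        * min(ratio, 1.0) ** sex_coef["alpha"]
        * max(ratio, 1.0) ** max_exp
        * coef["age_base"] ** age_years
        * sex_coef["factor"]
    )


def proteinuria_g_per_day(record: ClinicalRecord) -> float:
    """Daily protein excretion in g/day.

    A measured 24-h collection wins; otherwise the urinary total protein to
    creatinine ratio is converted with 100 mg/mmol per g/day (350 mg/mmol
    corresponds to 3.5 g/day).
    """
    if record.proteinuria_g24h is not None:
        return record.proteinuria_g24h
    if record.upcr_mg_mmol is not None:
        return record.upcr_mg_mmol / 100.0
    raise UnclassifiableError(
        f"{record.patient_id}/{record.timepoint}: no proteinuria measure available"
    )


def _has_proteinuria(record: ClinicalRecord) -> bool:
    return record.proteinuria_g24h is not None or record.upcr_mg_mmol is not None


def classify_response(
    biopsy_rec: ClinicalRecord,
    month6_rec: ClinicalRecord,
    creatinine_stability_tol: float = 0.30,
) -> Literal["responder", "non_responder"]:
    """Label a patient responder or non-responder at six months.

    Responder means proteinuria < 3.5 g/day (measured or UPCR-derived) with
    serum creatinine at month 6 no more than ``(1 + tol)`` times baseline.
    Fallbacks for incomplete data: an ACR below ~50 mg/mmol (roughly
    < 0.5 g/day) labels responder; a creatinine rise beyond tolerance with no
    proteinuria measure labels non-responder.  With neither proteinuria nor
    creatinine at month 6 the patient is unclassifiable.
    """
    if month6_rec.timepoint != "month6":
        raise ValidationError("second record must be the month-6 timepoint")

    creatinine_stable: Optional[bool] = None
    if month6_rec.scr_umol_l is not None and biopsy_rec.scr_umol_l is not None:
        creatinine_stable = month6_rec.scr_umol_l <= (
            (1.0 + creatinine_stability_tol) * biopsy_rec.scr_umol_l
        )

    if _has_proteinuria(month6_rec):
        in_remission = proteinuria_g_per_day(month6_rec) < PROTEINURIA_REMISSION_G_DAY
        if in_remission and creatinine_stable is not False:
            return "responder"
        return "non_responder"

    if month6_rec.acr_mg_mmol is not None:
        return "responder" if month6_rec.acr_mg_mmol < ACR_REMISSION_MG_MMOL else "non_responder"

    if creatinine_stable is False:
        return "non_responder"
    raise UnclassifiableError(
        f"{month6_rec.patient_id}: no proteinuria measure and no creatinine rise"
        " at month 6; cannot classify"
    )


def _opt(cell: str) -> Optional[float]:
    cell = cell.strip()
    return None if cell == "" else float(cell)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the long-format clinical CSV (one row per patient and timepoint)."""
    records: list[ClinicalRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CLINICAL_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    ClinicalRecord(
                        patient_id=row["patient_id"],
                        timepoint=row["timepoint"],  # type: ignore[arg-type]
                        age_years=float(row["age_years"]),
                        sex=row["sex"],  # type: ignore[arg-type]
                        scr_umol_l=_opt(row["scr_umol_l"]),
                        proteinuria_g24h=_opt(row["proteinuria_g24h"]),
                        upcr_mg_mmol=_opt(row["upcr_mg_mmol"]),
                        acr_mg_mmol=_opt(row["acr_mg_mmol"]),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    def fmt(v: Optional[float]) -> str:
        return "" if v is None else repr(float(v))

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLINICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.timepoint,
                    repr(float(r.age_years)),
                    r.sex,
                    fmt(r.scr_umol_l),
                    fmt(r.proteinuria_g24h),
                    fmt(r.upcr_mg_mmol),
                    fmt(r.acr_mg_mmol),
                ]
            )


def classify_cohort(
    records: Iterable[ClinicalRecord], creatinine_stability_tol: float = 0.30
) -> dict[str, str]:
    """Map patient id -> response label for a long-format record list."""
    by_patient: dict[str, dict[str, ClinicalRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, {})[rec.timepoint] = rec
    labels: dict[str, str] = {}
    for pid, recs in by_patient.items():
        if "month6" not in recs or "biopsy" not in recs:
            raise UnclassifiableError(f"{pid}: need both biopsy and month-6 records")
        labels[pid] = classify_response(
            recs["biopsy"], recs["month6"], creatinine_stability_tol
        )
    return labels


__all__ = [
    "ACR_REMISSION_MG_MMOL",
    "CLINICAL_COLUMNS",
    "ClinicalRecord",
    "PROTEINURIA_REMISSION_G_DAY",
    "UPCR_REMISSION_MG_MMOL",
    "classify_cohort",
    "classify_response",
    "egfr_ckd_epi",
    "proteinuria_g_per_day",
    "read_clinical",
    "write_clinical",
]
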