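"""Sclerosis-grade aggregation: GSI, %global sclerosis, %FSGS, threshold flags.

Each glomerular profile carries a grade 0-4 (0 = no sclerosis, 4 = global
sclerosis).  The glomerulosclerotic index is the count-weighted mean grade

    GSI = (1*N1 + 2*N2 + 3*N3 + 4*N4) / (N0 + N1 + N2 + N3 + N4)

where ``Nk`` is the number of glomeruli with grade ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from podometry.errors import ValidationError
from podometry.measurements import BiopsyMeasurement


@dataclass(frozen=True)
class SclerosisCounts:
    """Number of glomeruli at each sclerosis grade."""

    n0: int
    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.as_tuple()):
            raise ValidationError("grade counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.n0, self.n1, self.n2, self.n3, self.n4)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    @classmethod
    def from_scores(cls, scores: Iterable[int]) -> "SclerosisCounts":
        counts = [0, 0, 0, 0, 0]
        for s in scores:
            if s not in (0, 1, 2, 3, 4):
                raise ValidationError(f"sclerosis score {s} outside 0-4")
            counts[s] += 1
        return cls(*counts)

    @classmethod
    def from_biopsy(cls, biopsy: BiopsyMeasurement) -> "SclerosisCounts":
        return cls.from_scores(g.sclerosis_score for g in biopsy.glomeruli)


@dataclass(frozen=True)
class ThresholdFlags:
    """Per-patient threshold classifier outcomes."""

    low_podocyte: bool
    gsi_gt_1: bool
    global_gt_20: bool
    fsgs_gt_50: bool


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs for the four classifiers (directions fixed, see below)."""

    podocytes_per_tuft: float = 216.0  # "<= threshold" flags low podocyte number
    gsi: float = 1.0  # strictly greater flags
    pct_global: float = 20.0  # strictly greater flags
    pct_fsgs: float = 50.0  # strictly greater flags

    def __post_init__(self) -> None:
        if any(
            t < 0 for t in (self.podocytes_per_tuft, self.gsi, self.pct_global, self.pct_fsgs)
        ):
            raise ValidationError("thresholds must be non-negative")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class SclerosisResult:
    patient_id: str
    gsi: float
    pct_global: float
    pct_fsgs: float
    flags: ThresholdFlags


def gsi(counts: SclerosisCounts) -> float:
    """Glomerulosclerotic index, the count-weighted mean grade in [0, 4]."""
    if counts.total < 1:
        raise ValidationError("GSI needs at least one scored glomerulus")
    weighted = 1 * counts.n1 + 2 * counts.n2 + 3 * counts.n3 + 4 * counts.n4
    return weighted / counts.total


def pct_global(counts: SclerosisCounts) -> float:
    """Percentage of glomeruli with global sclerosis (grade 4)."""
    if counts.total < 1:
        raise ValidationError("percentage needs at least one scored glomerulus")
    return 100.0 * counts.n4 / counts.total


def pct_fsgs(counts: SclerosisCounts, include_global: bool = False) -> float:
    """Percentage of glomeruli with FSGS lesions.

    By default only segmental lesions (grades 1-3) count; ``include_global``
    adds grade 4, in which case the result dominates :func:`pct_global`.
    """
    if counts.total < 1:
        raise ValidationError("percentage needs at least one scored glomerulus")
    lesions = counts.n1 + counts.n2 + counts.n3
    if include_global:
        lesions += counts.n4
    return 100.0 * lesions / counts.total


def classify_thresholds(
    podocytes_per_tuft: float,
    gsi_value: float,
    pct_global_value: float,
    pct_fsgs_value: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ThresholdFlags:
    """Apply the four cut-offs.

    The podocyte-number comparison is inclusive ("216 or less"); the other
    three are strict ("greater than").
    """
    return ThresholdFlags(
        low_podocyte=podocytes_per_tuft <= thresholds.podocytes_per_tuft,
        gsi_gt_1=gsi_value > thresholds.gsi,
        global_gt_20=pct_global_value > thresholds.pct_global,
        fsgs_gt_50=pct_fsgs_value > thresholds.pct_fsgs,
    )


def compute_sclerosis(
    biopsy: BiopsyMeasurement,
    podocytes_per_tuft: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    include_global_in_fsgs: bool = False,
) -> SclerosisResult:
    """Score one biopsy and evaluate its threshold flags."""
    counts = SclerosisCounts.from_biopsy(biopsy)
    g = gsi(counts)
    p_glob = pct_global(counts)
    p_fsgs = pct_fsgs(counts, include_global=include_global_in_fsgs)
    flags = classify_thresholds(podocytes_per_tuft, g, p_glob, p_fsgs, thresholds)
    return SclerosisResult(
        patient_id=biopsy.patient_id,
        gsi=g,
        pct_global=p_glob,
        pct_fsgs=p_fsgs,
        flags=flags,
    )


def results_to_frame(results: list[SclerosisResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "patient_id": r.patient_id,
                "gsi": r.gsi,
                "pct_global": r.pct_global,
                "pct_fsgs": r.pct_fsgs,
                "flag_low_podocyte": int(r.flags.low_podocyte),
                "flag_gsi_gt_1": int(r.flags.gsi_gt_1),
                "flag_global_gt_20": int(r.flags.global_gt_20),
                "flag_fsgs_gt_50": int(r.flags.fsgs_gt_50),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_THRESHOLDS",
    "SclerosisCounts",
    "SclerosisResult",
    "ThresholdFlags",
    "Thresholds",
    "classify_thresholds",
    "compute_sclerosis",
    "gsi",
    "pct_fsgs",
    "pct_global",
    "results_to_frame",
]
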