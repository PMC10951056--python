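"""Measurement data model, CSV round-trip and the glomerulus-count inclusion rule.

One CSV dialect is used throughout: comma separated, ``.`` decimal, UTF-8,
with the per-nucleus caliper diameters stored as a ``;``-joined list in a
single cell.  Each diameter is the mean of the X- and Y-axis caliper of one
nucleus profile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from podometry.errors import FormatError, ValidationError

MEASUREMENT_COLUMNS = [
    "patient_id",
    "glomerulus_id",
    "tuft_area_um2",
    "sclerosis_score",
    "nuclear_caliper_diameters_um",
    "snp_area_um2",
]

OPTICS_COLUMNS = ["excitation_wavelength_nm", "refractive_index", "numerical_aperture"]

#: Biopsies with this many glomerular profiles or fewer are excluded.
MIN_GLOMERULI_EXCLUSIVE = 6

_DIAMETER_SEP = ";"


@dataclass(frozen=True)
class OpticalConfig:
    """Confocal acquisition parameters needed for the axial-resolution formula."""

    excitation_wavelength_nm: float = 405.0
    refractive_index: float = 1.515
    numerical_aperture: float = 1.25

    def __post_init__(self) -> None:
        if self.excitation_wavelength_nm <= 0:
            raise ValidationError("excitation wavelength must be positive")
        if self.refractive_index <= 0 or self.numerical_aperture <= 0:
            raise ValidationError("refractive index and numerical aperture must be positive")
        if self.numerical_aperture >= self.refractive_index:
            raise ValidationError(
                "numerical aperture must be smaller than the immersion refractive index"
            )


#: DAPI excitation on the system the estimators are calibrated for.
DEFAULT_OPTICS = OpticalConfig()


@dataclass(frozen=True)
class GlomerulusMeasurement:
    """Raw measurements for one glomerular tuft profile.

    ``tuft_area`` includes sclerotic regions.  ``nuclear_caliper_diameters``
    holds one value per detected podocyte nucleus (mean of X and Y caliper),
    so the podocyte count of the profile is the length of that tuple.
    """

    glomerulus_id: str
    tuft_area: float
    sclerosis_score: int
    nuclear_caliper_diameters: tuple[float, ...] = ()
    snp_area: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "nuclear_caliper_diameters", tuple(self.nuclear_caliper_diameters)
        )
        if self.tuft_area <= 0:
            raise ValidationError(
                f"glomerulus {self.glomerulus_id!r}: tuft area must be > 0"
            )
        if not isinstance(self.sclerosis_score, int) or isinstance(self.sclerosis_score, bool):
            raise ValidationError(
                f"glomerulus {self.glomerulus_id!r}: sclerosis score must be an integer"
            )
        if self.sclerosis_score not in (0, 1, 2, 3, 4):
            raise ValidationError(
                f"glomerulus {self.glomerulus_id!r}: sclerosis score "
                f"{self.sclerosis_score} outside 0-4"
            )
        if any(d <= 0 for d in self.nuclear_caliper_diameters):
            raise ValidationError(
                f"glomerulus {self.glomerulus_id!r}: all caliper diameters must be > 0"
            )
        if self.snp_area < 0 or self.snp_area > self.tuft_area:
            raise ValidationError(
                f"glomerulus {self.glomerulus_id!r}: synaptopodin area must lie in "
                f"[0, tuft area]"
            )

    @property
    def podocyte_count(self) -> int:
        return len(self.nuclear_caliper_diameters)


@dataclass(frozen=True)
class BiopsyMeasurement:
    """All measured glomerular profiles of one patient plus the optics used."""

    patient_id: str
    glomeruli: tuple[GlomerulusMeasurement, ...]
    optics: OpticalConfig = field(default_factory=OpticalConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "glomeruli", tuple(self.glomeruli))

    @property
    def n_glomeruli(self) -> int:
        return len(self.glomeruli)

    @property
    def total_tuft_area(self) -> float:
        return sum(g.tuft_area for g in self.glomeruli)

    @property
    def total_podocyte_count(self) -> int:
        return sum(g.podocyte_count for g in self.glomeruli)

    @property
    def all_caliper_diameters(self) -> tuple[float, ...]:
        return tuple(d for g in self.glomeruli for d in g.nuclear_caliper_diameters)


def _parse_diameters(cell: str, row_index: int) -> tuple[float, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    try:
        return tuple(float(tok) for tok in cell.split(_DIAMETER_SEP))
    except ValueError as exc:
        raise ValidationError(
            f"row {row_index}: cannot parse caliper diameters {cell!r}"
        ) from exc


def _format_diameters(diameters: Sequence[float]) -> str:
    # repr() round-trips doubles exactly
    return _DIAMETER_SEP.join(repr(float(d)) for d in diameters)


def read_optics(path: str | Path) -> OpticalConfig:
    """Read a single-row optics CSV (see :data:`OPTICS_COLUMNS`)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in OPTICS_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"optics file {path}: missing column(s) {missing}")
        rows = list(reader)
    if len(rows) != 1:
        raise FormatError(f"optics file {path}: expected exactly one row, got {len(rows)}")
    row = rows[0]
    return OpticalConfig(
        excitation_wavelength_nm=float(row["excitation_wavelength_nm"]),
        refractive_index=float(row["refractive_index"]),
        numerical_aperture=float(row["numerical_aperture"]),
    )


def write_optics(optics: OpticalConfig, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OPTICS_COLUMNS)
        writer.writerow(
            [
                repr(optics.excitation_wavelength_nm),
                repr(optics.refractive_index),
                repr(optics.numerical_aperture),
            ]
        )


def read_measurements(
    path: str | Path, optics: OpticalConfig | str | Path | None = None
) -> list[BiopsyMeasurement]:
    """Read a per-(patient, glomerulus) measurement CSV.

    Parameters
    ----------
    path:
        CSV file with the columns in :data:`MEASUREMENT_COLUMNS`.
    optics:
        Either an :class:`OpticalConfig`, a path to a one-row optics CSV, or
        ``None`` for the default DAPI/oil configuration.  The same optics are
        attached to every biopsy (one acquisition setup per study).
    """
    if optics is None:
        optics_cfg = DEFAULT_OPTICS
    elif isinstance(optics, OpticalConfig):
        optics_cfg = optics
    else:
        optics_cfg = read_optics(optics)

    per_patient: dict[str, list[GlomerulusMeasurement]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header required")
        missing = [c for c in MEASUREMENT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=1):
            score_raw = row["sclerosis_score"].strip()
            try:
                score = int(score_raw)
            except ValueError as exc:
                raise ValidationError(
                    f"row {i}: sclerosis_score {score_raw!r} is not an integer"
                ) from exc
            try:
                glom = GlomerulusMeasurement(
                    glomerulus_id=row["glomerulus_id"],
                    tuft_area=float(row["tuft_area_um2"]),
                    sclerosis_score=score,
                    nuclear_caliper_diameters=_parse_diameters(
                        row["nuclear_caliper_diameters_um"], i
                    ),
                    snp_area=float(row["snp_area_um2"]),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            per_patient.setdefault(row["patient_id"], []).append(glom)

    return [
        BiopsyMeasurement(patient_id=pid, glomeruli=tuple(gloms), optics=optics_cfg)
        for pid, gloms in per_patient.items()
    ]


def write_measurements(biopsies: Iterable[BiopsyMeasurement], path: str | Path) -> None:
    """Write biopsies to CSV in the schema read back by :func:`read_measurements`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for biopsy in biopsies:
            for glom in biopsy.glomeruli:
                writer.writerow(
                    [
                        biopsy.patient_id,
                        glom.glomerulus_id,
                        repr(float(glom.tuft_area)),
                        glom.sclerosis_score,
                        _format_diameters(glom.nuclear_caliper_diameters),
                        repr(float(glom.snp_area)),
                    ]
                )


def apply_inclusion_filter(
    biopsies: Iterable[BiopsyMeasurement],
) -> tuple[list[BiopsyMeasurement], list[str]]:
    """Partition biopsies by the glomerulus-count rule.

    Biopsies whose section contains ``MIN_GLOMERULI_EXCLUSIVE`` (= 6) glomeruli
    or fewer are excluded; the boundary is inclusive, so exactly 6 profiles is
    excluded and 7 is included.

    Returns ``(included biopsies, excluded patient ids)``.
    """
    included: list[BiopsyMeasurement] = []
    excluded: list[str] = []
    for biopsy in biopsies:
        if biopsy.n_glomeruli <= MIN_GLOMERULI_EXCLUSIVE:
            excluded.append(biopsy.patient_id)
        else:
            included.append(biopsy)
    return included, excluded


__all__ = [
    "BiopsyMeasurement",
    "GlomerulusMeasurement",
    "OpticalConfig",
    "DEFAULT_OPTICS",
    "MEASUREMENT_COLUMNS",
    "OPTICS_COLUMNS",
    "MIN_GLOMERULI_EXCLUSIVE",
    "apply_inclusion_filter",
    "read_measurements",
    "read_optics",
    "write_measurements",
    "write_optics",
]
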