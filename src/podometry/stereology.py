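"""Design-based stereological estimators for podocyte number, density and size.

The pipeline per biopsy is:

1. mean tuft profile area -> glomerular volume (shape-coefficient method,
   ``V = (beta / d) * A ** 1.5`` with ``beta = 1.382`` for spheres and
   ``d = 1.01``);
2. optical slab thickness from the confocal axial-resolution formula
   ``T = 0.88 * lambda / (n - sqrt(n**2 - NA**2))``;
3. numerical density ``N_V = (sum Q / sum A) / (D + T)`` of podocyte nuclei,
   with ``D`` the mean nuclear caliper diameter (apparent by default, or
   corrected, see :class:`StereologyConfig`);
4. podocytes per tuft = ``N_V * V``;
5. volume indices from the synaptopodin area fraction and the corrected
   nuclear diameter.

All lengths are in micrometres, areas in square and volumes in cubic
micrometres.  Display scaling (e.g. volumes per 10^6 um^3) is left to
reporting code.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from podometry.errors import ValidationError
from podometry.measurements import BiopsyMeasurement, OpticalConfig

FOUR_OVER_PI = 4.0 / math.pi

_CORRECTION_MODES = ("four_over_pi", "identity", "custom")


@dataclass(frozen=True)
class StereologyConfig:
    """Coefficients and conventions of the stereological estimators.

    ``diameter_correction_mode`` governs how an apparent (sectioned) nuclear
    caliper diameter is converted to an estimate of the true diameter:

    - ``four_over_pi``: multiply by 4/pi, the classical correction for the
      mean chord of a sectioned sphere (default);
    - ``identity``: no correction;
    - ``custom``: multiply by ``custom_correction_factor``.

    ``density_uses_corrected_diameter`` selects which diameter enters the
    density denominator ``D + T``.  The default (``False``) uses the apparent
    diameter, matching the original method description; setting it to ``True``
    uses the corrected diameter, which removes the over-counting bias of thin
    slabs (see the recovery tests).
    """

    shape_coefficient_beta: float = 1.382
    size_distribution_d: float = 1.01
    diameter_correction_mode: str = "four_over_pi"
    custom_correction_factor: float = FOUR_OVER_PI
    density_uses_corrected_diameter: bool = False

    def __post_init__(self) -> None:
        if self.shape_coefficient_beta <= 0:
            raise ValidationError("shape coefficient beta must be > 0")
        if self.size_distribution_d < 1:
            raise ValidationError("size distribution coefficient d must be >= 1")
        if self.diameter_correction_mode not in _CORRECTION_MODES:
            raise ValidationError(
                f"unknown diameter correction mode {self.diameter_correction_mode!r};"
                f" expected one of {_CORRECTION_MODES}"
            )
        if self.custom_correction_factor <= 0:
            raise ValidationError("custom correction factor must be > 0")

    @property
    def correction_factor(self) -> float:
        if self.diameter_correction_mode == "four_over_pi":
            return FOUR_OVER_PI
        if self.diameter_correction_mode == "identity":
            return 1.0
        return self.custom_correction_factor


DEFAULT_CONFIG = StereologyConfig()


@dataclass(frozen=True)
class PodometricResult:
    """Per-patient derived podometric indices."""

    patient_id: str
    mean_glomerular_area: float
    glomerular_volume: float
    optical_thickness: float
    mean_apparent_caliper: float
    estimated_true_caliper: float
    podocyte_density: float
    podocytes_per_tuft: float
    snp_fraction: float
    nuclear_volume: float
    cytoplasmic_volume: float
    total_podocyte_volume: float
    nc_ratio: float
    vv_pod_glom: float


def optical_section_thickness(optics: OpticalConfig) -> float:
    """Optical slab thickness (axial resolution) in micrometres.

    ``T = 0.88 * lambda / (n - sqrt(n^2 - NA^2))`` with the excitation
    wavelength in nm; the result is converted to um.
    """
    n = optics.refractive_index
    na = optics.numerical_aperture
    if na >= n:
        raise ValidationError("numerical aperture must be < refractive index")
    t_nm = 0.88 * optics.excitation_wavelength_nm / (n - math.sqrt(n * n - na * na))
    return t_nm / 1000.0


def mean_glomerular_area(biopsy: BiopsyMeasurement) -> float:
    """Arithmetic mean tuft profile area over all profiles (sclerotic included)."""
    if biopsy.n_glomeruli == 0:
        raise ValidationError(f"biopsy {biopsy.patient_id!r} has no glomeruli")
    return biopsy.total_tuft_area / biopsy.n_glomeruli


def glomerular_volume(mean_area: float, cfg: StereologyConfig = DEFAULT_CONFIG) -> float:
    """Glomerular volume from mean profile area, ``(beta / d) * A ** 1.5``."""
    if mean_area < 0:
        raise ValidationError("mean glomerular area must be >= 0")
    return cfg.shape_coefficient_beta / cfg.size_distribution_d * mean_area**1.5


def mean_apparent_caliper(biopsy: BiopsyMeasurement) -> float:
    """Mean apparent nuclear caliper diameter pooled over all nuclei of the biopsy."""
    diameters = biopsy.all_caliper_diameters
    if not diameters:
        raise ValidationError(f"biopsy {biopsy.patient_id!r} has no podocyte nuclei")
    return sum(diameters) / len(diameters)


def true_nuclear_diameter(mean_apparent: float, cfg: StereologyConfig = DEFAULT_CONFIG) -> float:
    """Estimated true nuclear diameter from the mean apparent caliper diameter."""
    if mean_apparent <= 0:
        raise ValidationError("apparent caliper diameter must be > 0")
    return cfg.correction_factor * mean_apparent


def podocyte_density(biopsy: BiopsyMeasurement, cfg: StereologyConfig = DEFAULT_CONFIG) -> float:
    """Podocyte numerical density in nuclei per cubic micrometre.

    ``N_V = (sum Q / sum A) / (D + T)`` where ``sum Q`` is the total nucleus
    count over all profiles, ``sum A`` the total tuft area, ``T`` the optical
    slab thickness and ``D`` the mean caliper diameter (apparent unless
    ``cfg.density_uses_corrected_diameter``).
    """
    total_area = biopsy.total_tuft_area
    if total_area <= 0:
        raise ValidationError("total tuft area must be > 0")
    d_mean = mean_apparent_caliper(biopsy)
    if cfg.density_uses_corrected_diameter:
        d_mean = true_nuclear_diameter(d_mean, cfg)
    thickness = optical_section_thickness(biopsy.optics)
    return (biopsy.total_podocyte_count / total_area) / (d_mean + thickness)


def podocytes_per_tuft(density: float, volume: float) -> float:
    """Podocyte number per tuft = density times glomerular volume (not rounded)."""
    if density < 0 or volume < 0:
        raise ValidationError("density and volume must be >= 0")
    return density * volume


def snp_fraction(biopsy: BiopsyMeasurement) -> float:
    """Synaptopodin-positive area fraction of the biopsy's pooled tuft area."""
    total_area = biopsy.total_tuft_area
    if total_area <= 0:
        raise ValidationError("total tuft area must be > 0")
    return sum(g.snp_area for g in biopsy.glomeruli) / total_area


def podocyte_nuclear_volume(mean_apparent: float, cfg: StereologyConfig = DEFAULT_CONFIG) -> float:
    """Mean podocyte nuclear volume as the sphere volume of the corrected diameter.

    In ``four_over_pi`` mode this is ``(4 pi / 3) * ((2 / pi) * d_apparent)**3``
    (radius = half the corrected diameter).
    """
    diameter = true_nuclear_diameter(mean_apparent, cfg)
    return 4.0 * math.pi / 3.0 * (diameter / 2.0) ** 3


def podocyte_cytoplasmic_volume(
    glom_volume: float, snp_frac: float, n_per_tuft: float
) -> float:
    """Mean cytoplasmic volume per podocyte: ``V_glom * fraction / N``."""
    if n_per_tuft <= 0:
        raise ValidationError("podocytes per tuft must be > 0")
    return glom_volume * snp_frac / n_per_tuft


def total_podocyte_volume(nuclear: float, cytoplasmic: float) -> float:
    """Total podocyte volume = nuclear + cytoplasmic."""
    return nuclear + cytoplasmic


def vv_pod_glom(total_volume: float, n_per_tuft: float, glom_volume: float) -> float:
    """Fraction of glomerular volume occupied by podocytes.

    ``V_V = total podocyte volume * N / V_glom``.  Physically consistent
    inputs give a value in [0, 1]; larger values are returned but flagged
    with a warning.
    """
    if glom_volume <= 0:
        raise ValidationError("glomerular volume must be > 0")
    vv = total_volume * n_per_tuft / glom_volume
    if vv > 1:
        warnings.warn(
            f"podocyte volume fraction {vv:.3f} exceeds 1; inputs are physically"
            " inconsistent",
            stacklevel=2,
        )
    return vv


def compute_podometrics(
    biopsy: BiopsyMeasurement, cfg: StereologyConfig = DEFAULT_CONFIG
) -> PodometricResult:
    """Run the full estimator chain on one biopsy."""
    area = mean_glomerular_area(biopsy)
    volume = glomerular_volume(area, cfg)
    thickness = optical_section_thickness(biopsy.optics)
    d_apparent = mean_apparent_caliper(biopsy)
    d_true = true_nuclear_diameter(d_apparent, cfg)
    density = podocyte_density(biopsy, cfg)
    n_per_tuft = podocytes_per_tuft(density, volume)
    frac = snp_fraction(biopsy)
    v_nuc = podocyte_nuclear_volume(d_apparent, cfg)
    v_cyt = podocyte_cytoplasmic_volume(volume, frac, n_per_tuft)
    v_tot = total_podocyte_volume(v_nuc, v_cyt)
    return PodometricResult(
        patient_id=biopsy.patient_id,
        mean_glomerular_area=area,
        glomerular_volume=volume,
        optical_thickness=thickness,
        mean_apparent_caliper=d_apparent,
        estimated_true_caliper=d_true,
        podocyte_density=density,
        podocytes_per_tuft=n_per_tuft,
        snp_fraction=frac,
        nuclear_volume=v_nuc,
        cytoplasmic_volume=v_cyt,
        total_podocyte_volume=v_tot,
        nc_ratio=v_nuc / v_cyt if v_cyt > 0 else math.inf,
        vv_pod_glom=vv_pod_glom(v_tot, n_per_tuft, volume),
    )


def results_to_frame(
    results: list[PodometricResult], cfg: StereologyConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One row per patient with all derived indices plus config echo columns."""
    frame = pd.DataFrame([vars(r) for r in results])
    frame["cfg_beta"] = cfg.shape_coefficient_beta
    frame["cfg_d"] = cfg.size_distribution_d
    frame["cfg_correction_mode"] = cfg.diameter_correction_mode
    frame["cfg_correction_factor"] = cfg.correction_factor
    frame["cfg_density_corrected"] = cfg.density_uses_corrected_diameter
    return frame


__all__ = [
    "DEFAULT_CONFIG",
    "FOUR_OVER_PI",
    "PodometricResult",
    "StereologyConfig",
    "compute_podometrics",
    "glomerular_volume",
    "mean_apparent_caliper",
    "mean_glomerular_area",
    "optical_section_thickness",
    "podocyte_cytoplasmic_volume",
    "podocyte_density",
    "podocyte_nuclear_volume",
    "podocytes_per_tuft",
    "results_to_frame",
    "snp_fraction",
    "total_podocyte_volume",
    "true_nuclear_diameter",
    "vv_pod_glom",
]
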