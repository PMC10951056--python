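"""Ground-truth synthetic glomeruli, optical sections, rasters and cohorts.

The sampling model matches the assumptions of the stereological estimators:
a spherical tuft of radius ``R`` containing ``N`` non-overlapping spherical
nuclei with centers uniform in the tuft, sectioned by a slab of thickness
``T``.  A nucleus contributes a profile when its center lies within
``r + T/2`` of the slab mid-plane; its apparent caliper diameter is
``2 * sqrt(r^2 - max(0, |z| - T/2)^2)`` for center-to-mid-plane distance
``z``.

Group-level truth distributions are lognormal, parameterised by median and
inter-quartile range (``median = exp(mu)``, quartiles at
``exp(mu +- 0.6745 sigma)``), and calibrated so the default cohort has 13
responders and 6 non-responders with realistic podometric and clinical
medians.  All randomness flows from one seeded generator, so a fixed seed
yields byte-identical CSV output.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from podometry.clinical import ClinicalRecord, write_clinical
from podometry.errors import ValidationError
from podometry.image_measure import GlomerulusImage
from podometry.measurements import (
    BiopsyMeasurement,
    GlomerulusMeasurement,
    OpticalConfig,
    write_measurements,
)
from podometry.stereology import optical_section_thickness

_Q3_Z = 0.6745  # upper-quartile z-score of the standard normal


# --------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class GlomerulusGeometry:
    """A tuft sphere with planted nuclei (centers in um, tuft-centered frame)."""

    tuft_radius: float
    nucleus_centers: np.ndarray  # (N, 3)
    nucleus_radii: np.ndarray  # (N,)


@dataclass(frozen=True)
class SectionPlane:
    """Optical slab: mid-plane offset from the tuft center and thickness."""

    offset: float
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValidationError("slab thickness must be > 0")


def generate_glomerulus(
    n_podocytes: int,
    nuclear_diameter: float,
    tuft_radius: float,
    rng: np.random.Generator,
    diameter_cv: float = 0.05,
    min_spacing: Optional[float] = None,
    max_attempts: int = 2000,
) -> GlomerulusGeometry:
    """Plant ``n_podocytes`` non-overlapping nuclei uniformly in the tuft sphere.

    ``min_spacing`` is the minimum center-to-center distance (default: the
    nuclear diameter, i.e. hard spheres).  Raises when the packing is
    infeasible.
    """
    if nuclear_diameter <= 0 or tuft_radius <= 0:
        raise ValidationError("diameter and radius must be > 0")
    if n_podocytes < 0:
        raise ValidationError("podocyte count must be >= 0")
    spacing = nuclear_diameter if min_spacing is None else min_spacing
    if n_podocytes == 0:
        return GlomerulusGeometry(
            tuft_radius=tuft_radius,
            nucleus_centers=np.empty((0, 3)),
            nucleus_radii=np.empty(0),
        )
    # hard-sphere packing fraction at the requested spacing
    fraction = n_podocytes * (spacing / 2.0) ** 3 / tuft_radius**3
    if fraction > 0.35:
        raise ValidationError(
            f"cannot pack {n_podocytes} nuclei with spacing {spacing:.2f} um into a"
            f" tuft of radius {tuft_radius:.1f} um (fraction {fraction:.2f})"
        )
    radii = nuclear_diameter / 2.0 * np.ones(n_podocytes)
    if diameter_cv > 0:
        radii = radii * np.clip(rng.normal(1.0, diameter_cv, n_podocytes), 0.5, 1.5)
    centers = np.empty((n_podocytes, 3))
    placed = 0
    spacing_sq = spacing * spacing
    while placed < n_podocytes:
        for attempt in range(max_attempts):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = direction * tuft_radius * rng.uniform() ** (1.0 / 3.0)
            if placed == 0:
                break
            d2 = np.sum((centers[:placed] - candidate) ** 2, axis=1)
            if d2.min() >= spacing_sq:
                break
        else:
            raise ValidationError(
                f"packing failed after {max_attempts} attempts at nucleus {placed}"
            )
        centers[placed] = candidate
        placed += 1
    return GlomerulusGeometry(
        tuft_radius=tuft_radius, nucleus_centers=centers, nucleus_radii=radii
    )


def sectioned_nuclei(
    geometry: GlomerulusGeometry, plane: SectionPlane
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and apparent caliper diameters of nuclei captured by the slab."""
    if geometry.nucleus_centers.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0)
    z = np.abs(geometry.nucleus_centers[:, 2] - plane.offset)
    r = geometry.nucleus_radii
    captured = z < r + plane.thickness / 2.0
    depth = np.maximum(0.0, z[captured] - plane.thickness / 2.0)
    apparent = 2.0 * np.sqrt(np.maximum(0.0, r[captured] ** 2 - depth**2))
    positive = apparent > 0
    return np.nonzero(captured)[0][positive], apparent[positive]


def section_glomerulus(
    geometry: GlomerulusGeometry,
    plane: SectionPlane,
    snp_fraction: float,
    sclerosis_score: int = 0,
    rng: Optional[np.random.Generator] = None,
    snp_noise_sigma: float = 0.1,
    glomerulus_id: str = "g",
) -> GlomerulusMeasurement:
    """Measure one optical section analytically (no rasterisation).

    The tuft profile area is ``pi * (R^2 - h^2)`` for mid-plane offset ``h``;
    the synaptopodin area is the target fraction of the profile area with
    multiplicative lognormal noise, clipped into [0, area].
    """
    h = plane.offset
    big_r = geometry.tuft_radius
    if abs(h) >= big_r:
        raise ValidationError("section plane does not intersect the tuft")
    area = math.pi * (big_r**2 - h**2)
    _, apparent = sectioned_nuclei(geometry, plane)
    noise = 1.0
    if rng is not None and snp_noise_sigma > 0:
        noise = float(rng.lognormal(0.0, snp_noise_sigma))
    snp_area = min(max(snp_fraction * area * noise, 0.0), area)
    return GlomerulusMeasurement(
        glomerulus_id=glomerulus_id,
        tuft_area=area,
        sclerosis_score=sclerosis_score,
        nuclear_caliper_diameters=tuple(float(d) for d in apparent),
        snp_area=snp_area,
    )


def expected_apparent_caliper(nucleus_radius: float, thickness: float) -> float:
    """Analytic mean apparent caliper over uniformly sampled capture offsets.

    For center offsets uniform in ``[0, r + T/2]`` the mean apparent diameter
    is ``(r T + pi r^2 / 2) / (r + T/2)``.
    """
    r, t = nucleus_radius, thickness
    return (r * t + math.pi * r * r / 2.0) / (r + t / 2.0)


def nuclear_diameter_for_apparent(target_apparent: float, thickness: float) -> float:
    """Invert :func:`expected_apparent_caliper`: true diameter whose slab-mean
    apparent caliper equals ``target_apparent``."""
    a, t = target_apparent, thickness
    if a <= 0:
        raise ValidationError("target apparent caliper must be > 0")
    r = ((a - t) + math.sqrt((t - a) ** 2 + math.pi * a * t)) / math.pi
    return 2.0 * r


# --------------------------------------------------------------------------
# cohort truth distributions


@dataclass(frozen=True)
class LogNormalSpec:
    """A positive, right-skewed variable given as median (q1-q3)."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (0 < self.q1 <= self.median <= self.q3) or self.q1 >= self.q3:
            raise ValidationError(
                f"invalid median/IQR spec ({self.median}, {self.q1}-{self.q3})"
            )

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return (math.log(self.q3) - math.log(self.q1)) / (2.0 * _Q3_Z)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.lognormal(self.mu, self.sigma, size)


@dataclass(frozen=True)
class GroupParams:
    """Truth distributions for one response group."""

    name: str
    n_patients: int
    podocyte_number: LogNormalSpec
    glomerular_volume: LogNormalSpec  # um^3
    apparent_diameter: LogNormalSpec  # um, target slab-mean apparent caliper
    snp_pct: LogNormalSpec  # percent of tuft area
    score_probs: tuple[float, float, float, float, float]
    age_years: LogNormalSpec
    male_fraction: float
    proteinuria_biopsy: LogNormalSpec  # g/24 h
    creatinine_biopsy: LogNormalSpec  # umol/L
    proteinuria_month6: LogNormalSpec
    creatinine_ratio_month6: LogNormalSpec  # month-6 / baseline creatinine

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("group size must be >= 0")
        if abs(sum(self.score_probs) - 1.0) > 1e-9:
            raise ValidationError("score probabilities must sum to 1")


@dataclass(frozen=True)
class CohortParams:
    responders: GroupParams
    non_responders: GroupParams
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    profiles_mean: float = 14.0
    profiles_sd: float = 7.0
    profiles_min: int = 7
    profiles_max: int = 30
    snp_noise_sigma: float = 0.1
    diameter_cv: float = 0.05
    #: Dirichlet concentration for per-patient sclerosis-score heterogeneity
    #: (larger = patients closer to the group-level distribution).
    score_concentration: float = 10.0


def default_cohort_params(
    n_responders: int = 13, n_non_responders: int = 6
) -> CohortParams:
    """Default truth calibration: 13 responders vs 6 non-responders."""
    responders = GroupParams(
        name="responder",
        n_patients=n_responders,
        podocyte_number=LogNormalSpec(279, 203, 507),
        glomerular_volume=LogNormalSpec(3.88e6, 2.76e6, 4.56e6),
        apparent_diameter=LogNormalSpec(7.31, 7.11, 7.70),
        snp_pct=LogNormalSpec(13, 11, 19),
        score_probs=(0.55, 0.25, 0.09, 0.04, 0.07),
        age_years=LogNormalSpec(35, 23, 53),
        male_fraction=7 / 13,
        proteinuria_biopsy=LogNormalSpec(3.87, 2.14, 6.75),
        creatinine_biopsy=LogNormalSpec(88, 65, 114),
        proteinuria_month6=LogNormalSpec(1.00, 0.20, 1.90),
        creatinine_ratio_month6=LogNormalSpec(1.03, 0.95, 1.12),
    )
    non_responders = GroupParams(
        name="non_responder",
        n_patients=n_non_responders,
        podocyte_number=LogNormalSpec(186, 118, 310),
        glomerular_volume=LogNormalSpec(2.95e6, 2.35e6, 4.85e6),
        apparent_diameter=LogNormalSpec(7.64, 6.90, 8.02),
        snp_pct=LogNormalSpec(12, 9, 18),
        score_probs=(0.17, 0.32, 0.15, 0.08, 0.28),
        age_years=LogNormalSpec(45, 41, 58),
        male_fraction=1.0,
        proteinuria_biopsy=LogNormalSpec(5.83, 5.18, 6.77),
        creatinine_biopsy=LogNormalSpec(116, 84, 161),
        proteinuria_month6=LogNormalSpec(6.11, 3.92, 9.14),
        creatinine_ratio_month6=LogNormalSpec(1.10, 0.95, 1.60),
    )
    return CohortParams(responders=responders, non_responders=non_responders)


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    group: str
    n_podocytes: int
    nuclear_diameter: float
    apparent_target: float
    tuft_radius: float
    glomerular_volume: float
    snp_fraction: float
    n_profiles: int
    score_probs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class CohortData:
    biopsies: list[BiopsyMeasurement]
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_measurements(self.biopsies, out / "measurements.csv")
        write_clinical(self.clinical, out / "clinical.csv")
        self.truth.to_csv(out / "truth.csv", index=False)


def _resample_until(spec: LogNormalSpec, rng, predicate, fallback: float, tries=200):
    for _ in range(tries):
        value = float(spec.sample(rng))
        if predicate(value):
            return value
    return fallback


def sample_biopsy(
    truth: PatientTruth,
    params: CohortParams,
    rng: np.random.Generator,
    n_profiles: Optional[int] = None,
) -> BiopsyMeasurement:
    """Simulate one biopsy: a fresh glomerulus per profile, random mid-plane."""
    thickness = optical_section_thickness(params.optics)
    n = truth.n_profiles if n_profiles is None else n_profiles
    glomeruli = []
    for i in range(n):
        geometry = generate_glomerulus(
            truth.n_podocytes,
            truth.nuclear_diameter,
            truth.tuft_radius,
            rng,
            diameter_cv=params.diameter_cv,
        )
        offset = rng.uniform(-truth.tuft_radius, truth.tuft_radius)
        plane = SectionPlane(offset=offset, thickness=thickness)
        score = int(rng.choice(5, p=truth.score_probs))
        glomeruli.append(
            section_glomerulus(
                geometry,
                plane,
                truth.snp_fraction,
                sclerosis_score=score,
                rng=rng,
                snp_noise_sigma=params.snp_noise_sigma,
                glomerulus_id=f"{truth.patient_id}-g{i + 1:02d}",
            )
        )
    return BiopsyMeasurement(
        patient_id=truth.patient_id, glomeruli=tuple(glomeruli), optics=params.optics
    )


def _draw_patient_truth(
    pid: str, group: GroupParams, params: CohortParams, rng: np.random.Generator
) -> PatientTruth:
    thickness = optical_section_thickness(params.optics)
    volume = float(np.clip(group.glomerular_volume.sample(rng), 8e5, 1.2e7))
    radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    apparent = float(np.clip(group.apparent_diameter.sample(rng), 5.0, 10.0))
    diameter = nuclear_diameter_for_apparent(apparent, thickness)
    n_max = int(0.3 * radius**3 / (diameter / 2.0) ** 3)
    n_podocytes = int(np.clip(round(group.podocyte_number.sample(rng)), 30, n_max))
    snp = float(np.clip(group.snp_pct.sample(rng) / 100.0, 0.02, 0.5))
    n_profiles = int(
        np.clip(
            round(rng.normal(params.profiles_mean, params.profiles_sd)),
            params.profiles_min,
            params.profiles_max,
        )
    )
    alpha = params.score_concentration * np.asarray(group.score_probs)
    probs = rng.dirichlet(np.maximum(alpha, 1e-3))
    probs = probs / probs.sum()
    return PatientTruth(
        patient_id=pid,
        group=group.name,
        n_podocytes=n_podocytes,
        nuclear_diameter=diameter,
        apparent_target=apparent,
        tuft_radius=radius,
        glomerular_volume=volume,
        snp_fraction=snp,
        n_profiles=n_profiles,
        score_probs=tuple(float(p) for p in probs),
    )


def _draw_clinical(
    truth: PatientTruth, group: GroupParams, rng: np.random.Generator
) -> tuple[ClinicalRecord, ClinicalRecord]:
    age = float(np.clip(group.age_years.sample(rng), 18.0, 85.0))
    sex = "male" if rng.uniform() < group.male_fraction else "female"
    scr_b = float(group.creatinine_biopsy.sample(rng))
    prot_b = float(group.proteinuria_biopsy.sample(rng))
    if group.name == "responder":
        prot_6 = _resample_until(
            group.proteinuria_month6, rng, lambda v: v < 3.4, fallback=3.0
        )
        ratio = float(np.clip(group.creatinine_ratio_month6.sample(rng), 0.7, 1.25))
    else:
        prot_6 = _resample_until(
            group.proteinuria_month6, rng, lambda v: v >= 3.6, fallback=3.6
        )
        ratio = float(np.clip(group.creatinine_ratio_month6.sample(rng), 0.8, 3.0))
    biopsy_rec = ClinicalRecord(
        patient_id=truth.patient_id,
        timepoint="biopsy",
        age_years=age,
        sex=sex,
        scr_umol_l=scr_b,
        proteinuria_g24h=prot_b,
    )
    month6_rec = ClinicalRecord(
        patient_id=truth.patient_id,
        timepoint="month6",
        age_years=age + 0.5,
        sex=sex,
        scr_umol_l=scr_b * ratio,
        proteinuria_g24h=prot_6,
    )
    return biopsy_rec, month6_rec


def generate_cohort(
    params: Optional[CohortParams] = None, seed: int = 0
) -> CohortData:
    """Generate the full synthetic cohort (measurements + clinical + truth)."""
    if params is None:
        params = default_cohort_params()
    rng = np.random.default_rng(seed)
    biopsies: list[BiopsyMeasurement] = []
    clinical: list[ClinicalRecord] = []
    truth_rows = []
    counter = 0
    for group in (params.responders, params.non_responders):
        for _ in range(group.n_patients):
            counter += 1
            pid = f"P{counter:03d}"
            truth = _draw_patient_truth(pid, group, params, rng)
            biopsies.append(sample_biopsy(truth, params, rng))
            rec_b, rec_6 = _draw_clinical(truth, group, rng)
            clinical.extend([rec_b, rec_6])
            truth_rows.append(
                {
                    "patient_id": pid,
                    "group": group.name,
                    "n_podocytes_true": truth.n_podocytes,
                    "nuclear_diameter_true_um": truth.nuclear_diameter,
                    "apparent_target_um": truth.apparent_target,
                    "tuft_radius_um": truth.tuft_radius,
                    "glomerular_volume_true_um3": truth.glomerular_volume,
                    "snp_fraction_true": truth.snp_fraction,
                    "n_profiles": truth.n_profiles,
                    "seed": seed,
                }
            )
    return CohortData(
        biopsies=biopsies,
        clinical=clinical,
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )


# --------------------------------------------------------------------------
# raster rendering


@dataclass(frozen=True)
class RenderNoise:
    blur_sigma_px: float = 1.0
    poisson: bool = True


@dataclass(frozen=True)
class RenderTruth:
    """Ground truth of one rendered frame (only nuclei actually drawn)."""

    n_nuclei: int
    apparent_diameters: tuple[float, ...]
    profile_radius: float
    snp_fraction: float


ZERO_NOISE = RenderNoise(blur_sigma_px=0.0, poisson=False)

_BACKGROUND = 20.0
_FOREGROUND = 200.0
_CAPSULE_GAP_UM = 2.0
_CAPSULE_WIDTH_UM = 3.0
_MIN_RENDER_RADIUS_UM = 1.5


def render_images(
    geometry: GlomerulusGeometry,
    plane: SectionPlane,
    pixel_size: float,
    rng: np.random.Generator,
    snp_fraction: float = 0.13,
    noise: RenderNoise = RenderNoise(),
    n_parietal: int = 5,
) -> tuple[GlomerulusImage, RenderTruth]:
    """Rasterise one optical section into a 3-channel frame with masks.

    Only nucleus profiles that fit wholly inside the tuft circle and exceed
    the minimum renderable radius are drawn; the returned truth counts exactly
    those.  Parietal cells are drawn on the capsule ring (all pan-nuclear
    positive, some also positive in the podocyte nuclear channel) to exercise
    the capsule-exclusion rule downstream.
    """
    from scipy import ndimage

    big_r = geometry.tuft_radius
    if abs(plane.offset) >= big_r:
        raise ValidationError("section plane does not intersect the tuft")
    if geometry.nucleus_radii.size and pixel_size > 0:
        min_diam = 2.0 * float(geometry.nucleus_radii.min())
        if min_diam / pixel_size < 4:
            warnings.warn(
                f"pixel size {pixel_size} um gives fewer than 4 px per nucleus",
                stacklevel=2,
            )
    rho = math.sqrt(big_r**2 - plane.offset**2)
    half = rho + _CAPSULE_GAP_UM + _CAPSULE_WIDTH_UM + 4.0
    n_px = 2 * int(math.ceil(half / pixel_size)) + 1
    center = n_px // 2
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    dist = np.hypot(yy - center, xx - center) * pixel_size
    tuft_mask = dist <= rho
    capsule_mask = (dist >= rho + _CAPSULE_GAP_UM) & (
        dist <= rho + _CAPSULE_GAP_UM + _CAPSULE_WIDTH_UM
    )

    dach1 = np.full((n_px, n_px), _BACKGROUND)
    dapi = np.full((n_px, n_px), _BACKGROUND)
    snp = np.full((n_px, n_px), _BACKGROUND)

    idx, apparent = sectioned_nuclei(geometry, plane)
    drawn: list[float] = []
    margin = 2.0 * pixel_size
    for i, diam in zip(idx, apparent):
        a = diam / 2.0
        cx, cy = geometry.nucleus_centers[i, 0], geometry.nucleus_centers[i, 1]
        if a < _MIN_RENDER_RADIUS_UM:
            continue
        if math.hypot(cx, cy) + a > rho - margin:
            continue
        disk = dist_to(yy, xx, center, cx, cy, pixel_size) <= a
        dach1[disk] = _FOREGROUND
        dapi[disk] = _FOREGROUND
        drawn.append(float(diam))

    ring_radius = rho + _CAPSULE_GAP_UM + _CAPSULE_WIDTH_UM / 2.0
    for j in range(n_parietal):
        theta = rng.uniform(0, 2 * math.pi)
        px = ring_radius * math.cos(theta)
        py = ring_radius * math.sin(theta)
        disk = dist_to(yy, xx, center, px, py, pixel_size) <= 2.5
        dapi[disk] = _FOREGROUND
        if j % 2 == 0:  # some parietal cells express the podocyte nuclear marker
            dach1[disk] = _FOREGROUND

    # synaptopodin texture: smooth noise thresholded to the target fraction
    field_img = ndimage.gaussian_filter(rng.normal(size=(n_px, n_px)), 3.0)
    in_tuft = field_img[tuft_mask]
    if snp_fraction > 0 and in_tuft.size:
        cut = np.quantile(in_tuft, 1.0 - snp_fraction)
        snp[tuft_mask & (field_img > cut)] = _FOREGROUND

    channels = []
    for img in (dach1, snp, dapi):
        out = img
        if noise.blur_sigma_px > 0:
            out = ndimage.gaussian_filter(out, noise.blur_sigma_px)
        if noise.poisson:
            out = rng.poisson(out).astype(float)
        channels.append(out)

    image = GlomerulusImage(
        dach1=channels[0],
        snp=channels[1],
        dapi=channels[2],
        pixel_size=pixel_size,
        tuft_mask=tuft_mask,
        capsule_mask=capsule_mask,
    )
    truth = RenderTruth(
        n_nuclei=len(drawn),
        apparent_diameters=tuple(drawn),
        profile_radius=rho,
        snp_fraction=snp_fraction,
    )
    return image, truth


def dist_to(yy, xx, center: int, x_um: float, y_um: float, pixel_size: float):
    """Pixel-grid distance (um) to a point given in tuft-centered um coords."""
    px = center + x_um / pixel_size
    py = center + y_um / pixel_size
    return np.hypot(yy - py, xx - px) * pixel_size


def write_manifest(path: str | Path, seed: int, extra: Optional[dict] = None) -> None:
    payload = {"seed": seed}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


__all__ = [
    "CohortData",
    "CohortParams",
    "GlomerulusGeometry",
    "GroupParams",
    "LogNormalSpec",
    "PatientTruth",
    "RenderNoise",
    "RenderTruth",
    "SectionPlane",
    "ZERO_NOISE",
    "default_cohort_params",
    "expected_apparent_caliper",
    "generate_cohort",
    "generate_glomerulus",
    "nuclear_diameter_for_apparent",
    "render_images",
    "sample_biopsy",
    "section_glomerulus",
    "sectioned_nuclei",
    "write_manifest",
]
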