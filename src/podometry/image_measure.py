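"""Measurement of glomerulus rasters: IsoData thresholding, nucleus detection,
caliper diameters and areas.

A :class:`GlomerulusImage` holds three co-registered 2-D intensity channels
(podocyte nuclear marker, podocyte cytoplasm marker, pan-nuclear stain) plus
binary tuft and capsule masks.  Podocyte nuclei are the connected components
that are foreground in both nuclear channels, inside the tuft, and not
touching the capsule (capsule-touching components are treated as parietal
cells).  Sclerosis scoring is never automated; scores come from annotation
or the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure as sk_measure

from podometry.errors import ValidationError
from podometry.measurements import GlomerulusMeasurement

#: Components smaller than this (um^2) are discarded as debris.
DEFAULT_MIN_NUCLEUS_AREA_UM2 = 4.0

#: Convergence tolerance of the iterative threshold, in intensity units.
ISODATA_TOL = 0.5


@dataclass
class GlomerulusImage:
    """Three-channel raster of one glomerulus plus annotation masks."""

    dach1: np.ndarray
    snp: np.ndarray
    dapi: np.ndarray
    pixel_size: float  # um per pixel
    tuft_mask: Optional[np.ndarray] = None
    capsule_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shapes = {self.dach1.shape, self.snp.shape, self.dapi.shape}
        for mask in (self.tuft_mask, self.capsule_mask):
            if mask is not None:
                shapes.add(mask.shape)
        if len(shapes) != 1:
            raise ValidationError("all channels and masks must share one shape")
        if self.pixel_size <= 0:
            raise ValidationError("pixel size must be > 0")


def isodata_threshold(raster: np.ndarray, tol: float = ISODATA_TOL) -> float:
    """Iterative intensity threshold (Ridler-Calvard fixed point).

    Starting from the global mean, iterate
    ``t <- (mean(values <= t) + mean(values > t)) / 2`` until the change is
    below ``tol``.  Pixels strictly greater than the returned threshold are
    foreground.
    """
    values = np.asarray(raster, dtype=float).ravel()
    if values.size == 0 or np.ptp(values) == 0:
        raise ValidationError("threshold undefined for a constant raster")
    t = float(values.mean())
    vmax = float(values.max())
    for _ in range(500):
        low = values[values <= t]
        high = values[values > t]
        if high.size == 0:
            # all mass below t; pull t down to keep both classes non-empty
            t = float(low.max()) - tol
            continue
        if low.size == 0:
            t = float(high.min())
            continue
        t_next = (low.mean() + high.mean()) / 2.0
        if abs(t_next - t) < tol:
            return float(t_next)
        t = t_next
    return float(min(t, vmax))


def _foreground(raster: np.ndarray, tol: float = ISODATA_TOL) -> np.ndarray:
    return np.asarray(raster, dtype=float) > isodata_threshold(raster, tol)


def detect_podocyte_nuclei(
    img: GlomerulusImage, min_area_um2: float = DEFAULT_MIN_NUCLEUS_AREA_UM2
) -> list[np.ndarray]:
    """Detect podocyte nuclei; returns one boolean mask per nucleus.

    A nucleus is a connected component of
    ``dach1 foreground AND dapi foreground``, restricted to
    ``tuft AND NOT capsule``.  Any component whose full extent overlaps (or is
    adjacent to) the capsule mask is removed as a parietal cell, even when the
    overlapping part lies outside the tuft; components below ``min_area_um2``
    after restriction are dropped.
    """
    if img.tuft_mask is None or img.capsule_mask is None:
        raise ValidationError("nucleus detection requires tuft and capsule masks")
    if not np.any(np.asarray(img.dach1, dtype=float) > 0):
        return []
    foreground = _foreground(img.dach1) & _foreground(img.dapi)
    labels = sk_measure.label(foreground, connectivity=2)
    min_pixels = min_area_um2 / (img.pixel_size**2)
    # any overlap within one pixel of the capsule counts as "on the capsule"
    near_capsule = ndimage.binary_dilation(
        img.capsule_mask.astype(bool), structure=np.ones((3, 3), dtype=bool)
    )
    touching = set(np.unique(labels[near_capsule])) - {0}
    keep = img.tuft_mask.astype(bool) & ~img.capsule_mask.astype(bool)
    masks: list[np.ndarray] = []
    for region in sk_measure.regionprops(labels):
        if region.label in touching:
            continue
        comp = (labels == region.label) & keep
        if comp.sum() < min_pixels:
            continue
        masks.append(comp)
    return masks


def caliper_diameter_xy(mask: np.ndarray, pixel_size: float) -> float:
    """Mean of the axis-aligned X and Y extents of a mask, in micrometres.

    Uses the pixel-edge convention: a single pixel has extent 1 pixel.
    Axis-aligned by design, hence rotation-sensitive.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("caliper diameter undefined for an empty mask")
    rows, cols = np.nonzero(mask)
    extent_y = rows.max() - rows.min() + 1
    extent_x = cols.max() - cols.min() + 1
    return (extent_x + extent_y) / 2.0 * pixel_size


def measure_glomerulus(
    img: GlomerulusImage,
    sclerosis_score: int,
    glomerulus_id: str = "g",
    min_area_um2: float = DEFAULT_MIN_NUCLEUS_AREA_UM2,
) -> GlomerulusMeasurement:
    """Extract one measurement record from a raster.

    Tuft area is the mask area; synaptopodin-positive area is the
    IsoData-thresholded cytoplasm channel restricted to the tuft; nuclei come
    from :func:`detect_podocyte_nuclei`.  The sclerosis score is annotation
    input and passed through.
    """
    if img.tuft_mask is None or img.capsule_mask is None:
        raise ValidationError("measurement requires tuft and capsule masks")
    px_area = img.pixel_size**2
    tuft = img.tuft_mask.astype(bool)
    tuft_area = float(tuft.sum()) * px_area

    snp = np.asarray(img.snp, dtype=float)
    if np.ptp(snp) == 0:
        snp_area = 0.0
    else:
        snp_area = float((_foreground(snp) & tuft).sum()) * px_area

    diameters = tuple(
        caliper_diameter_xy(mask, img.pixel_size)
        for mask in detect_podocyte_nuclei(img, min_area_um2)
    )
    return GlomerulusMeasurement(
        glomerulus_id=glomerulus_id,
        tuft_area=tuft_area,
        sclerosis_score=sclerosis_score,
        nuclear_caliper_diameters=diameters,
        snp_area=min(snp_area, tuft_area),
    )


__all__ = [
    "DEFAULT_MIN_NUCLEUS_AREA_UM2",
    "ISODATA_TOL",
    "GlomerulusImage",
    "caliper_diameter_xy",
    "detect_podocyte_nuclei",
    "isodata_threshold",
    "measure_glomerulus",
]
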