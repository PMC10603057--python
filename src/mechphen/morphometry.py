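"""Image-derived morpho-mechanical features: focal adhesions, area, height.

Focal adhesions (FAs) are segmented from paxillin-like stainings with a
white top-hat background subtraction, global Otsu threshold and
8-connected component labeling, then fractionated into the study's size
classes: small (area <= 0.18 um^2), intermediate (0.18 < area <= 0.36
um^2) and large (> 0.36 um^2).  Cell and nucleus spread areas come from
max-projections of confocal stacks; heights from the occupied z-extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, white_tophat

__all__ = [
    "FA_SMALL_MAX_UM2",
    "FA_INTERMEDIATE_MAX_UM2",
    "FocalAdhesionSet",
    "FASizeFractions",
    "segment_fas",
    "fractionate_fas",
    "measure_area",
    "measure_height",
]

# FA size-class boundaries, um^2; boundaries belong to the smaller class
# (small: <= 0.18, intermediate: <= 0.36, large: above).
FA_SMALL_MAX_UM2 = 0.18
FA_INTERMEDIATE_MAX_UM2 = 0.36


@dataclass
class FocalAdhesionSet:
    """Segmented focal-adhesion regions of one image."""

    regions: list[dict]  # id, area_um2, area_px, centroid
    pixel_size_um: float
    source: str = ""

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([r["area_um2"] for r in self.regions], dtype=float)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class FASizeFractions:
    """Counts and proportions of FAs per size class."""

    n_small: int
    n_intermediate: int
    n_large: int
    t1_um2: float = FA_SMALL_MAX_UM2
    t2_um2: float = FA_INTERMEDIATE_MAX_UM2

    @property
    def total(self) -> int:
        return self.n_small + self.n_intermediate + self.n_large

    @property
    def proportions(self) -> tuple[float, float, float]:
        if self.total == 0:
            return (0.0, 0.0, 0.0)
        return (
            self.n_small / self.total,
            self.n_intermediate / self.total,
            self.n_large / self.total,
        )


def segment_fas(
    image: np.ndarray,
    pixel_size_um: float,
    background_radius_px: int = 10,
    min_area_px: int = 3,
    smooth_sigma_px: float = 0.7,
    source: str = "",
) -> FocalAdhesionSet:
    """Segment focal adhesions from a 2D FA-marker image.

    Pipeline: Gaussian denoising (``smooth_sigma_px``), white top-hat
    with a disk of ``background_radius_px`` (removes diffuse background
    larger than an FA), global Otsu threshold on the residual,
    8-connectivity labeling, and removal of regions below
    ``min_area_px``.  A flat or empty image yields an empty set rather
    than an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("FA segmentation expects a 2D image")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    if image.size == 0 or np.ptp(image) == 0:
        return FocalAdhesionSet([], pixel_size_um, source)
    if smooth_sigma_px > 0:
        image = gaussian(image, smooth_sigma_px, preserve_range=True)
    flat = white_tophat(image, footprint=disk(background_radius_px))
    if np.ptp(flat) == 0:
        return FocalAdhesionSet([], pixel_size_um, source)
    mask = flat > threshold_otsu(flat)
    labels = label(mask, connectivity=2)
    regions = []
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        regions.append(
            {
                "id": len(regions),
                "area_px": int(rp.area),
                "area_um2": float(rp.area) * pixel_size_um**2,
                "centroid": tuple(float(c) for c in rp.centroid),
            }
        )
    return FocalAdhesionSet(regions, pixel_size_um, source)


def fractionate_fas(fa_set: FocalAdhesionSet | np.ndarray) -> FASizeFractions:
    """Classify FA areas into small / intermediate / large size classes.

    Accepts a FocalAdhesionSet or a bare array of areas in um^2.  The
    printed boundaries are inclusive on the smaller class: an area of
    exactly 0.18 um^2 is small, exactly 0.36 um^2 intermediate.
    """
    areas = (
        fa_set.areas_um2
        if isinstance(fa_set, FocalAdhesionSet)
        else np.asarray(fa_set, dtype=float)
    )
    small = int(np.sum(areas <= FA_SMALL_MAX_UM2))
    inter = int(
        np.sum((areas > FA_SMALL_MAX_UM2) & (areas <= FA_INTERMEDIATE_MAX_UM2))
    )
    large = int(np.sum(areas > FA_INTERMEDIATE_MAX_UM2))
    return FASizeFractions(small, inter, large)


def measure_area(mask: np.ndarray, pixel_size_um: float) -> float:
    """Projected area of a binary mask in um^2.

    For a 3D (z, y, x) mask the max-projection along z is measured,
    matching area quantification from the top view of a confocal stack.
    An empty mask measures 0 with a warning.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    mask = np.asarray(mask).astype(bool)
    if mask.ndim == 3:
        mask = mask.any(axis=0)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D or 3D")
    n = int(mask.sum())
    if n == 0:
        warnings.warn("empty mask: area is 0", stacklevel=2)
    return n * pixel_size_um**2


def measure_height(
    mask3d: np.ndarray,
    z_step_um: float,
    occupancy_fraction: float = 0.01,
) -> float:
    """Height of a 3D mask from its occupied z-extent, in um.

    Height = (top occupied slice - bottom occupied slice + 1) x z_step,
    counting only slices whose occupancy exceeds ``occupancy_fraction``
    of the fullest slice — a guard against isolated speckle voxels far
    above the object inflating the height.
    """
    if z_step_um <= 0:
        raise ValueError("z step must be positive")
    mask3d = np.asarray(mask3d).astype(bool)
    if mask3d.ndim != 3:
        raise ValueError("height measurement expects a 3D (z, y, x) mask")
    occ = mask3d.sum(axis=(1, 2))
    if occ.sum() == 0:
        raise ValueError("empty mask: height undefined")
    keep = np.nonzero(occ > occupancy_fraction * occ.max())[0]
    return float((keep.max() - keep.min() + 1) * z_step_um)
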