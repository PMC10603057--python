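"""Particle image velocimetry for traction force microscopy bead images.

Displacements of fiducial beads between a cell-free reference image and
each stressed timelapse frame are estimated by windowed cross-
correlation: the images are tiled into interrogation windows, each
window pair is correlated via FFT after mean subtraction, and the
correlation peak is localized to subpixel precision with a three-point
Gaussian fit per axis.  A rigid pre-alignment (phase correlation)
removes stage drift, and a normalized-median test removes spurious
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import VectorField2D

__all__ = [
    "BeadImage",
    "AlignmentResult",
    "align_to_reference",
    "compute_displacement",
    "filter_outliers",
]


@dataclass
class BeadImage:
    """A fluorescent-bead image with its lateral calibration."""

    intensity: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("bead image must be 2D")
        if np.any(self.intensity < 0):
            raise ValueError("bead image intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class AlignmentResult:
    """Outcome of rigid drift correction against the reference image."""

    aligned: BeadImage
    shift_px: tuple[float, float]  # (row, col) drift of the frame
    alignable: bool
    confidence: float


def align_to_reference(
    frame: BeadImage,
    reference: BeadImage,
    confidence_threshold: float = 0.2,
    upsample_factor: int = 20,
) -> AlignmentResult:
    """Estimate and remove rigid drift of a frame relative to the reference.

    The translation is estimated by phase correlation (subpixel via
    Fourier upsampling); the frame is shifted back onto the reference
    grid.  Confidence is the Pearson correlation between the aligned
    frame and the reference over their central overlap; frames below
    ``confidence_threshold`` (e.g. pure noise) are flagged unalignable
    and returned unshifted.
    """
    if frame.intensity.shape != reference.intensity.shape:
        raise ValueError("frame and reference must have equal shapes")
    if frame.pixel_size_um != reference.pixel_size_um:
        raise ValueError("frame and reference must share the pixel size")
    shift, _, _ = phase_cross_correlation(
        reference.intensity, frame.intensity, upsample_factor=upsample_factor
    )
    # phase_cross_correlation returns the shift registering the frame to
    # the reference; the frame's drift is the negative of that.
    drift = (-float(shift[0]), -float(shift[1]))
    if drift == (0.0, 0.0):
        aligned = frame.intensity.copy()
    elif float(drift[0]).is_integer() and float(drift[1]).is_integer():
        aligned = np.roll(
            frame.intensity, (-int(drift[0]), -int(drift[1])), axis=(0, 1)
        )
    else:
        aligned = ndimage.shift(
            frame.intensity, (-drift[0], -drift[1]), order=3, mode="nearest"
        )
    conf = _overlap_correlation(aligned, reference.intensity, drift)
    ok = conf >= confidence_threshold
    out = aligned if ok else frame.intensity.copy()
    return AlignmentResult(
        aligned=BeadImage(np.clip(out, 0, None), frame.pixel_size_um),
        shift_px=drift,
        alignable=ok,
        confidence=conf,
    )


def _overlap_correlation(a: np.ndarray, b: np.ndarray, drift) -> float:
    """Pearson correlation over the region unaffected by edge fill."""
    my = int(np.ceil(abs(drift[0]))) + 1
    mx = int(np.ceil(abs(drift[1]))) + 1
    aa = a[my:-my or None, mx:-mx or None].ravel()
    bb = b[my:-my or None, mx:-mx or None].ravel()
    if aa.size < 4 or aa.std() == 0 or bb.std() == 0:
        return 0.0
    return float(np.corrcoef(aa, bb)[0, 1])


def compute_displacement(
    reference: BeadImage,
    deformed: BeadImage,
    window_px: int = 32,
    overlap_fraction: float = 0.5,
) -> VectorField2D:
    """Windowed cross-correlation PIV between reference and deformed image.

    For each interrogation window the displacement is the argmax of the
    mean-subtracted FFT cross-correlation, refined per axis with a
    three-point Gaussian (log-parabolic) fit.  The vector grid spacing
    is ``window_px * (1 - overlap_fraction)`` and displacements are
    returned in um.

    Each reference window is matched against a search region of the
    deformed image extended by ``window_px // 4`` on every side
    (single-pass search limit), so bead pairs leaving the window do not
    bias the peak.  Windows are placed so the search region fits inside
    the image.  Windows with (near-)zero intensity variance, or whose
    correlation peak sits on the search border, are marked invalid.
    """
    if window_px < 8:
        raise ValueError("interrogation window must be at least 8 px")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap fraction must lie in [0, 1)")
    ref = reference.intensity
    de = deformed.intensity
    if ref.shape != de.shape:
        raise ValueError("reference and deformed images must match in shape")
    if reference.pixel_size_um != deformed.pixel_size_um:
        raise ValueError("images must share the pixel size")
    margin = window_px // 4
    if window_px + 2 * margin > min(ref.shape):
        raise ValueError("interrogation window larger than the image")

    step = max(1, int(round(window_px * (1.0 - overlap_fraction))))
    ys = np.arange(margin, ref.shape[0] - window_px - margin + 1, step)
    xs = np.arange(margin, ref.shape[1] - window_px - margin + 1, step)
    u = np.zeros((len(ys), len(xs)))
    v = np.zeros((len(ys), len(xs)))
    valid = np.ones((len(ys), len(xs)), dtype=bool)

    from skimage.feature import match_template

    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            a = ref[y0 : y0 + window_px, x0 : x0 + window_px]
            b = de[
                y0 - margin : y0 + window_px + margin,
                x0 - margin : x0 + window_px + margin,
            ]
            if a.std() < 1e-12 or b.std() < 1e-12:
                valid[i, j] = False
                continue
            ncc = match_template(b, a)  # shape (2*margin+1, 2*margin+1)
            iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
            if (
                ncc[iy, ix] <= 0
                or iy in (0, ncc.shape[0] - 1)
                or ix in (0, ncc.shape[1] - 1)
            ):
                valid[i, j] = False
                continue
            dy = iy - margin + _gaussian_subpixel(ncc[:, ix], iy)
            dx = ix - margin + _gaussian_subpixel(ncc[iy, :], ix)
            u[i, j] = dx * reference.pixel_size_um
            v[i, j] = dy * reference.pixel_size_um

    px = reference.pixel_size_um
    origin = (
        (ys[0] + (window_px - 1) / 2.0) * px,
        (xs[0] + (window_px - 1) / 2.0) * px,
    )
    return VectorField2D(u, v, spacing_um=step * px, origin_um=origin, valid=valid)


def _gaussian_subpixel(line: np.ndarray, i: int) -> float:
    """Three-point Gaussian peak interpolation along one axis."""
    if i <= 0 or i >= len(line) - 1:
        return 0.0
    cm, c0, cp = line[i - 1], line[i], line[i + 1]
    if cm <= 0 or c0 <= 0 or cp <= 0:
        # parabolic fallback when log-fit is undefined
        denom = cm - 2 * c0 + cp
        return 0.0 if denom == 0 else float(0.5 * (cm - cp) / denom)
    lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
    denom = 2.0 * (lm + lp - 2.0 * l0)
    return 0.0 if denom == 0 else float((lm - lp) / denom)


def filter_outliers(
    field: VectorField2D,
    threshold: float = 2.0,
    epsilon_um: float = 0.02,
) -> VectorField2D:
    """Normalized-median outlier test over the 8-neighborhood.

    For each vector, the residual against the median of its valid
    neighbors is normalized by the median absolute neighbor residual
    plus ``epsilon_um``; vectors whose normalized residual magnitude
    exceeds ``threshold`` are invalidated and replaced by the median of
    their valid neighbors.  ``threshold = inf`` is the identity.

    The noise floor ``epsilon_um`` is in um (0.1 px at the default
    0.2 um/px calibration).
    """
    if field.shape[0] < 3 or field.shape[1] < 3:
        raise ValueError("outlier filtering needs at least a 3x3 vector grid")
    u, v = field.u, field.v
    valid = field.valid
    ny, nx = field.shape
    bad = np.zeros_like(valid)
    repl_u = np.zeros_like(u)
    repl_v = np.zeros_like(v)

    for i in range(ny):
        for j in range(nx):
            nu, nv = _neighbors(u, v, valid, i, j)
            if len(nu) < 3:
                continue
            med_u, med_v = np.median(nu), np.median(nv)
            ru = np.abs(u[i, j] - med_u) / (np.median(np.abs(nu - med_u)) + epsilon_um)
            rv = np.abs(v[i, j] - med_v) / (np.median(np.abs(nv - med_v)) + epsilon_um)
            if np.hypot(ru, rv) > threshold or not valid[i, j]:
                bad[i, j] = True
                repl_u[i, j] = med_u
                repl_v[i, j] = med_v

    out = field.copy()
    out.u[bad] = repl_u[bad]
    out.v[bad] = repl_v[bad]
    # replaced vectors are valid again; invalid vectors without enough
    # neighbors to interpolate from stay invalid
    out.valid = valid | bad
    return out


def _neighbors(u, v, valid, i, j):
    ny, nx = u.shape
    nu, nv = [], []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ii, jj = i + di, j + dj
            if 0 <= ii < ny and 0 <= jj < nx and valid[ii, jj]:
                nu.append(u[ii, jj])
                nv.append(v[ii, jj])
    return np.asarray(nu), np.asarray(nv)
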