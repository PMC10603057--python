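"""Fourier-transform traction cytometry (FTTC) on an elastic half-space.

Cells pulling on a soft gel deform it; with the gel modelled as a
semi-infinite, homogeneous, isotropic linear-elastic solid the surface
displacement u is the Boussinesq Green's function G convolved with the
surface traction t.  In Fourier space the convolution becomes a per-mode
2x2 matrix product, u_hat(k) = G_hat(k) t_hat(k), so the inverse problem
(tractions from measured bead displacements) reduces to independent 2x2
solves, optionally Tikhonov-regularized for noisy data.

Conventions: displacements in um, tractions in Pa, wavevectors in
rad/um.  The zero mode (net force / rigid translation) carries no
information about internal tractions and is forced to zero on both the
forward and the inverse path, which enforces global force balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SubstrateModel, VectorField2D

__all__ = [
    "TractionResult",
    "greens_tensor_fourier",
    "forward_displacement",
    "solve_fttc",
    "traction_summary",
    "traction_summary_normalized",
]

#: Relative tolerance on the net traction vector for a field to count as
#: balanced (net force zero).
FORCE_BALANCE_RTOL = 1e-9


@dataclass
class TractionResult:
    """Reconstructed traction field plus inversion diagnostics."""

    traction: VectorField2D
    magnitude_map: np.ndarray
    regularization_lambda: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.regularization_lambda < 0:
            raise ValueError("regularization lambda must be >= 0")


def greens_tensor_fourier(
    kx: np.ndarray | float, ky: np.ndarray | float, substrate: SubstrateModel
) -> np.ndarray:
    """Boussinesq surface Green's tensor of the elastic half-space in
    Fourier space.

    For wavevector k = (kx, ky), |k| = k,

        G_hat(k) = 2 (1 + nu) / (E k^3) *
                   [[(1 - nu) k^2 + nu ky^2,  -nu kx ky],
                    [-nu kx ky,               (1 - nu) k^2 + nu kx^2]]

    which maps a traction mode (Pa) to a surface displacement mode (um
    when k is in rad/um).

    Parameters
    ----------
    kx, ky : float or ndarray
        Wavevector components, rad/um.  Must not both be zero anywhere.
    substrate : SubstrateModel

    Returns
    -------
    ndarray, shape (..., 2, 2)
        The symmetric, positive-definite tensor at each wavevector.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k2 = kx**2 + ky**2
    if np.any(k2 == 0):
        raise ValueError(
            "Green's tensor is singular at the zero wavevector; the solver "
            "handles the zero mode separately"
        )
    k = np.sqrt(k2)
    e = substrate.young_modulus_pa
    nu = substrate.poisson_ratio
    pref = 2.0 * (1.0 + nu) / (e * k**3)
    g = np.empty(np.broadcast(kx, ky).shape + (2, 2), dtype=float)
    g[..., 0, 0] = pref * ((1.0 - nu) * k2 + nu * ky**2)
    g[..., 1, 1] = pref * ((1.0 - nu) * k2 + nu * kx**2)
    g[..., 0, 1] = g[..., 1, 0] = pref * (-nu * kx * ky)
    return g


def _wavevectors(shape: tuple[int, int], spacing_um: float):
    """fftfreq-ordered angular wavevector grids (rad/um) for a field."""
    ny, nx = shape
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing_um)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing_um)
    return np.meshgrid(kx, ky)  # both shaped (ny, nx)


def _greens_grid(shape, spacing_um, substrate) -> np.ndarray:
    """Green's tensor on the FFT grid; the zero mode is left as zeros.

    At the Nyquist frequencies of even-sized grids the shear coupling
    G_xy (odd in kx and ky) has no Hermitian-symmetric partner bin, so
    it is zeroed there; otherwise real traction fields would map to
    displacement spectra with a non-real inverse transform.
    """
    kxg, kyg = _wavevectors(shape, spacing_um)
    g = np.zeros(shape + (2, 2))
    nz = (kxg != 0) | (kyg != 0)
    g[nz] = greens_tensor_fourier(kxg[nz], kyg[nz], substrate)
    ny, nx = shape
    nyq = np.zeros(shape, dtype=bool)
    if nx % 2 == 0:
        nyq[:, nx // 2] = True
    if ny % 2 == 0:
        nyq[ny // 2, :] = True
    g[nyq, 0, 1] = 0.0
    g[nyq, 1, 0] = 0.0
    return g


def forward_displacement(
    traction: VectorField2D, substrate: SubstrateModel
) -> VectorField2D:
    """Surface displacement produced by a balanced traction field.

    Applies u_hat(k) = G_hat(k) t_hat(k) per non-zero mode and sets
    u_hat(0) = 0 (the rigid-body translation is unobservable).  Input
    tractions in Pa, output displacements in um.

    Raises
    ------
    ValueError
        If the traction field is unbalanced: the magnitude of the summed
        traction vector exceeds ``FORCE_BALANCE_RTOL`` relative to the
        summed traction magnitude.
    """
    net = traction.net_vector()
    scale = np.sum(traction.magnitude())
    if scale > 0 and np.linalg.norm(net) > FORCE_BALANCE_RTOL * scale:
        raise ValueError(
            f"traction field is not balanced: net force {net} "
            f"(relative {np.linalg.norm(net) / scale:.3e})"
        )
    that = np.stack(
        [np.fft.fft2(traction.u), np.fft.fft2(traction.v)], axis=-1
    )
    g = _greens_grid(traction.shape, traction.spacing_um, substrate)
    uhat = np.einsum("...ij,...j->...i", g, that)
    uhat[0, 0, :] = 0.0
    u = np.fft.ifft2(uhat[..., 0]).real
    v = np.fft.ifft2(uhat[..., 1]).real
    return VectorField2D(u, v, traction.spacing_um, traction.origin_um)


def solve_fttc(
    displacement: VectorField2D,
    substrate: SubstrateModel,
    lam: float = 0.0,
    pad_factor: int = 1,
) -> TractionResult:
    """Invert a displacement field for the traction field.

    Per non-zero Fourier mode solves the (optionally Tikhonov-
    regularized) normal equations

        t_hat = (G_hat^T G_hat + lam^2 I)^-1 G_hat^T u_hat,

    which for ``lam = 0`` reduces to the direct inverse t_hat =
    G_hat^-1 u_hat.  The mean displacement is subtracted first and the
    zero-mode traction is forced to zero, so the reconstruction is
    balanced by construction.

    Parameters
    ----------
    displacement : VectorField2D
        Measured displacement field, um.
    substrate : SubstrateModel
    lam : float
        Tikhonov parameter, same units as the Green's tensor entries
        (um/Pa).  0 disables regularization.
    pad_factor : int
        Zero-pad each axis to ``pad_factor`` times its extent before the
        FFT and crop back, to attenuate periodic wrap-around on fields
        cropped from larger scenes.  1 (default) disables padding; the
        unpadded inversion is the exact inverse of
        :func:`forward_displacement`.

    Returns
    -------
    TractionResult
        Traction in Pa, its magnitude map, and the displacement-space
        residual norm ``||G t_hat - u_hat||`` (um, Frobenius over modes).
    """
    if lam < 0:
        raise ValueError("regularization lambda must be >= 0")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    u0 = displacement.u
    v0 = displacement.v
    if not (np.all(np.isfinite(u0)) and np.all(np.isfinite(v0))):
        raise ValueError(
            "displacement field contains NaN/inf; interpolate invalid "
            "vectors before inversion"
        )
    u0 = u0 - u0.mean()
    v0 = v0 - v0.mean()

    ny, nx = u0.shape
    if pad_factor > 1:
        pny, pnx = pad_factor * ny, pad_factor * nx
        up = np.zeros((pny, pnx))
        vp = np.zeros((pny, pnx))
        up[:ny, :nx] = u0
        vp[:ny, :nx] = v0
    else:
        pny, pnx = ny, nx
        up, vp = u0, v0

    uhat = np.stack([np.fft.fft2(up), np.fft.fft2(vp)], axis=-1)
    g = _greens_grid((pny, pnx), displacement.spacing_um, substrate)

    if lam == 0.0:
        # direct per-mode inverse; zero mode stays zero
        that = np.zeros_like(uhat)
        nz = np.ones((pny, pnx), dtype=bool)
        nz[0, 0] = False
        that[nz] = np.linalg.solve(g[nz], uhat[nz][..., None])[..., 0]
    else:
        gt = np.swapaxes(g, -1, -2)
        lhs = gt @ g + (lam**2) * np.eye(2)
        rhs = np.einsum("...ij,...j->...i", gt, uhat)
        that = np.zeros_like(uhat)
        nz = np.ones((pny, pnx), dtype=bool)
        nz[0, 0] = False
        that[nz] = np.linalg.solve(lhs[nz], rhs[nz][..., None])[..., 0]

    res = np.einsum("...ij,...j->...i", g, that) - uhat
    res[0, 0, :] = 0.0
    residual = float(np.linalg.norm(res) / np.sqrt(pny * pnx))

    tx = np.fft.ifft2(that[..., 0]).real[:ny, :nx]
    ty = np.fft.ifft2(that[..., 1]).real[:ny, :nx]
    field = VectorField2D(
        tx, ty, displacement.spacing_um, displacement.origin_um
    )
    return TractionResult(
        traction=field,
        magnitude_map=field.magnitude(),
        regularization_lambda=lam,
        residual_norm=residual,
    )


def traction_summary(
    magnitude_maps: list[np.ndarray] | np.ndarray,
    cell_masks: list[np.ndarray] | np.ndarray,
) -> float:
    """Per-cell traction magnitude: median over space, then mean over time.

    At each timepoint the median traction magnitude over the pixels
    inside the cell mask is taken; the summary is the arithmetic mean of
    these per-timepoint medians (Pa).
    """
    maps = _as_map_list(magnitude_maps)
    masks = _as_map_list(cell_masks)
    if len(maps) == 0:
        raise ValueError("at least one timepoint is required")
    if len(maps) != len(masks):
        raise ValueError("one cell mask is required per timepoint")
    medians = []
    for t, (m, mask) in enumerate(zip(maps, masks)):
        mask = np.asarray(mask, dtype=bool)
        if m.shape != mask.shape:
            raise ValueError(f"map/mask shape mismatch at timepoint {t}")
        if not mask.any():
            raise ValueError(f"empty cell mask at timepoint {t}")
        medians.append(float(np.median(np.asarray(m, float)[mask])))
    return float(np.mean(medians))


def _as_map_list(maps) -> list[np.ndarray]:
    if isinstance(maps, np.ndarray) and maps.ndim == 2:
        return [maps]
    return [np.asarray(m) for m in maps]


def traction_summary_normalized(summary_pa: float, cell_area_um2: float) -> float:
    """Traction summary divided by cell spread area (Pa/um^2)."""
    if cell_area_um2 <= 0:
        raise ValueError("cell area must be positive")
    return summary_pa / cell_area_um2
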