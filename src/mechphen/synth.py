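"""Seeded synthetic data emulating the vimentin mechanostasis study design.

Every input the analysis pipeline consumes can be generated here with a
fixed seed: ground-truth traction scenes and bead-image pairs for the
TFM stages, focal-adhesion and 3D cell/nucleus images for morphometry,
condition-structured morpho-mechanical property tables for the
phenotype analysis, and qPCR Ct tables for relative expression.

The property-table generator encodes the study's qualitative structure:
vimentin-wildtype (VimWT) fibroblasts respond to substrate stiffness
(12 vs 27 kPa) and collagen density (25 vs 100 ug/ml), vimentin-knockout
(VimKO) cells are unresponsive at 24 h, and at 48 h VimKO cells on the
stiff substrate recover the wildtype-like response.  Absolute scales are
conventions; only this relational structure is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Condition,
    SubstrateModel,
    VectorField2D,
    control_condition,
    full_design,
)
from .piv import BeadImage

__all__ = [
    "TractionScene",
    "EffectModel",
    "PropertyEffect",
    "CellStack",
    "make_traction_scene",
    "render_bead_images",
    "make_fa_image",
    "make_cell_stack",
    "default_effect_model",
    "make_property_table",
    "make_qpcr_dataset",
]


# --------------------------------------------------------------------------
# Traction scenes and bead images
# --------------------------------------------------------------------------

@dataclass
class TractionScene:
    """Ground-truth traction field with its cell mask and substrate."""

    truth_traction: VectorField2D
    cell_mask: np.ndarray
    substrate: SubstrateModel
    seed: int


def make_traction_scene(
    grid_shape: tuple[int, int] = (128, 128),
    grid_spacing_um: float = 0.2,
    n_patches: int = 8,
    peak_traction_pa: float = 300.0,
    substrate: SubstrateModel | None = None,
    seed: int = 0,
) -> TractionScene:
    """Generate a balanced, cell-like ground-truth traction field.

    The traction is a sum of compact Gaussian patches inside an
    elliptical cell mask, oriented inward (contractile, as adherent
    cells pull toward their center).  The mean traction inside the mask
    is subtracted per component, so the field sums to zero exactly and
    stays zero outside the mask.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if peak_traction_pa <= 0:
        raise ValueError("peak traction must be positive")
    ny, nx = grid_shape
    if min(ny, nx) < 32:
        raise ValueError("grid too small to contain a cell mask (min 32)")
    if substrate is None:
        substrate = SubstrateModel(young_modulus_pa=12_000.0)
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = 0.30 * ny, 0.38 * nx  # cell semi-axes, px
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    tx = np.zeros(grid_shape)
    ty = np.zeros(grid_shape)
    sigma = 0.04 * min(ny, nx)
    for _ in range(n_patches):
        # rejection-sample a patch center inside the mask, off-center so
        # the inward pull is non-trivial
        while True:
            py = rng.uniform(cy - ay, cy + ay)
            px = rng.uniform(cx - ax, cx + ax)
            r2 = ((py - cy) / ay) ** 2 + ((px - cx) / ax) ** 2
            if 0.15 < r2 <= 0.95:
                break
        amp = rng.uniform(0.4, 1.0) * peak_traction_pa
        blob = np.exp(-(((yy - py) ** 2 + (xx - px) ** 2) / (2 * sigma**2)))
        dvec = np.array([cy - py, cx - px])
        dvec = dvec / np.linalg.norm(dvec)
        ty += amp * blob * dvec[0]
        tx += amp * blob * dvec[1]

    tx[~mask] = 0.0
    ty[~mask] = 0.0
    # enforce exact force balance without touching pixels outside the cell
    tx[mask] -= tx[mask].mean()
    ty[mask] -= ty[mask].mean()

    truth = VectorField2D(tx, ty, spacing_um=grid_spacing_um)
    return TractionScene(truth, mask, substrate, seed)


def render_bead_images(
    scene: TractionScene,
    displacement: VectorField2D,
    bead_density_per_um2: float = 0.5,
    bead_sigma_px: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BeadImage, BeadImage]:
    """Render the relaxed/stressed bead-image pair for a scene.

    The reference image shows beads at seeded random positions as
    Gaussian spots (the cell-free, relaxed gel); the deformed image
    shows the same beads displaced by the displacement field sampled at
    each bead position.  Additive Gaussian noise of ``noise_sd`` is
    applied to both.
    """
    if bead_density_per_um2 <= 0:
        raise ValueError("bead density must be positive")
    if displacement.shape != scene.truth_traction.shape:
        raise ValueError("displacement grid must match the scene grid")
    ny, nx = displacement.shape
    px_um = displacement.spacing_um
    max_disp_px = displacement.magnitude().max() / px_um
    if max_disp_px > min(ny, nx) / 4:
        raise ValueError(
            "displacement exceeds a quarter of the image size; PIV cannot "
            "recover it"
        )
    rng = np.random.default_rng(seed)
    n_beads = int(round(bead_density_per_um2 * ny * nx * px_um**2))
    by = rng.uniform(0, ny - 1, n_beads)
    bx = rng.uniform(0, nx - 1, n_beads)
    amp = rng.uniform(0.6, 1.0, n_beads)

    # displacement (um -> px) at each bead position, bilinear interpolation
    from scipy.ndimage import map_coordinates

    u_px = map_coordinates(displacement.u, [by, bx], order=1) / px_um
    v_px = map_coordinates(displacement.v, [by, bx], order=1) / px_um

    ref = _render_spots(ny, nx, by, bx, amp, bead_sigma_px)
    de = _render_spots(ny, nx, by + v_px, bx + u_px, amp, bead_sigma_px)
    if noise_sd > 0:
        ref = ref + rng.normal(0, noise_sd, ref.shape)
        de = de + rng.normal(0, noise_sd, de.shape)
    ref = np.clip(ref, 0, None)
    de = np.clip(de, 0, None)
    return BeadImage(ref, px_um), BeadImage(de, px_um)


def _render_spots(ny, nx, ys, xs, amps, sigma) -> np.ndarray:
    """Sum of Gaussian spots, each rendered over a +-4 sigma patch."""
    img = np.zeros((ny, nx))
    r = int(np.ceil(4 * sigma))
    for y, x, a in zip(ys, xs, amps):
        y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
        x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
        y0c, y1c = max(y0, 0), min(y1, ny)
        x0c, x1c = max(x0, 0), min(x1, nx)
        if y0c >= y1c or x0c >= x1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        img[y0c:y1c, x0c:x1c] += a * np.exp(
            -(((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
        )
    return img


# --------------------------------------------------------------------------
# Focal-adhesion images and 3D cell stacks
# --------------------------------------------------------------------------

def make_fa_image(
    image_shape: tuple[int, int] = (512, 512),
    n_fas: int = 40,
    area_distribution_um2: tuple[float, float] = (0.25, 0.15),
    pixel_size_um: float = 0.1,
    intensity_snr: float = 10.0,
    seed: int = 0,
    max_placement_tries: int = 200,
) -> tuple[np.ndarray, list[dict]]:
    """Synthetic paxillin-like image: bright elliptical focal adhesions
    on a noisy background.

    Areas are drawn from a lognormal matched to the given (mean, sd) in
    um^2 and truncated below at one pixel.  Regions are placed without
    overlap by rejection sampling; if a region cannot be placed within
    ``max_placement_tries`` attempts a RuntimeError is raised.

    Returns the image and a ground-truth list of regions, each a dict
    with keys ``id``, ``area_um2`` (exact rasterized pixel count times
    pixel_size^2), ``area_px`` and ``centroid``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    ny, nx = image_shape
    rng = np.random.default_rng(seed)
    noise_sd = 1.0
    background = 5.0
    img = background + rng.normal(0, noise_sd, image_shape)
    occupied = np.zeros(image_shape, dtype=bool)
    truth: list[dict] = []

    mean, sd = area_distribution_um2
    mu = np.log(mean**2 / np.sqrt(mean**2 + sd**2))
    s2 = np.log(1 + (sd / mean) ** 2)

    from skimage.draw import ellipse as draw_ellipse

    for k in range(n_fas):
        area_um2 = float(np.exp(rng.normal(mu, np.sqrt(s2))))
        area_px = max(1, int(round(area_um2 / pixel_size_um**2)))
        q = rng.uniform(1.5, 3.0)  # FAs are elongated
        a = np.sqrt(area_px * q / np.pi)
        b = area_px / (np.pi * a)
        theta = rng.uniform(0, np.pi)
        placed = False
        for _ in range(max_placement_tries):
            cy = rng.uniform(a + 2, ny - a - 3)
            cx = rng.uniform(a + 2, nx - a - 3)
            rr, cc = draw_ellipse(cy, cx, max(b, 0.6), max(a, 0.6),
                                  shape=image_shape, rotation=theta)
            if rr.size == 0:
                continue
            # demand a one-pixel moat so regions stay separable
            if not occupied[np.clip(rr, 0, ny - 1), np.clip(cc, 0, nx - 1)].any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place focal adhesion {k} without overlap; "
                "lower n_fas or enlarge the image"
            )
        img[rr, cc] += intensity_snr * noise_sd
        # occupy a dilated ellipse so later regions keep a moat and
        # connected components stay separable
        rm, cm = draw_ellipse(cy, cx, max(b, 0.6) + 2, max(a, 0.6) + 2,
                              shape=image_shape, rotation=theta)
        occupied[rm, cm] = True
        truth.append(
            {
                "id": k,
                "area_px": int(rr.size),
                "area_um2": float(rr.size) * pixel_size_um**2,
                "centroid": (float(rr.mean()), float(cc.mean())),
            }
        )
    return np.clip(img, 0, None), truth


@dataclass
class CellStack:
    """3D boolean masks of a cell and its nucleus on a confocal grid."""

    cell: np.ndarray  # (z, y, x) boolean
    nucleus: np.ndarray
    voxel_size_um: float  # lateral (xy)
    z_step_um: float


def make_cell_stack(
    xy_shape: tuple[int, int] = (128, 128),
    z_steps: int = 20,
    cell_area_um2: float = 1000.0,
    cell_height_um: float = 5.0,
    nucleus_area_um2: float = 180.0,
    nucleus_height_um: float = 3.0,
    voxel_size_um: float = 0.5,
    z_step_um: float = 0.5,
    seed: int = 0,
) -> CellStack:
    """Generate 3D cell and nucleus masks with controlled area and height.

    The in-plane footprints are quasi-circular masks built from exactly
    the pixel count that matches the requested projected area, so the
    measured max-projection area equals the request to within one voxel.
    Heights are realized as whole numbers of z-slices (nearest to the
    request).  The nucleus is centered inside the cell.
    """
    ny, nx = xy_shape
    if nucleus_area_um2 >= cell_area_um2:
        raise ValueError("nucleus must fit inside the cell (area)")
    if nucleus_height_um > cell_height_um:
        raise ValueError("nucleus height cannot exceed cell height")
    n_cell = int(round(cell_height_um / z_step_um))
    n_nuc = int(round(nucleus_height_um / z_step_um))
    if n_cell < 1 or n_nuc < 1:
        raise ValueError("heights below one z-step are not representable")
    if n_cell > z_steps:
        raise ValueError("cell height exceeds the z extent of the stack")
    cell_px = int(round(cell_area_um2 / voxel_size_um**2))
    nuc_px = int(round(nucleus_area_um2 / voxel_size_um**2))
    if cell_px > ny * nx:
        raise ValueError("cell area exceeds the field of view")
    rng = np.random.default_rng(seed)

    cell2d = _exact_area_footprint(xy_shape, cell_px, rng)
    nuc2d = _exact_area_footprint(xy_shape, nuc_px, rng)
    cell = np.zeros((z_steps, ny, nx), dtype=bool)
    nuc = np.zeros((z_steps, ny, nx), dtype=bool)
    cell[:n_cell] = cell2d
    nuc[:n_nuc] = nuc2d
    return CellStack(cell, nuc, voxel_size_um, z_step_um)


def _exact_area_footprint(shape, n_px: int, rng) -> np.ndarray:
    """Quasi-circular centered mask with exactly n_px pixels."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = (yy - (ny - 1) / 2.0) ** 2 + (xx - (nx - 1) / 2.0) ** 2
    # deterministic sub-pixel jitter breaks distance ties
    d = d + rng.uniform(0, 1e-6, d.shape)
    idx = np.argsort(d.ravel())[:n_px]
    mask = np.zeros(ny * nx, dtype=bool)
    mask[idx] = True
    return mask.reshape(shape)


# --------------------------------------------------------------------------
# Morpho-mechanical property tables (the phenotype-analysis input)
# --------------------------------------------------------------------------

@dataclass
class PropertyEffect:
    """Effect structure of one morpho-mechanical property.

    Multipliers act on the control-condition mean: ``stiffness_mult``
    applies on the stiff substrate (E_H), ``density_mult`` on the dense
    coating (C_H) — both only when the cell is responsive — and
    ``genotype_mult`` applies to unresponsive VimKO cells.
    """

    category: str
    baseline: float
    replicate_sd: float
    stiffness_mult: float = 1.0
    density_mult: float = 1.0
    genotype_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0:
            raise ValueError("replicate SD must be non-negative")


@dataclass
class EffectModel:
    """Generative model for condition-structured property tables.

    Encodes the study's qualitative structure: VimWT cells respond to
    substrate stiffness and ECM density; VimKO cells sit at a flat,
    genotype-shifted level at 24 h; at 48 h VimKO cells on the stiff
    substrate are rescued and respond like VimWT (``rescue_at_48h``).
    The control condition (E_P-C_P-VimWT) has all multipliers at 1.
    """

    properties: dict[str, PropertyEffect] = field(default_factory=dict)
    n_replicates: int = 6
    rescue_at_48h: bool = True

    def mean_value(self, condition: Condition, prop: str) -> float:
        eff = self.properties[prop]
        stiff = condition.stiffness_level == "E_H"
        dense = condition.ecm_level == "C_H"
        ko = condition.genotype == "VimKO"
        rescued = (
            ko and self.rescue_at_48h and condition.timepoint_h >= 48 and stiff
        )
        mean = eff.baseline
        if not ko or rescued:
            if stiff:
                mean *= eff.stiffness_mult
            if dense:
                mean *= eff.density_mult
        if ko and not rescued:
            mean *= eff.genotype_mult
        return mean


# ~15 properties, 3 per category; multipliers sized so condition shifts
# are 1-3 control SDs (replicate CV is 10%), recoverable but not
# degenerate.  Cellular morphology / mechanics / cell-matrix respond
# strongly to the substrate; nuclear morphology and migration are the
# properties most depressed by vimentin loss.
_DEFAULT_PROPERTIES: dict[str, PropertyEffect] = {
    # cellular morphology
    "cell_area_um2": PropertyEffect("cellular morphology", 1500.0, 150.0, 1.25, 1.12, 0.85),
    "cell_height_um": PropertyEffect("cellular morphology", 5.0, 0.5, 0.80, 0.92, 1.15),
    "cell_aspect_ratio": PropertyEffect("cellular morphology", 1.8, 0.18, 1.22, 1.10, 0.88),
    # nuclear morphology
    "nucleus_area_um2": PropertyEffect("nuclear morphology", 180.0, 18.0, 1.12, 1.06, 0.78),
    "nucleus_height_um": PropertyEffect("nuclear morphology", 3.0, 0.3, 0.90, 0.95, 1.20),
    "nucleus_volume_um3": PropertyEffect("nuclear morphology", 400.0, 40.0, 1.10, 1.05, 0.76),
    # cell mechanics
    "traction_pa": PropertyEffect("cell mechanics", 120.0, 12.0, 1.30, 1.15, 0.80),
    "traction_per_area_pa_um2": PropertyEffect("cell mechanics", 0.08, 0.008, 1.22, 1.10, 0.82),
    "strain_energy_pj": PropertyEffect("cell mechanics", 0.50, 0.05, 1.28, 1.12, 0.78),
    # cell migration
    "migration_speed_um_h": PropertyEffect("cell migration", 20.0, 2.0, 1.10, 1.05, 0.72),
    "migration_persistence": PropertyEffect("cell migration", 0.50, 0.05, 1.08, 1.04, 0.75),
    "track_length_um": PropertyEffect("cell migration", 80.0, 8.0, 1.10, 1.06, 0.72),
    # cell-matrix interactions
    "fa_count": PropertyEffect("cell-matrix interactions", 60.0, 6.0, 1.20, 1.25, 0.85),
    "fa_mean_area_um2": PropertyEffect("cell-matrix interactions", 0.30, 0.03, 1.18, 1.20, 0.86),
    "fa_large_fraction": PropertyEffect("cell-matrix interactions", 0.25, 0.025, 1.20, 1.22, 0.84),
}


def default_effect_model(n_replicates: int = 6) -> EffectModel:
    """The default 15-property effect model (see module docstring)."""
    return EffectModel(properties=dict(_DEFAULT_PROPERTIES),
                       n_replicates=n_replicates)


def make_property_table(
    effect_model: EffectModel | None = None,
    design: list[Condition] | None = None,
    n_replicates: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level morpho-mechanical property table for a design.

    Values are drawn from Normal(condition mean, replicate SD), where
    the condition mean is the control baseline times the condition's
    effect multipliers.  Columns: condition_id, stiffness_level,
    ecm_level, genotype, timepoint_h, replicate, property, category,
    value.

    The design must contain the control condition E_P-C_P-VimWT (at any
    of its timepoints).
    """
    if effect_model is None:
        effect_model = default_effect_model()
    if design is None:
        design = full_design(24)
    if n_replicates is None:
        n_replicates = effect_model.n_replicates
    has_control = any(
        c.stiffness_level == "E_P" and c.ecm_level == "C_P"
        and c.genotype == "VimWT"
        for c in design
    )
    if not has_control:
        raise ValueError("design must include the control condition E_P-C_P-VimWT")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in design:
        for prop, eff in effect_model.properties.items():
            mean = effect_model.mean_value(cond, prop)
            vals = rng.normal(mean, eff.replicate_sd, n_replicates)
            for r, val in enumerate(vals):
                rows.append(
                    {
                        "condition_id": cond.condition_id,
                        "stiffness_level": cond.stiffness_level,
                        "ecm_level": cond.ecm_level,
                        "genotype": cond.genotype,
                        "timepoint_h": cond.timepoint_h,
                        "replicate": r,
                        "property": prop,
                        "category": eff.category,
                        "value": float(val),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

def make_qpcr_dataset(
    true_fold_changes: dict[str, dict[str, float]],
    efficiencies: dict[str, float] | None = None,
    ct_noise_sd: float = 0.0,
    n_samples: int = 6,
    seed: int = 0,
    reference_gene: str = "Gapdh",
    control_condition_id: str = "control",
    ct_target_control: float = 24.0,
    ct_reference: float = 18.0,
) -> pd.DataFrame:
    """qPCR Ct table whose exact Pfaffl back-calculation returns the
    requested fold changes.

    ``true_fold_changes`` maps gene -> {condition_id -> fold change
    relative to the control condition}; the control condition itself is
    added implicitly with fold change 1.  A target amplifying with
    efficiency E and fold change F relative to control has its Ct
    lowered by log(F)/log(E) cycles; the reference gene's Ct is held
    constant across conditions.  Gaussian Ct noise of ``ct_noise_sd``
    cycles is added per well.

    Columns: sample, gene, ct, efficiency, is_reference, condition_id.
    """
    if efficiencies is None:
        efficiencies = {}
    rng = np.random.default_rng(seed)
    conditions = sorted(
        {control_condition_id}
        | {c for folds in true_fold_changes.values() for c in folds}
    )
    genes = sorted(true_fold_changes)
    eff_of = {g: float(efficiencies.get(g, 2.0)) for g in genes}
    eff_of[reference_gene] = float(efficiencies.get(reference_gene, 2.0))
    for g, e in eff_of.items():
        if not 1.0 < e <= 2.0:
            raise ValueError(f"amplification efficiency of {g} outside (1, 2]")

    rows = []
    for cond in conditions:
        for s in range(n_samples):
            sample_id = f"{cond}_s{s}"
            for gene in genes:
                fold = 1.0 if cond == control_condition_id else float(
                    true_fold_changes[gene][cond]
                )
                if fold <= 0:
                    raise ValueError("fold changes must be positive")
                ct = ct_target_control - np.log(fold) / np.log(eff_of[gene])
                if ct_noise_sd > 0:
                    ct += rng.normal(0, ct_noise_sd)
                rows.append(
                    {
                        "sample": sample_id,
                        "gene": gene,
                        "ct": float(ct),
                        "efficiency": eff_of[gene],
                        "is_reference": False,
                        "condition_id": cond,
                    }
                )
            ct_ref = ct_reference
            if ct_noise_sd > 0:
                ct_ref = ct_ref + rng.normal(0, ct_noise_sd)
            rows.append(
                {
                    "sample": sample_id,
                    "gene": reference_gene,
                    "ct": float(ct_ref),
                    "efficiency": eff_of[reference_gene],
                    "is_reference": True,
                    "condition_id": cond,
                }
            )
    return pd.DataFrame(rows)
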