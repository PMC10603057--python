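"""End-to-end pipeline: simulate -> piv -> tfm -> features -> phenotype -> qpcr.

A single PipelineConfig drives every stage with seeded randomness, so a
rerun with the same config and seed produces bit-identical outputs.
Each stage writes its artifacts under the output directory; a stage is
skipped on rerun when its cached result exists and the stored config
hash matches.  The final report bundles traction summaries, FA size
fractions, cell/nucleus morphometry, the Z/C/P matrices with cluster
labels, and qPCR fold changes into one machine-readable JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry, phenotype, piv, qpcr, synth, traction
from .core import STIFFNESS_PA, Condition, SubstrateModel, VectorField2D, full_design

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Parameters of every pipeline stage (YAML-compatible)."""

    seed: int = 0
    # --- simulate: traction scenes + bead images (one per stiffness level)
    grid_shape: tuple[int, int] = (128, 128)
    grid_spacing_um: float = 0.2
    n_patches: int = 8
    peak_traction_pa: float = 300.0
    poisson_ratio: float = 0.5
    bead_density_per_um2: float = 0.5
    bead_sigma_px: float = 1.5
    bead_noise_sd: float = 0.05
    # --- piv
    piv_window_px: int = 32
    piv_overlap: float = 0.5
    piv_outlier_threshold: float = 2.0
    # --- tfm
    regularization_lambda: float = 0.0
    # --- features
    fa_n: int = 40
    fa_image_shape: tuple[int, int] = (512, 512)
    fa_pixel_size_um: float = 0.1
    fa_snr: float = 10.0
    stack_cell_area_um2: float = 1000.0
    stack_cell_height_um: float = 5.0
    stack_nucleus_area_um2: float = 180.0
    stack_nucleus_height_um: float = 3.0
    # --- phenotype
    timepoints_h: tuple[int, ...] = (24, 48)
    n_replicates: int = 6
    control_stiffness: str = "E_P"
    control_ecm: str = "C_P"
    # --- qpcr
    qpcr_fold_changes: dict = field(
        default_factory=lambda: {"Vim": {"VimKO": 0.01}, "Acta2": {"VimKO": 0.5}}
    )
    qpcr_n_samples: int = 6

    def __post_init__(self) -> None:
        if self.control_stiffness not in STIFFNESS_PA:
            raise ValueError("control stiffness level unknown")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        self.grid_shape = tuple(self.grid_shape)  # type: ignore[assignment]
        self.fa_image_shape = tuple(self.fa_image_shape)  # type: ignore[assignment]
        self.timepoints_h = tuple(self.timepoints_h)  # type: ignore[assignment]

    def control_id(self, timepoint_h: int) -> str:
        return Condition(
            self.control_stiffness, self.control_ecm, "VimWT", timepoint_h
        ).condition_id

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _cached_stage(outdir: Path, stage: str, cfg_hash: str, fn) -> dict:
    """Run a stage, or reload its cached result when the config matches."""
    marker = outdir / f".{stage}.done"
    cache = outdir / f".stage_{stage}.json"
    if marker.exists() and marker.read_text().strip() == cfg_hash and cache.exists():
        return json.loads(cache.read_text())
    result = fn()
    cache.write_text(json.dumps(result, sort_keys=True))
    marker.write_text(cfg_hash)
    return result


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in dependency order; return the report dict.

    Also written to ``<outdir>/report.json``.  Intermediate artifacts:
    bead images (TIFF), displacement and traction grids (CSV), feature,
    property and qPCR tables (CSV), Z/C/P matrices (CSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    report: dict = {"config_hash": cfg_hash, "seed": int(config.seed)}
    report["tfm"] = _cached_stage(
        outdir, "tfm", cfg_hash, lambda: _stage_tfm(config, outdir)
    )
    report["features"] = _cached_stage(
        outdir, "features", cfg_hash, lambda: _stage_features(config, outdir)
    )
    report["phenotype"] = _cached_stage(
        outdir, "phenotype", cfg_hash, lambda: _stage_phenotype(config, outdir)
    )
    report["qpcr"] = _cached_stage(
        outdir, "qpcr", cfg_hash, lambda: _stage_qpcr(config, outdir)
    )
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    return report


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _stage_tfm(config: PipelineConfig, outdir: Path) -> dict:
    """Simulate a traction scene per stiffness level, run PIV + FTTC."""
    import tifffile

    results: dict = {}
    for i, (level, modulus) in enumerate(sorted(STIFFNESS_PA.items())):
        substrate = SubstrateModel(
            young_modulus_pa=modulus,
            poisson_ratio=config.poisson_ratio,
            pixel_size_um=config.grid_spacing_um,
        )
        scene_seed = int(config.seed) + 1000 * i
        scene = synth.make_traction_scene(
            grid_shape=config.grid_shape,
            grid_spacing_um=config.grid_spacing_um,
            n_patches=config.n_patches,
            peak_traction_pa=config.peak_traction_pa,
            substrate=substrate,
            seed=scene_seed,
        )
        disp_true = traction.forward_displacement(scene.truth_traction, substrate)
        ref_img, def_img = synth.render_bead_images(
            scene,
            disp_true,
            bead_density_per_um2=config.bead_density_per_um2,
            bead_sigma_px=config.bead_sigma_px,
            noise_sd=config.bead_noise_sd,
            seed=scene_seed + 1,
        )
        tifffile.imwrite(outdir / f"beads_{level}_reference.tif",
                         ref_img.intensity.astype(np.float32))
        tifffile.imwrite(outdir / f"beads_{level}_deformed.tif",
                         def_img.intensity.astype(np.float32))

        aligned = piv.align_to_reference(def_img, ref_img)
        disp = piv.compute_displacement(
            ref_img,
            aligned.aligned,
            window_px=config.piv_window_px,
            overlap_fraction=config.piv_overlap,
        )
        if min(disp.shape) >= 3:  # the filter needs an 8-neighborhood
            disp = piv.filter_outliers(
                disp, threshold=config.piv_outlier_threshold
            )
        _write_field(disp, outdir / f"displacement_{level}.csv")

        result = traction.solve_fttc(
            disp, substrate, lam=config.regularization_lambda
        )
        _write_field(result.traction, outdir / f"traction_{level}.csv")
        mask = _mask_on_piv_grid(scene.cell_mask, disp, config.grid_spacing_um)
        summary_pa = traction.traction_summary([result.magnitude_map], [mask])
        cell_area = float(scene.cell_mask.sum()) * config.grid_spacing_um**2
        results[level] = {
            "traction_pa": summary_pa,
            "traction_per_area_pa_um2": traction.traction_summary_normalized(
                summary_pa, cell_area
            ),
            "residual_norm_um": result.residual_norm,
            "drift_px": list(aligned.shift_px),
        }
    return results


def _stage_features(config: PipelineConfig, outdir: Path) -> dict:
    """FA segmentation + fractionation and 3D cell/nucleus morphometry."""
    import tifffile

    fa_img, fa_truth = synth.make_fa_image(
        image_shape=config.fa_image_shape,
        n_fas=config.fa_n,
        pixel_size_um=config.fa_pixel_size_um,
        intensity_snr=config.fa_snr,
        seed=int(config.seed) + 17,
    )
    tifffile.imwrite(outdir / "fa_image.tif", fa_img.astype(np.float32))
    fa_set = morphometry.segment_fas(fa_img, config.fa_pixel_size_um)
    fractions = morphometry.fractionate_fas(fa_set)
    stack = synth.make_cell_stack(
        cell_area_um2=config.stack_cell_area_um2,
        cell_height_um=config.stack_cell_height_um,
        nucleus_area_um2=config.stack_nucleus_area_um2,
        nucleus_height_um=config.stack_nucleus_height_um,
        seed=int(config.seed) + 18,
    )
    return {
        "fa_count_true": len(fa_truth),
        "fa_count_segmented": len(fa_set),
        "fa_fractions": {
            "small": fractions.proportions[0],
            "intermediate": fractions.proportions[1],
            "large": fractions.proportions[2],
        },
        "cell_area_um2": morphometry.measure_area(stack.cell, stack.voxel_size_um),
        "cell_height_um": morphometry.measure_height(stack.cell, stack.z_step_um),
        "nucleus_area_um2": morphometry.measure_area(
            stack.nucleus, stack.voxel_size_um
        ),
        "nucleus_height_um": morphometry.measure_height(
            stack.nucleus, stack.z_step_um
        ),
    }


def _stage_phenotype(config: PipelineConfig, outdir: Path) -> dict:
    """Property tables -> Z / C / P -> clustering, per timepoint."""
    model = synth.default_effect_model(n_replicates=config.n_replicates)
    out: dict = {}
    for t in config.timepoints_h:
        table = synth.make_property_table(
            model, full_design(t), seed=int(config.seed) + 100 + t
        )
        table.to_csv(outdir / f"properties_{t}h.csv", index=False)
        z = phenotype.compute_zmatrix(table, config.control_id(t))
        c = phenotype.cosine_similarity_matrix(z, axis="conditions")
        p = phenotype.cosine_similarity_matrix(z, axis="properties")
        cond_clusters = phenotype.cluster_similarity(c, k="auto")
        prop_clusters = phenotype.cluster_similarity(p, k="auto")
        z_ordered = phenotype.reorder_zmatrix(z, cond_clusters, prop_clusters)
        z.values.to_csv(outdir / f"zmatrix_{t}h.csv")
        c.values.to_csv(outdir / f"similarity_conditions_{t}h.csv")
        p.values.to_csv(outdir / f"similarity_properties_{t}h.csv")
        z_ordered.values.to_csv(outdir / f"zmatrix_ordered_{t}h.csv")
        out[f"{t}h"] = {
            "condition_clusters": {
                item: int(lab)
                for item, lab in zip(cond_clusters.items, cond_clusters.labels)
            },
            "property_clusters": {
                item: int(lab)
                for item, lab in zip(prop_clusters.items, prop_clusters.labels)
            },
            "k_conditions": cond_clusters.k,
            "k_properties": prop_clusters.k,
        }
    return out


def _stage_qpcr(config: PipelineConfig, outdir: Path) -> dict:
    """Ct table generation and Pfaffl relative expression."""
    folds = {
        gene: dict(per_cond)
        for gene, per_cond in config.qpcr_fold_changes.items()
    }
    ct_table = synth.make_qpcr_dataset(
        folds,
        n_samples=config.qpcr_n_samples,
        ct_noise_sd=0.15,
        seed=int(config.seed) + 23,
        control_condition_id="VimWT",
    )
    ct_table.to_csv(outdir / "qpcr_ct.csv", index=False)
    _, summary = qpcr.relative_expression(ct_table, "VimWT")
    summary.to_csv(outdir / "qpcr_expression.csv", index=False)
    return {
        f"{row['gene']}:{row['condition_id']}": {
            "mean": float(row["mean"]),
            "sem": float(row["sem"]),
        }
        for _, row in summary.iterrows()
    }


# --------------------------------------------------------------------------
# Helpers
# --------------------------------------------------------------------------

def _write_field(field_: VectorField2D, path: Path) -> None:
    ny, nx = field_.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    pd.DataFrame(
        {
            "x_um": (xs * field_.spacing_um + field_.origin_um[1]).ravel(),
            "y_um": (ys * field_.spacing_um + field_.origin_um[0]).ravel(),
            "u": field_.u.ravel(),
            "v": field_.v.ravel(),
            "valid": field_.valid.ravel(),
        }
    ).to_csv(path, index=False)


def _mask_on_piv_grid(mask, disp_field: VectorField2D, px_um: float) -> np.ndarray:
    """Sample the pixel-grid cell mask at the PIV vector positions."""
    ny, nx = disp_field.shape
    oy, ox = disp_field.origin_um
    ys = np.clip(
        np.round((oy + np.arange(ny) * disp_field.spacing_um) / px_um).astype(int),
        0, mask.shape[0] - 1,
    )
    xs = np.clip(
        np.round((ox + np.arange(nx) * disp_field.spacing_um) / px_um).astype(int),
        0, mask.shape[1] - 1,
    )
    return mask[np.ix_(ys, xs)]
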