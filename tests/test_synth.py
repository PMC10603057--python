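"""Synthetic-data generators: traction scenes, bead images, FA images,
3D stacks, property tables and qPCR Ct tables."""

import numpy as np
import pandas as pd
import pytest

from mechphen.core import Condition, SubstrateModel, control_condition, full_design
from mechphen.synth import (
    EffectModel,
    PropertyEffect,
    default_effect_model,
    make_cell_stack,
    make_fa_image,
    make_property_table,
    make_qpcr_dataset,
    make_traction_scene,
    render_bead_images,
)
from mechphen.traction import forward_displacement


class TestConditions:
    def test_design_enumerates_eight_combinations(self):
        design = full_design(24)
        assert len(design) == 8
        assert len({c.condition_id for c in design}) == 8

    def test_levels_map_to_physical_values(self):
        c = Condition("E_H", "C_P", "VimKO", 48)
        assert c.modulus_pa == 27_000.0
        assert c.coating_ug_ml == 25.0
        assert c.condition_id == "E_H-C_P-VimKO-48h"
        assert control_condition(24).condition_id == "E_P-C_P-VimWT-24h"

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            Condition("E_X", "C_P", "VimWT")
        with pytest.raises(ValueError):
            SubstrateModel(-5.0)
        with pytest.raises(ValueError):
            SubstrateModel(1000.0, poisson_ratio=0.7)


class TestTractionScene:
    def test_zero_patches_rejected(self):
        with pytest.raises(ValueError):
            make_traction_scene(n_patches=0)

    def test_force_balance_and_mask_support(self):
        scene = make_traction_scene(grid_shape=(96, 96), seed=13)
        t = scene.truth_traction
        norm = np.sum(t.magnitude())
        assert np.abs(t.net_vector()).max() <= 1e-9 * norm
        assert np.all(t.u[~scene.cell_mask] == 0)
        assert np.all(t.v[~scene.cell_mask] == 0)

    def test_same_seed_bit_identical(self):
        a = make_traction_scene(seed=42)
        b = make_traction_scene(seed=42)
        assert np.array_equal(a.truth_traction.u, b.truth_traction.u)
        assert np.array_equal(a.truth_traction.v, b.truth_traction.v)
        assert np.array_equal(a.cell_mask, b.cell_mask)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_traction_scene(grid_shape=(16, 16))


@pytest.fixture(scope="module")
def scene():
    return make_traction_scene(grid_shape=(96, 96), seed=1)


class TestBeadImages:

    def test_zero_displacement_identity(self, scene):
        zero = scene.truth_traction.copy()
        zero.u[:] = 0
        zero.v[:] = 0
        ref, de = render_bead_images(scene, zero, noise_sd=0.0, seed=5)
        assert np.array_equal(ref.intensity, de.intensity)

    def test_uniform_shift_matches_translation_oracle(self, scene):
        """A uniform 3 px displacement renders the reference translated
        by 3 px (interior pixels)."""
        shift = scene.truth_traction.copy()
        shift.u[:] = 3.0 * shift.spacing_um  # 3 px in x
        shift.v[:] = 0.0
        ref, de = render_bead_images(scene, shift, noise_sd=0.0, seed=5)
        expected = np.zeros_like(ref.intensity)
        expected[:, 3:] = ref.intensity[:, :-3]
        interior = np.s_[10:-10, 10:-10]
        assert np.allclose(de.intensity[interior], expected[interior], atol=1e-8)

    def test_same_seed_same_beads(self, scene):
        zero = scene.truth_traction.copy()
        zero.u[:] = 0
        zero.v[:] = 0
        r1, _ = render_bead_images(scene, zero, seed=9)
        r2, _ = render_bead_images(scene, zero, seed=9)
        assert np.array_equal(r1.intensity, r2.intensity)

    def test_unrecoverable_displacement_rejected(self, scene):
        huge = scene.truth_traction.copy()
        huge.u[:] = scene.truth_traction.shape[1] * huge.spacing_um
        with pytest.raises(ValueError, match="quarter"):
            render_bead_images(scene, huge, seed=0)


class TestFAImage:
    def test_empty_image_for_zero_fas(self):
        img, truth = make_fa_image(n_fas=0, seed=0)
        assert truth == []
        assert img.shape == (512, 512)

    def test_truth_areas_are_pixel_counts(self):
        _, truth = make_fa_image(n_fas=15, pixel_size_um=0.1, seed=3)
        for t in truth:
            assert t["area_um2"] == pytest.approx(t["area_px"] * 0.01)

    def test_fixed_seed_identical_truth(self):
        _, t1 = make_fa_image(n_fas=10, seed=8)
        _, t2 = make_fa_image(n_fas=10, seed=8)
        assert t1 == t2

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError, match="overlap"):
            make_fa_image(image_shape=(48, 48), n_fas=500, seed=0,
                          max_placement_tries=10)


class TestCellStack:
    def test_projected_area_matches_request(self):
        st = make_cell_stack(cell_area_um2=1000.0, voxel_size_um=0.5, seed=2)
        proj = st.cell.any(axis=0)
        assert proj.sum() * 0.25 == pytest.approx(1000.0, abs=0.25)

    def test_heights_match_requested_slices(self):
        st = make_cell_stack(cell_height_um=5.0, nucleus_height_um=3.0,
                             z_step_um=0.5, seed=1)
        assert st.cell.any(axis=(1, 2)).sum() == 10
        assert st.nucleus.any(axis=(1, 2)).sum() == 6

    def test_single_slice_stack(self):
        st = make_cell_stack(z_steps=1, cell_height_um=0.5,
                             nucleus_height_um=0.5, z_step_um=0.5, seed=0)
        assert st.cell.shape[0] == 1

    def test_nucleus_taller_than_cell_rejected(self):
        with pytest.raises(ValueError, match="height"):
            make_cell_stack(cell_height_um=3.0, nucleus_height_um=4.0)

    def test_unrepresentable_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_cell_stack(cell_height_um=50.0, z_steps=20, z_step_um=0.5)
        with pytest.raises(ValueError):
            make_cell_stack(cell_area_um2=1e9)


class TestPropertyTable:
    def test_requires_control_condition(self):
        design = [Condition("E_H", "C_H", "VimKO", 24)]
        with pytest.raises(ValueError, match="control"):
            make_property_table(design=design)

    def test_zero_sd_reproduces_effect_model_exactly(self):
        model = EffectModel(
            properties={
                "traction": PropertyEffect("cell mechanics", 100.0, 0.0,
                                           genotype_mult=0.5)
            }
        )
        table = make_property_table(model, full_design(24), seed=0)
        means = table.groupby("genotype")["value"].mean()
        assert means["VimKO"] == pytest.approx(50.0)
        assert means["VimWT"] == pytest.approx(100.0)

    def test_all_unit_multipliers_give_control_means_everywhere(self):
        model = EffectModel(
            properties={"p": PropertyEffect("cell mechanics", 10.0, 0.0)}
        )
        table = make_property_table(model, full_design(24), seed=0)
        assert (table["value"] == 10.0).all()

    def test_default_model_structure(self):
        table = make_property_table(seed=0)
        assert set(table["category"]) == {
            "cellular morphology",
            "nuclear morphology",
            "cell mechanics",
            "cell migration",
            "cell-matrix interactions",
        }
        assert table.groupby(["condition_id", "property"]).size().eq(6).all()

    def test_same_seed_identical_table(self):
        a = make_property_table(seed=3)
        b = make_property_table(seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestQpcrDataset:
    def test_two_fold_change_shifts_ct_by_one_cycle(self):
        tbl = make_qpcr_dataset({"Vim": {"ko": 2.0}}, ct_noise_sd=0,
                                n_samples=2, seed=0)
        tgt = tbl[~tbl["is_reference"]]
        ct_ctrl = tgt.loc[tgt["condition_id"] == "control", "ct"].iloc[0]
        ct_ko = tgt.loc[tgt["condition_id"] == "ko", "ct"].iloc[0]
        assert ct_ctrl - ct_ko == pytest.approx(1.0)

    def test_reference_ct_constant_across_conditions(self):
        tbl = make_qpcr_dataset({"Vim": {"ko": 3.0}}, ct_noise_sd=0, seed=0)
        ref = tbl[tbl["is_reference"]]
        assert ref["ct"].nunique() == 1

    def test_efficiency_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            make_qpcr_dataset({"Vim": {"ko": 2.0}},
                              efficiencies={"Vim": 2.5}, seed=0)
        with pytest.raises(ValueError, match="efficiency"):
            make_qpcr_dataset({"Vim": {"ko": 2.0}},
                              efficiencies={"Vim": 1.0}, seed=0)


def test_default_effect_model_control_is_neutral():
    model = default_effect_model()
    ctrl = control_condition(24)
    for prop, eff in model.properties.items():
        assert model.mean_value(ctrl, prop) == eff.baseline
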