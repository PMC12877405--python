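"""Mitochondrial morphology, intensity, and membrane-potential readout tests."""

import numpy as np
import pytest
from skimage import measure

from stretchquant import synthetic as syn
from stretchquant.mitochondria import (
    jc1_ratio,
    mitotracker_intensity,
    postprocess_cell_mask,
    remove_small_regions,
    skeleton_length,
    tomm20_segment_plane,
    tomm20_stats,
)


class TestTomm20Segmentation:
    def test_blank_plane_gives_empty_mask_and_skeleton(self):
        mask, skel = tomm20_segment_plane(np.zeros((64, 64)))
        assert not mask.any() and not skel.any()

    def test_straight_branch_single_object_and_length(self):
        stack, truth = syn.make_mito_scene(
            1, branch_length_law=("uniform", 100.0, 100.0), curliness=0.0,
            heading=0.0, seed=5,
        )
        mask, skel = tomm20_segment_plane(stack.plane("tomm20"))
        assert measure.label(skel, connectivity=2).max() == 1
        assert skeleton_length(skel) == pytest.approx(100.0, abs=4.0)

    def test_skeleton_is_subset_of_mask_and_idempotent(self):
        from skimage import morphology as sm

        stack, _ = syn.make_mito_scene(8, seed=2)
        mask, skel = tomm20_segment_plane(stack.plane("tomm20"))
        assert not (skel & ~mask).any()
        assert np.array_equal(sm.skeletonize(skel), skel)

    @pytest.mark.parametrize("noisy", [False, True])
    def test_branch_count_recovered_within_10pct(self, noisy):
        stack, truth = syn.make_mito_scene(20, seed=3)
        if noisy:
            stack = syn.apply_noise(stack, **syn.DEFAULT_NOISE, seed=93)
        _, skel = tomm20_segment_plane(stack.plane("tomm20"))
        n = measure.label(skel, connectivity=2).max()
        assert abs(n - 20) <= 2


class TestTomm20Stats:
    def test_per_cell_arithmetic_across_planes(self):
        stack, truth = syn.make_mito_scene(12, n_planes=3, seed=6)
        masks = stack.channel("actin") > 0
        morph = tomm20_stats(stack, masks, n_cells=2)
        counts = [n for n, _ in morph.per_plane]
        assert len(morph.per_plane) == 3
        assert morph.objects_per_cell == pytest.approx(np.mean(counts) / 2)
        assert 0 <= morph.mean_area_normalized <= 1

    def test_empty_stack_yields_zeros(self):
        from stretchquant.imgio import ImageStack

        stack = ImageStack(np.zeros((2, 2, 64, 64)), ("tomm20", "actin"), 0.183)
        morph = tomm20_stats(stack, np.ones((2, 64, 64), dtype=bool), n_cells=3)
        assert morph.objects_per_cell == 0.0
        assert morph.mean_area_normalized == 0.0

    def test_bad_cell_count_rejected(self):
        stack, _ = syn.make_mito_scene(1, seed=0)
        with pytest.raises(ValueError):
            tomm20_stats(stack, stack.channel("actin") > 0, n_cells=0)


class TestMitoTracker:
    def test_corrected_intensity_matches_truth_within_2pct(self):
        stack, truth = syn.make_cell_scene(seed=2)
        ref = (
            truth.generative_params["amplitude"]
            - truth.generative_params["background"]
        )
        res = mitotracker_intensity(stack)
        assert res.corrected_intensity == pytest.approx(ref, rel=0.02)

    def test_invariant_to_global_additive_offset(self):
        stack, _ = syn.make_cell_scene(seed=4)
        base = mitotracker_intensity(stack).corrected_intensity
        shifted = mitotracker_intensity(
            stack.with_planes(stack.planes + 37.0)
        ).corrected_intensity
        assert shifted == pytest.approx(base, abs=1e-6)

    @pytest.mark.parametrize(
        "dims,kept", [((27, 37), False), ((25, 40), True)]  # 999 px vs 1000 px
    )
    def test_small_object_boundary_inclusive_retain(self, dims, kept):
        mask = np.zeros((300, 300), dtype=bool)
        mask[50 : 50 + dims[0], 50 : 50 + dims[1]] = True
        assert dims[0] * dims[1] in (999, 1000)
        assert remove_small_regions(mask).any() == kept

    def test_postprocess_keeps_large_and_drops_speckle(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[40:140, 40:140] = True  # 10,000 px cell
        mask[200, 200] = True  # isolated speckle
        out = postprocess_cell_mask(mask)
        assert out[90, 90] and not out[200, 200]

    def test_control_normalisation(self):
        stack, _ = syn.make_cell_scene(seed=2)
        res = mitotracker_intensity(stack, control_mean=125.0)
        assert res.normalized == pytest.approx(res.corrected_intensity / 125.0)

    def test_constant_stack_is_an_error(self):
        from stretchquant.imgio import ImageStack

        flat = ImageStack(np.full((1, 3, 300, 300), 50.0), ("mitotracker",), 0.18)
        with pytest.raises(ValueError):
            mitotracker_intensity(flat)


class TestJc1:
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.5])
    def test_generated_ratio_recovered_within_2pct(self, ratio):
        stack, _ = syn.make_jc1_scene(ratio, seed=3)
        assert jc1_ratio(stack).red_green_ratio == pytest.approx(ratio, rel=0.02)

    def test_identical_channels_give_unit_ratio(self):
        stack, _ = syn.make_jc1_scene(1.0, seed=7)
        assert jc1_ratio(stack).red_green_ratio == pytest.approx(1.0, rel=1e-9)

    def test_scale_invariance(self):
        stack, _ = syn.make_jc1_scene(2.0, seed=4)
        r1 = jc1_ratio(stack).red_green_ratio
        r2 = jc1_ratio(stack.with_planes(stack.planes * 7.3)).red_green_ratio
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_monotone_dose_response(self):
        measured = [
            jc1_ratio(syn.make_jc1_scene(r, seed=5)[0]).red_green_ratio
            for r in (0.5, 1.0, 2.0, 4.0)
        ]
        assert measured == sorted(measured)
        assert measured[0] < measured[-1]

    def test_blank_scene_is_an_error(self):
        from stretchquant.imgio import ImageStack

        blank = ImageStack(
            np.zeros((2, 3, 64, 64)), ("jc1_red", "jc1_green"), 0.721
        )
        with pytest.raises(ValueError):
            jc1_ratio(blank)
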