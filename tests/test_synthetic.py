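"""Ground-truth consistency and determinism of the scene generators."""

import numpy as np
import pytest

from stretchquant import synthetic as syn


@pytest.mark.parametrize(
    "maker,kwargs",
    [
        (syn.make_fiber_scene, dict(n_fibers=40)),
        (syn.make_puncta_scene, dict(n_spots=8, cluster_pairs=2)),
        (syn.make_adhesion_scene, dict(n_pairs=4, image_shape=(300, 300))),
        (syn.make_mito_scene, dict(n_branches=6, image_shape=(200, 200))),
        (syn.make_jc1_scene, dict(red_green_ratio=2.0)),
        (syn.make_cell_scene, dict(n_cells=2, image_shape=(300, 300))),
    ],
)
def test_generators_are_deterministic_under_fixed_seed(maker, kwargs):
    s1, t1 = maker(**kwargs, seed=42)
    s2, t2 = maker(**kwargs, seed=42)
    assert np.array_equal(s1.planes, s2.planes)
    assert t1.objects == t2.objects
    s3, _ = maker(**kwargs, seed=43)
    assert not np.array_equal(s1.planes, s3.planes)


class TestFiberScene:
    def test_empty_scene(self):
        stack, truth = syn.make_fiber_scene(0, seed=0)
        assert stack.channel("actin").max() == 0
        assert truth.objects == []

    def test_fixed_law_records_exact_angles(self):
        _, truth = syn.make_fiber_scene(50, ("fixed", 30.0), seed=1)
        angles = [o["angle_folded_deg"] for o in truth.of_kind("fiber")]
        assert angles == [30.0] * 50

    def test_uniform_law_truth_mean_near_45(self):
        _, truth = syn.make_fiber_scene(500, "uniform", seed=7)
        folded = np.array([o["angle_folded_deg"] for o in truth.of_kind("fiber")])
        se = folded.std(ddof=1) / np.sqrt(folded.size)
        assert abs(folded.mean() - 45.0) < 3 * se + 1e-9

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            syn.make_fiber_scene(1, image_shape=(2, 100), fiber_width=3.0, seed=0)


class TestPunctaScene:
    def test_blank_spots_with_nuclei(self):
        stack, truth = syn.make_puncta_scene(0, n_nuclei=3, seed=0)
        assert stack.channel("lc3b").max() == 0
        assert len(truth.of_kind("nucleus")) == 3
        assert truth.of_kind("punctum") == []

    def test_cluster_pairs_are_touching_dumbbells(self):
        stack, truth = syn.make_puncta_scene(8, cluster_pairs=4, seed=3)
        puncta = truth.of_kind("punctum")
        assert len(puncta) == 8
        ref = truth.generative_params["reference_threshold"]
        from skimage import measure

        n_comp = measure.label(
            stack.plane("lc3b") > ref, connectivity=2
        ).max()
        assert n_comp == 4  # each pair fused into one component

    def test_rendered_area_truth_is_exact(self):
        stack, truth = syn.make_puncta_scene(5, seed=2)
        ref = truth.generative_params["reference_threshold"]
        total_truth = sum(o["area_at_threshold_px"] for o in truth.of_kind("punctum"))
        assert total_truth == int((stack.plane("lc3b") > ref).sum())

    def test_peak_recovers_nominal_amplitude(self):
        stack, truth = syn.make_puncta_scene(5, seed=2, amplitude=150.0)
        assert stack.channel("lc3b").max() == pytest.approx(150.0, rel=0.01)

    def test_infeasible_packing_fails_loudly(self):
        with pytest.raises(syn.PackingError):
            syn.make_puncta_scene(500, image_shape=(64, 64), seed=0)


class TestAdhesionScene:
    @pytest.mark.parametrize("overlap", [4, 5])
    def test_pairwise_overlap_is_exact(self, overlap):
        stack, truth = syn.make_adhesion_scene(n_pairs=6, overlap_px=overlap, seed=2)
        pairs = truth.of_kind("adhesion_pair")
        assert len(pairs) == 6
        assert all(p["overlap_px"] == overlap for p in pairs)
        thr = truth.generative_params["render_threshold"]
        a = stack.plane("pxn") > thr
        b = stack.plane("vcl") > thr
        assert int((a & b).sum()) == 6 * overlap

    def test_union_bounds_and_lone_spots(self):
        _, truth = syn.make_adhesion_scene(
            n_pairs=0, n_lone_pxn=10, seed=1, image_shape=(400, 400)
        )
        assert truth.of_kind("adhesion_pair") == []
        assert len(truth.of_kind("lone_pxn")) == 10
        _, truth = syn.make_adhesion_scene(n_pairs=5, seed=1)
        for p in truth.of_kind("adhesion_pair"):
            assert p["union_area_px"] >= max(p["pxn_area_px"], p["vcl_area_px"])
            assert p["union_area_px"] == p["pxn_area_px"] + p["vcl_area_px"] - p["overlap_px"]

    def test_overlap_larger_than_spot_rejected(self):
        with pytest.raises(ValueError):
            syn.make_adhesion_scene(n_pairs=1, overlap_px=300, spot_area_px=250, seed=0)


class TestMitoScene:
    def test_blank_scene(self):
        stack, truth = syn.make_mito_scene(0, seed=0)
        assert stack.channel("tomm20").max() == 0
        assert truth.of_kind("mito_branch") == []

    def test_straight_branch_skeleton_length_oracle(self):
        from skimage import morphology as sm
        from stretchquant.mitochondria import skeleton_length

        stack, truth = syn.make_mito_scene(
            1, branch_length_law=("uniform", 80.0, 80.0), curliness=0.0,
            heading=0.0, seed=4,
        )
        branch = truth.objects[0]
        assert branch["path_length_px"] == pytest.approx(80.0)
        skel = sm.skeletonize(stack.plane("tomm20") > 0)
        # skeletonization trims roughly one branch-width from the rendered ends
        assert skeleton_length(skel) == pytest.approx(80.0 - 5.0, abs=6.0)

    def test_branch_masks_never_touch(self):
        from skimage import measure

        stack, truth = syn.make_mito_scene(20, seed=3)
        fg = (stack.channel("tomm20") > 0).any(axis=0)
        assert measure.label(fg, connectivity=2).max() == 20
        assert truth.generative_params["total_foreground_px"] == int(
            (stack.channel("tomm20") > 0).sum()
        )


class TestJc1Scene:
    def test_ratio_one_means_identical_channels(self):
        stack, _ = syn.make_jc1_scene(1.0, seed=0)
        assert np.array_equal(stack.channel("jc1_red"), stack.channel("jc1_green"))

    def test_noiseless_foreground_ratio_is_exact(self):
        stack, _ = syn.make_jc1_scene(2.5, seed=1)
        green = stack.channel("jc1_green")
        fg = green > 0
        ratio = stack.channel("jc1_red")[fg].mean() / green[fg].mean()
        assert ratio == pytest.approx(2.5, rel=1e-12)

    def test_noisy_generator_side_ratio_within_2pct(self):
        stack, _ = syn.make_jc1_scene(2.5, seed=1)
        fg = stack.channel("jc1_green") > 20
        noisy = syn.apply_noise(stack, photon_scale=5.0, read_noise_sd=1.0,
                                background_offset=0.0, seed=9)
        ratio = noisy.channel("jc1_red")[fg].mean() / noisy.channel("jc1_green")[fg].mean()
        assert ratio == pytest.approx(2.5, rel=0.02)


class TestNoiseModel:
    def test_noise_free_limit_is_identity(self):
        stack, _ = syn.make_puncta_scene(4, seed=0)
        out = syn.apply_noise(stack, photon_scale=1e7, read_noise_sd=0.0,
                              background_offset=0.0, seed=1)
        assert np.allclose(out.planes, stack.planes, atol=0.05)

    def test_fixed_seed_reproducible(self):
        stack, _ = syn.make_puncta_scene(4, seed=0)
        o1 = syn.apply_noise(stack, seed=5)
        o2 = syn.apply_noise(stack, seed=5)
        assert np.array_equal(o1.planes, o2.planes)

    def test_variance_matches_moment_prediction(self):
        from stretchquant.imgio import ImageStack

        const = ImageStack(np.full((1, 1, 1000, 1000), 40.0), ("lc3b",), 0.071)
        out = syn.apply_noise(const, photon_scale=2.0, read_noise_sd=3.0,
                              background_offset=0.0, seed=2)
        predicted = 40.0 / 2.0 + 3.0**2
        assert out.planes.var() == pytest.approx(predicted, rel=0.05)

    def test_invalid_parameters(self):
        stack, _ = syn.make_puncta_scene(1, seed=0)
        with pytest.raises(ValueError):
            syn.apply_noise(stack, photon_scale=0.0)
        with pytest.raises(ValueError):
            syn.apply_noise(stack, read_noise_sd=-1.0)
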