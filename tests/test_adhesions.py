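"""Focal-adhesion detection, colocalization, and measurement tests."""

import numpy as np
import pytest

from stretchquant import synthetic as syn
from stretchquant.adhesions import (
    adhesion_metrics,
    background_peak_threshold,
    build_adhesions,
    cell_mask,
    channel_spots,
    local_zscore,
    mutual_overlap_filter,
    spots_from_binary,
)
from stretchquant.imgio import max_project


class TestBackgroundPeakThreshold:
    def test_gaussian_mixture_matches_fwhm_closed_form(self, rng):
        """Background N(100, 10): threshold = 100 + 0.2 * 2.355 * 10 ~ 104.7."""
        img = np.concatenate(
            [rng.normal(100, 10, 900_000), rng.normal(200, 10, 100_000)]
        ).reshape(1000, 1000)
        thr = background_peak_threshold(img)
        assert thr == pytest.approx(100 + 0.2 * 2.355 * 10, abs=1.0)

    def test_single_symmetric_peak_ordering(self, rng):
        img = rng.normal(50, 5, 250_000).reshape(500, 500)
        thr = background_peak_threshold(img)
        # beyond the peak but below the right-flank half-max point
        assert 50.0 < thr < 50.0 + 2.355 * 5 / 2

    def test_two_level_image_threshold_separates_levels(self):
        img = np.full((100, 100), 10.0)
        img[:20] = 200.0
        assert 10.0 < background_peak_threshold(img) < 200.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="single gray level"):
            background_peak_threshold(np.full((50, 50), 3.0))


class TestCellMask:
    def test_plateau_fully_covered_and_background_mostly_excluded(self, rng):
        """The mask's contract downstream: never lose cell area to the
        threshold (spots are only searched in-mask), and reject the bulk of
        the empty background."""
        img = rng.normal(100, 2, (300, 300))
        truth = np.zeros((300, 300), dtype=bool)
        truth[60:240, 40:240] = True  # 40% of the frame
        img[truth] = rng.normal(200, 2, truth.sum())
        mask = cell_mask(img)
        assert (mask & truth).sum() / truth.sum() >= 0.99
        assert (mask & ~truth).sum() / (~truth).sum() < 0.5

    def test_uniformly_bright_image_is_all_cell(self):
        assert cell_mask(np.full((64, 64), 120.0)).all()

    def test_blank_image_surfaces_degenerate_histogram(self):
        with pytest.raises(ValueError, match="blank"):
            cell_mask(np.zeros((64, 64)))


class TestChannelSpots:
    def test_flat_image_has_no_spots(self):
        img = np.full((128, 128), 30.0)
        assert channel_spots(img, np.ones_like(img, dtype=bool)).count == 0

    def test_zero_variance_window_yields_zero_zscore(self):
        z = local_zscore(np.full((64, 64), 5.0))
        assert np.all(z == 0.0)

    @pytest.mark.parametrize("area,expected", [(100, 0), (101, 1)])
    def test_area_filter_is_strictly_greater(self, blob, area, expected):
        """'Area exceeded 100 pixels' is strict: 100 px rejected, 101 kept."""
        binary = blob((64, 64), (32, 32), area)
        assert spots_from_binary(binary).count == expected

    def test_synthetic_blob_detected_inside_mask(self):
        stack, _ = syn.make_adhesion_scene(n_pairs=2, overlap_px=30, seed=4)
        pxn = max_project(stack, "pxn")
        spots = channel_spots(pxn, cell_mask(pxn))
        assert spots.count == 2

    def test_mask_must_be_congruent(self):
        with pytest.raises(ValueError, match="congruent"):
            channel_spots(np.zeros((32, 32)), np.ones((16, 16), dtype=bool))


class TestMutualOverlapFilter:
    @pytest.mark.parametrize("overlap,kept", [(5, 6), (4, 0)])
    def test_five_pixel_boundary_is_inclusive(self, overlap, kept):
        stack, truth = syn.make_adhesion_scene(n_pairs=6, overlap_px=overlap, seed=2)
        thr = truth.generative_params["render_threshold"]
        sa = spots_from_binary(max_project(stack, "pxn") > thr)
        sb = spots_from_binary(max_project(stack, "vcl") > thr)
        ra, rb = mutual_overlap_filter(sa, sb, min_overlap_px=5)
        assert ra.count == kept and rb.count == kept

    def test_lone_spot_rejected(self):
        stack, truth = syn.make_adhesion_scene(
            n_pairs=2, overlap_px=20, n_lone_pxn=3, seed=6
        )
        thr = truth.generative_params["render_threshold"]
        sa = spots_from_binary(max_project(stack, "pxn") > thr)
        sb = spots_from_binary(max_project(stack, "vcl") > thr)
        assert sa.count == 5
        ra, rb = mutual_overlap_filter(sa, sb)
        assert ra.count == 2 and rb.count == 2

    def test_overlap_counted_per_partner_not_pooled(self):
        """Two 4-px overlaps with different partners do not add up to pass 5."""
        a = np.zeros((80, 80), dtype=bool)
        a[20:23, 5:75] = True  # one long bar, 210 px
        b1 = np.zeros((80, 80), dtype=bool)
        b1[22:53, 10:14] = True  # 124 px, overlaps bar on row 22 only: 4 px
        b2 = np.zeros((80, 80), dtype=bool)
        b2[22:53, 60:64] = True  # second partner, another 4 px
        sa = spots_from_binary(a, min_area_px=100)
        sb = spots_from_binary(b1 | b2, min_area_px=100)
        assert sa.count == 1 and sb.count == 2
        assert int((a & b1).sum()) == 4 and int((a & b2).sum()) == 4
        ra, rb = mutual_overlap_filter(sa, sb, min_overlap_px=5)
        assert ra.count == 0 and rb.count == 0
        # pooled counting would have kept the bar (4 + 4 >= 5)
        ra, rb = mutual_overlap_filter(sa, sb, min_overlap_px=4)
        assert ra.count == 1 and rb.count == 2


class TestBuildAdhesions:
    def test_inclusion_exclusion_on_constructed_masks(self, blob):
        a = np.zeros((80, 80), dtype=bool)
        a[30:36, 10:35] = True  # 150 px
        b = np.zeros((80, 80), dtype=bool)
        b[30:36, 30:50] = True  # 120 px, overlap = 6 x 5 = 30 px
        sa = spots_from_binary(a)
        sb = spots_from_binary(b)
        table = build_adhesions(sa, sb)
        assert len(table) == 1
        rec = table.adhesions.iloc[0]
        assert rec["pxn_area_px"] == 150
        assert rec["vcl_area_px"] == 120
        assert rec["union_area_px"] == 150 + 120 - 30

    def test_components_missing_a_channel_are_dropped(self):
        a = np.zeros((60, 60), dtype=bool)
        a[5:16, 5:16] = True
        b = np.zeros((60, 60), dtype=bool)
        b[40:51, 40:51] = True
        table = build_adhesions(spots_from_binary(a), spots_from_binary(b))
        assert len(table) == 0

    def test_orientation_recovered_from_superellipse_pairs(self):
        stack, truth = syn.make_adhesion_scene(
            n_pairs=8, overlap_px=40, orientation_law="uniform", seed=9
        )
        thr = truth.generative_params["render_threshold"]
        sa = spots_from_binary(max_project(stack, "pxn") > thr)
        sb = spots_from_binary(max_project(stack, "vcl") > thr)
        table = build_adhesions(*mutual_overlap_filter(sa, sb))
        assert len(table) == 8
        meas = np.sort(table.adhesions["orientation_deg"].to_numpy())
        true = np.sort([p["angle_folded_deg"] for p in truth.of_kind("adhesion_pair")])
        assert np.all(np.abs(meas - true) <= 3.0)


class TestAdhesionMetrics:
    def _table(self, overlap=30, n_pairs=4, seed=3):
        stack, truth = syn.make_adhesion_scene(n_pairs=n_pairs, overlap_px=overlap, seed=seed)
        thr = truth.generative_params["render_threshold"]
        sa = spots_from_binary(max_project(stack, "pxn") > thr)
        sb = spots_from_binary(max_project(stack, "vcl") > thr)
        return build_adhesions(*mutual_overlap_filter(sa, sb))

    def test_summary_arithmetic(self):
        table = self._table()
        summary, dist = adhesion_metrics(table, n_cells=2)
        t = table.adhesions
        px2 = table.pixel_size_um**2
        assert summary["mean_fa_area_um2"] == pytest.approx(
            t["union_area_px"].mean() * px2
        )
        assert summary["fa_per_cell"] == len(t) / 2
        assert summary["pxn_coverage_fraction"] == pytest.approx(
            t["pxn_area_px"].sum() / t["union_area_px"].sum()
        )
        assert dist.n_units == len(t)

    def test_coverage_fractions_in_unit_interval(self):
        summary, _ = adhesion_metrics(self._table(overlap=60, seed=5), n_cells=3)
        assert 0 < summary["pxn_coverage_fraction"] <= 1
        assert 0 < summary["vcl_coverage_fraction"] <= 1

    def test_full_coverage_limit(self, blob):
        a = np.zeros((60, 60), dtype=bool)
        a[20:35, 10:40] = True
        table = build_adhesions(spots_from_binary(a), spots_from_binary(a))
        summary, _ = adhesion_metrics(table, n_cells=1)
        assert summary["pxn_coverage_fraction"] == 1.0


class TestMonotonicity:
    def test_raising_min_overlap_never_increases_fa_count(self):
        stack, truth = syn.make_adhesion_scene(n_pairs=6, overlap_px=12, seed=7)
        thr = truth.generative_params["render_threshold"]
        sa = spots_from_binary(max_project(stack, "pxn") > thr)
        sb = spots_from_binary(max_project(stack, "vcl") > thr)
        counts = [
            len(build_adhesions(*mutual_overlap_filter(sa, sb, k)))
            for k in (1, 5, 12, 13, 40)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[2] == 6 and counts[3] == 0

    def test_raising_min_area_never_increases_spot_count(self):
        stack, _ = syn.make_adhesion_scene(n_pairs=5, overlap_px=20, seed=8)
        pxn = max_project(stack, "pxn")
        mask = cell_mask(pxn)
        counts = [
            channel_spots(pxn, mask, min_area_px=m).count for m in (50, 100, 200, 5000)
        ]
        assert counts == sorted(counts, reverse=True)


def test_end_to_end_zscore_route_recovers_truth():
    """Full chain (cell mask, z-score spots, overlap filter, union FAs)."""
    stack, truth = syn.make_adhesion_scene(
        n_pairs=12, overlap_px=30, image_shape=(640, 640), seed=11
    )
    pxn, vcl = max_project(stack, "pxn"), max_project(stack, "vcl")
    mask = cell_mask(pxn)
    sa = channel_spots(pxn, mask)
    sb = channel_spots(vcl, mask)
    table = build_adhesions(*mutual_overlap_filter(sa, sb))
    assert len(table) == 12
    meas = np.sort(table.adhesions["union_area_px"].to_numpy())
    true = np.sort([p["union_area_px"] for p in truth.of_kind("adhesion_pair")])
    assert np.all(np.abs(meas / true - 1) <= 0.10)
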