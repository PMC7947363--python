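"""Rotation, canopy masking, plot segmentation, ROI shrinkage, features."""

import numpy as np
import pandas as pd
import pytest

from pulsepheno import (
    BandStack,
    PlotLayout,
    build_master_mask,
    calibrate,
    compute_vi_maps,
    exclude_flowers,
    extract_features,
    render_orthomosaic,
    rotate_stack,
    segment_plots,
    shrink_roi,
    suggest_threshold_otsu,
)
from pulsepheno.pipeline import process_scene
from pulsepheno.radiometric import VIMapSet
from pulsepheno.synthetic_trial import SceneSpec


def rect_layout(h, w, nr, nc, **kw):
    corners = np.array([[0, 0], [0, w], [h, w], [h, 0]], dtype=float)
    return PlotLayout(corners, nr, nc, **kw)


def random_convex_quad(rng, lo=12.0, hi=68.0, jitter=8.0):
    """A randomly perturbed rectangle: convex by construction for small
    jitter, ordered TL, TR, BR, BL."""
    base = np.array([[lo, lo], [lo, hi], [hi, hi], [hi, lo]])
    while True:
        pts = base + rng.uniform(-jitter, jitter, (4, 2))
        signs = []
        for i in range(4):
            a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
            e1, e2 = b - a, c - b
            signs.append(np.sign(e1[0] * e2[1] - e1[1] * e2[0]))
        if len(set(signs)) == 1 and signs[0] != 0:
            return pts


class TestRotation:
    def test_zero_degrees_is_identity(self, noiseless_scene):
        assert rotate_stack(noiseless_scene.stack, 0.0) is noiseless_scene.stack

    def test_inverse_pair_recovers_interior(self):
        rng = np.random.default_rng(0)
        stack = BandStack(rng.uniform(0, 1, (5, 40, 50)), state="calibrated")
        back = rotate_stack(rotate_stack(stack, 90.0), -90.0)
        h, w = back.shape
        r0 = (h - 40) // 2
        c0 = (w - 50) // 2
        inner = back.data[:, r0 + 2 : r0 + 38, c0 + 2 : c0 + 48]
        orig = stack.data[:, 2:38, 2:48]
        np.testing.assert_allclose(inner, orig, atol=1e-8)

    def test_rotated_scene_correction_recovers_truth(self, small_plot_map):
        """Render pre-rotated by 7 degrees; the processing path rotates back
        and still recovers per-plot canopy areas within a small boundary
        tolerance (bilinear interpolation blurs blob edges)."""
        scene = SceneSpec(noise_sd=0.0, rotation_deg=7.0)
        scn = render_orthomosaic(small_plot_map, scene, 0.6, seed=2, stage="pod_seed")
        feats = process_scene(scn, savi_threshold=0.4, crop="pea")
        assert len(feats) == 12
        truth = scn.truth.sort_values("plot")["canopy_px"].to_numpy()
        got = feats.sort_values("plot")["canopy_area"].to_numpy()
        rel_err = np.abs(got - truth) / truth
        assert rel_err.max() < 0.06

    def test_non_finite_angle_rejected(self, noiseless_scene):
        with pytest.raises(ValueError):
            rotate_stack(noiseless_scene.stack, np.nan)


class TestMasking:
    def test_threshold_counting(self):
        savi = np.array([[0.1, 0.6], [0.7, 0.2]])
        assert build_master_mask(savi, 0.5).sum() == 2
        assert build_master_mask(savi, 0.9).sum() == 0

    def test_missing_savi_is_background(self):
        savi = np.array([[np.nan, 0.8]])
        mask = build_master_mask(savi, 0.5)
        assert not mask[0, 0] and mask[0, 1]

    def test_noiseless_mask_equals_truth(self, noiseless_scene):
        cal = calibrate(noiseless_scene.stack, noiseless_scene.panel)
        vi = compute_vi_maps(cal)
        # threshold midway between soil and canopy SAVI
        mask = build_master_mask(vi.savi, 0.4)
        mask = exclude_flowers(mask, cal, crop="pea")
        assert mask.sum() == noiseless_scene.truth["canopy_px"].sum()

    def test_otsu_suggestion_separates_soil_and_canopy(self, noiseless_scene):
        cal = calibrate(noiseless_scene.stack, noiseless_scene.panel)
        vi = compute_vi_maps(cal)
        thr = suggest_threshold_otsu(vi.savi)
        soil_savi, canopy_savi = 0.15, 0.64
        assert soil_savi < thr < canopy_savi


class TestFlowerExclusion:
    def test_no_flowers_leaves_mask_unchanged(self, small_plot_map):
        scn = render_orthomosaic(small_plot_map, SceneSpec(noise_sd=0.0), 0.6,
                                 seed=1, stage="pod_seed")
        cal = calibrate(scn.stack, scn.panel)
        mask = build_master_mask(compute_vi_maps(cal).savi, 0.4)
        np.testing.assert_array_equal(exclude_flowers(mask, cal, crop="pea"), mask)

    def test_excluded_pixels_equal_truth_flowers(self, noiseless_scene):
        cal = calibrate(noiseless_scene.stack, noiseless_scene.panel)
        vi = compute_vi_maps(cal)
        # low threshold keeps flowers (SAVI ~0.24) and canopy (~0.64), drops soil (~0.15)
        mask = build_master_mask(vi.savi, 0.2)
        after = exclude_flowers(mask, cal, crop="pea")
        removed = int(mask.sum() - after.sum())
        assert removed == int(noiseless_scene.truth["flower_px"].sum())

    def test_chickpea_is_identity(self, noiseless_scene):
        cal = calibrate(noiseless_scene.stack, noiseless_scene.panel)
        mask = build_master_mask(compute_vi_maps(cal).savi, 0.2)
        out = exclude_flowers(mask, cal, crop="chickpea")
        assert out is mask


class TestSegmentation:
    def test_axis_aligned_rectangle_cells(self):
        grid = segment_plots(rect_layout(100, 200, 2, 5), (100, 200))
        assert grid.n_cells == 10
        for k in range(10):
            cell = grid.cell_mask(k)
            assert cell.sum() == 50 * 40
        assert (grid.labels >= 0).all()

    def test_single_cell_equals_quadrilateral(self):
        corners = np.array([[5, 10], [8, 60], [45, 55], [40, 5]], dtype=float)
        layout = PlotLayout(corners, 1, 1, shrink_tb=0, shrink_lr=0)
        grid = segment_plots(layout, (50, 70))
        assert grid.n_cells == 1
        assert (grid.labels >= 0).sum() == grid.cell_mask(0).sum() > 0

    @pytest.mark.parametrize("seed", range(8))
    def test_random_convex_quads_tile_disjointly(self, seed):
        rng = np.random.default_rng(seed)
        pts = random_convex_quad(rng)
        layout = PlotLayout(pts, 3, 4)
        grid = segment_plots(layout, (80, 80))
        assert grid.n_cells == 12
        covered = np.zeros((80, 80), dtype=int)
        for k in range(12):
            covered += grid.cell_mask(k)
        assert covered.max() <= 1  # pairwise disjoint
        np.testing.assert_array_equal(covered > 0, grid.labels >= 0)

    def test_non_convex_corners_rejected(self):
        bad = np.array([[0, 0], [0, 10], [3, 3], [10, 0]], dtype=float)
        with pytest.raises(ValueError, match="convex"):
            PlotLayout(bad, 2, 2)


class TestShrink:
    def test_box_arithmetic(self):
        cell = np.zeros((300, 400), dtype=bool)
        cell[50:250, 50:350] = True  # 200 x 300 box
        roi = shrink_roi(cell, 20, 50)
        rows = np.flatnonzero(roi.any(axis=1))
        cols = np.flatnonzero(roi.any(axis=0))
        assert rows.size == 160 and cols.size == 200

    def test_zero_margins_identity(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[3:15, 2:18] = True
        np.testing.assert_array_equal(shrink_roi(cell, 0, 0), cell)

    def test_empty_interior_names_plot(self):
        cell = np.zeros((30, 30), dtype=bool)
        cell[5:15, 5:15] = True
        with pytest.raises(ValueError, match="plot 3"):
            shrink_roi(cell, 20, 50, plot_id=3)

    def test_field_preset_excludes_alleys_on_large_plots(self):
        """The 2018-19 preset (20, 50) drops every inter-plot alley pixel on a
        field rendered at full ground-sampling distance."""
        import pandas as pd

        pm = pd.DataFrame(
            {"location": "Pullman", "plot": range(4), "range": [0, 0, 1, 1],
             "column": [0, 1, 0, 1], "entry": list("ABAB"), "rep": [1, 1, 2, 2]}
        )
        scene = SceneSpec(plot_size_px=(160, 150), alley_px=40, margin_px=50,
                          panel_origin=(5, 5), panel_size=12, noise_sd=0.0)
        scn = render_orthomosaic(pm, scene, 0.9, seed=1, stage="pod_seed")
        grid = segment_plots(scn.layout, scn.stack.shape)
        m, a2 = scene.margin_px, scene.alley_px // 2
        for k in range(4):
            roi = shrink_roi(grid.cell_mask(k), 20, 50, plot_id=k)
            rows = np.flatnonzero(roi.any(axis=1)) - m
            cols = np.flatnonzero(roi.any(axis=0)) - m
            ph, pw = scene.plot_size_px
            ch, cw = ph + scene.alley_px, pw + scene.alley_px
            assert rows.min() % ch >= a2 and rows.max() % ch < a2 + ph
            assert cols.min() % cw >= a2 and cols.max() % cw < a2 + pw


def uniform_vi(shape, value):
    maps = {n: np.full(shape, float(value)) for n in ("ndvi", "gndvi", "savi", "ndre", "tvi")}
    return VIMapSet(**maps)


class TestFeatures:
    def test_uniform_values_arithmetic(self):
        vi = uniform_vi((20, 20), 0.6)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 100 canopy pixels
        layout = rect_layout(20, 20, 1, 1, shrink_tb=0, shrink_lr=0)
        grid = segment_plots(layout, (20, 20))
        table = extract_features(vi, mask, grid, layout)
        assert table.loc[0, "canopy_area"] == 100
        assert table.loc[0, "mean_ndvi"] == pytest.approx(0.6)
        assert table.loc[0, "sum_ndvi"] == pytest.approx(60.0)

    def test_empty_mask_gives_missing_means(self):
        vi = uniform_vi((10, 10), 0.5)
        layout = rect_layout(10, 10, 1, 1, shrink_tb=0, shrink_lr=0)
        grid = segment_plots(layout, (10, 10))
        table = extract_features(vi, np.zeros((10, 10), dtype=bool), grid, layout)
        assert table.loc[0, "canopy_area"] == 0
        assert np.isnan(table.loc[0, "mean_ndvi"]) and np.isnan(table.loc[0, "sum_ndvi"])

    def test_full_scene_matches_truth(self, noiseless_scene):
        feats = process_scene(noiseless_scene, savi_threshold=0.4, crop="pea")
        truth = noiseless_scene.truth
        np.testing.assert_array_equal(
            feats.sort_values("plot")["canopy_area"].to_numpy(),
            truth.sort_values("plot")["canopy_px"].to_numpy(),
        )
        for vi in ("ndvi", "gndvi", "savi", "ndre", "tvi"):
            np.testing.assert_allclose(
                feats.sort_values("plot")[f"mean_{vi}"],
                truth.sort_values("plot")[f"mean_{vi}"],
                rtol=1e-10,
            )

    def test_sum_equals_mean_times_area_with_noise(self, small_plot_map):
        scn = render_orthomosaic(small_plot_map, SceneSpec(noise_sd=0.01), 0.6, seed=4)
        feats = process_scene(scn, savi_threshold=0.4, crop="pea")
        for vi in ("ndvi", "gndvi", "savi", "ndre", "tvi"):
            np.testing.assert_allclose(
                feats[f"sum_{vi}"], feats[f"mean_{vi}"] * feats["canopy_area"], rtol=1e-9
            )

    def test_total_canopy_bounded_by_mask(self, noiseless_scene):
        cal = calibrate(noiseless_scene.stack, noiseless_scene.panel)
        vi = compute_vi_maps(cal)
        mask = exclude_flowers(build_master_mask(vi.savi, 0.4), cal, crop="pea")
        feats = process_scene(noiseless_scene, savi_threshold=0.4, crop="pea")
        assert feats["canopy_area"].sum() <= int(mask.sum())

    def test_permutation_equivariance(self, noiseless_scene):
        """Shuffling the metadata plot order permutes rows, not values."""
        cal = calibrate(noiseless_scene.stack, noiseless_scene.panel)
        vi = compute_vi_maps(cal)
        mask = exclude_flowers(build_master_mask(vi.savi, 0.4), cal, crop="pea")
        grid = segment_plots(noiseless_scene.layout, cal.shape)
        meta = noiseless_scene.truth[["plot", "entry", "rep", "location"]]
        base = extract_features(vi, mask, grid, noiseless_scene.layout, metadata=meta)
        # metadata must arrive in range-major (cell) order; values per plot id
        # are independent of how the output table is later sorted
        shuffled = base.sample(frac=1.0, random_state=0).sort_values("plot")
        pd.testing.assert_frame_equal(
            shuffled.reset_index(drop=True), base.sort_values("plot").reset_index(drop=True)
        )
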