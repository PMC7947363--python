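"""RCBD layout generation, scene rendering, and trait simulation."""

import numpy as np
import pandas as pd
import pytest

from pulsepheno import (
    TrialDesign,
    generate_layout,
    generate_traits,
    noise_sd_for_signal_fraction,
    render_orthomosaic,
    spectrum_vi,
)
from pulsepheno.synthetic_trial import SceneSpec, growth_fraction
from pulsepheno.trait_stats import pearson


class TestLayout:
    @pytest.mark.parametrize(
        "entries,rows,cols",
        [(4, 3, 4), (21, 7, 9)],  # 12 and 63 plots
    )
    def test_every_entry_once_per_replicate(self, entries, rows, cols):
        d = TrialDesign(n_entries=entries, plot_rows=rows, plot_cols=cols, seed=1)
        pm = generate_layout(d)
        assert len(pm) == entries * 3
        counts = pm.groupby(["entry", "rep"]).size()
        assert (counts == 1).all()
        # each replicate occupies a contiguous block of plots
        for r, sub in pm.groupby("rep"):
            plots = np.sort(sub["plot"].to_numpy())
            np.testing.assert_array_equal(plots, np.arange(plots[0], plots[0] + entries))

    def test_randomization_differs_across_replicates(self):
        d = TrialDesign(n_entries=21, plot_rows=7, plot_cols=9, seed=5)
        pm = generate_layout(d)
        orders = [tuple(sub.sort_values("plot")["entry"]) for _, sub in pm.groupby("rep")]
        assert len(set(orders)) == 3

    def test_same_seed_identical_maps(self):
        d = TrialDesign(n_entries=8, plot_rows=4, plot_cols=6, seed=9)
        pd.testing.assert_frame_equal(generate_layout(d), generate_layout(d))

    def test_dimension_mismatch_names_both_products(self):
        with pytest.raises(ValueError, match="12 plots.*15 experimental"):
            TrialDesign(n_entries=5, plot_rows=3, plot_cols=4)


class TestRender:
    def test_zero_cover_gives_zero_canopy(self, small_plot_map):
        scn = render_orthomosaic(small_plot_map, SceneSpec(noise_sd=0.0), 0.0, seed=1,
                                 stage="early")
        assert (scn.truth["canopy_px"] == 0).all()
        assert scn.truth["mean_ndvi"].isna().all()

    def test_full_cover_noiseless_equals_canopy_spectrum(self, small_plot_map):
        scene = SceneSpec(noise_sd=0.0, gain=(1.0,) * 5)
        scn = render_orthomosaic(small_plot_map, scene, 1.0, seed=1, stage="pod_seed")
        # interior of plot (0, 0): rows/cols margin+alley/2 onward
        m, a2 = scene.margin_px, scene.alley_px // 2
        ph, pw = scene.plot_size_px
        block = scn.stack.data[:, m + a2 : m + a2 + ph, m + a2 : m + a2 + pw]
        np.testing.assert_array_equal(
            block, np.broadcast_to(np.array(scene.canopy_spectrum)[:, None, None], block.shape)
        )

    def test_bit_reproducible_under_seed(self, small_plot_map):
        scene = SceneSpec(noise_sd=0.01)
        a = render_orthomosaic(small_plot_map, scene, 0.6, seed=3)
        b = render_orthomosaic(small_plot_map, scene, 0.6, seed=3)
        np.testing.assert_array_equal(a.stack.data, b.stack.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_flower_fraction_above_cover_rejected(self, small_plot_map):
        scene = SceneSpec(noise_sd=0.0, flower_fraction=0.5)
        with pytest.raises(ValueError, match="flower fraction"):
            render_orthomosaic(small_plot_map, scene, 0.3, seed=1, stage="flowering")

    def test_flowers_only_at_flowering_and_only_for_pea(self, small_plot_map):
        scene = SceneSpec(noise_sd=0.0)
        flowering = render_orthomosaic(small_plot_map, scene, 0.6, seed=1, stage="flowering")
        pod = render_orthomosaic(small_plot_map, scene, 0.6, seed=1, stage="pod_seed")
        chick = render_orthomosaic(small_plot_map, scene, 0.6, seed=1, stage="flowering",
                                   crop="chickpea")
        assert (flowering.truth["flower_px"] > 0).all()
        assert (pod.truth["flower_px"] == 0).all()
        assert (chick.truth["flower_px"] == 0).all()

    def test_truth_sum_equals_mean_times_area(self, noiseless_scene):
        t = noiseless_scene.truth
        for vi in ("ndvi", "gndvi", "savi", "ndre", "tvi"):
            np.testing.assert_allclose(
                t[f"sum_{vi}"], t[f"mean_{vi}"] * t["canopy_px"], rtol=1e-12
            )

    def test_invalid_spectra_rejected(self):
        with pytest.raises(ValueError, match="canopy_spectrum"):
            SceneSpec(canopy_spectrum=(0.04, 0.08, 0.05, 0.3, 1.5))
        with pytest.raises(ValueError, match="white"):
            SceneSpec(flower_spectrum=(0.9, 0.5, 0.55, 0.65, 0.85))
        with pytest.raises(ValueError, match="NIR"):
            SceneSpec(canopy_spectrum=(0.04, 0.08, 0.4, 0.3, 0.5))


def _fake_features(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "location": "Pullman",
            "plot": np.arange(n),
            "entry": [f"E{i % 21:02d}" for i in range(n)],
            "rep": 1 + (np.arange(n) % 3),
            "canopy_area_flowering": rng.uniform(100, 500, n),
            "sum_ndvi_flowering": rng.normal(200, 40, n),
        }
    )


class TestTraits:
    def test_noiseless_identity(self):
        feats = _fake_features(30)
        traits, _ = generate_traits(feats, {"sum_ndvi_flowering": 1.0}, 0.0, seed=1)
        np.testing.assert_allclose(traits["yield"], feats["sum_ndvi_flowering"])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_traits(_fake_features(10), {}, -1.0, seed=1)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariates"):
            generate_traits(_fake_features(10), {"no_such_feature": 1.0}, 0.0, seed=1)

    def test_null_coefficients_give_null_correlation(self):
        feats = _fake_features(10_000)
        traits, _ = generate_traits(feats, {"intercept": 5.0}, 1.0, seed=2)
        r, _, _ = pearson(traits["yield"], feats["sum_ndvi_flowering"])
        assert abs(r) < 0.05

    def test_target_correlation_inside_fisher_band(self):
        """Fisher-z oracle: with noise sized for population r = 0.8 at n = 63,
        the sample correlation lands in the 95% band in nearly all seeds."""
        feats = _fake_features(63)
        x = feats["sum_ndvi_flowering"].to_numpy()
        target = 0.8
        sd = x.std() * np.sqrt(1.0 / target**2 - 1.0)
        lo, hi = np.tanh(np.arctanh(target) + np.array([-1.96, 1.96]) / np.sqrt(60))
        inside = 0
        for seed in range(60):
            traits, _ = generate_traits(feats, {"sum_ndvi_flowering": 1.0}, sd, seed=seed)
            r, _, _ = pearson(traits["yield"], x)
            inside += lo <= r <= hi
        assert inside >= 50  # ~95% coverage expected

    def test_phenology_sign_structure(self):
        """F50 declines with early vigor; PM rises with late vigor."""
        rng = np.random.default_rng(3)
        feats = _fake_features(200)
        feats["canopy_area_early"] = rng.uniform(50, 300, 200)
        feats["sum_ndvi_pod_seed"] = rng.normal(250, 50, 200)
        traits, params = generate_traits(feats, {"intercept": 100.0}, 1.0, seed=3)
        assert params["f50_covariate"] == "canopy_area_early"
        assert params["pm_covariate"] == "sum_ndvi_pod_seed"
        r_f50, p_f50, _ = pearson(traits["f50"], feats["canopy_area_early"])
        r_pm, p_pm, _ = pearson(traits["pm"], feats["sum_ndvi_pod_seed"])
        assert r_f50 < 0 and p_f50 < 0.001
        assert r_pm > 0 and p_pm < 0.001


def test_growth_curve_monotone():
    assert growth_fraction("early") < growth_fraction("flowering") < growth_fraction("pod_seed")


def test_noise_sd_for_signal_fraction_roundtrip():
    rng = np.random.default_rng(0)
    s = rng.normal(0, 3.0, 10_000)
    sd = noise_sd_for_signal_fraction(s, 0.85)
    frac = s.var() / (s.var() + sd**2)
    assert frac == pytest.approx(0.85, rel=1e-12)
    with pytest.raises(ValueError):
        noise_sd_for_signal_fraction(s, 0.0)


def test_spectrum_vi_matches_hand_computation():
    vals = spectrum_vi((0.1, 0.2, 0.2, 0.3, 0.8))
    assert vals["ndvi"] == pytest.approx(0.6)
    assert vals["tvi"] == pytest.approx(36.0)
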