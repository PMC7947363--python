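"""Canopy masking, plot segmentation and per-plot feature extraction.

Thresholds SAVI for the canopy master mask, excludes white pea flowers,
splits the field into plot cells from the four corners, shrinks each region
of interest, and extracts the 11 features per plot.
"""

from pulsepheno import (
    TrialDesign, build_master_mask, calibrate, compute_vi_maps,
    exclude_flowers, extract_features, segment_plots, simulate_trial,
    suggest_threshold_otsu,
)

trial = simulate_trial(TrialDesign(n_entries=21, plot_rows=7, plot_cols=9,
                                   n_locations=1, seed=42))
scn = trial.scenes[0]  # flowering stage

cal = calibrate(scn.stack, scn.panel)
vi = compute_vi_maps(cal)
print(f"Otsu suggestion for the SAVI threshold: {suggest_threshold_otsu(vi.savi):.3f} "
      "(operator chooses; 0.35 used here)")

mask = build_master_mask(vi.savi, 0.35)
mask = exclude_flowers(mask, cal, crop="pea")
grid = segment_plots(scn.layout, cal.shape)
feats = extract_features(vi, mask, grid, scn.layout,
                         metadata=scn.truth[["plot", "entry", "rep", "location"]],
                         stage=scn.stage)

print(feats[["plot", "entry", "rep", "canopy_area", "mean_ndvi", "sum_ndvi"]]
      .head(6).to_string(index=False))
match = (feats.sort_values("plot")["canopy_area"].to_numpy()
         == scn.truth.sort_values("plot")["canopy_px"].to_numpy()).mean()
print(f"plots whose canopy area equals generator truth exactly: {match:.0%}")
# With zero-noise spectra this is 100%; sum_ndvi = mean_ndvi x canopy_area
# for every row, the bookkeeping identity the whole feature table obeys.
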