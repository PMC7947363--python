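"""Radiometric calibration and vegetation-index maps.

Converts a rendered orthomosaic from digital numbers to reflectance using the
in-scene 99% panel, then computes the five index maps.
"""

import numpy as np

from pulsepheno import TrialDesign, calibrate, compute_vi_maps, simulate_trial

trial = simulate_trial(TrialDesign(n_entries=21, plot_rows=7, plot_cols=9,
                                   n_locations=1, seed=42))
scn = trial.scenes[0]

cal = calibrate(scn.stack, scn.panel)
print("per-band panel mean digital numbers:")
for band, m in cal.meta["panel_means"].items():
    print(f"  {band:8s} {m:8.1f}")

vi = compute_vi_maps(cal, savi_l=0.5)
for name, m in vi.maps.items():
    print(f"{name.upper():6s} range [{np.nanmin(m):7.3f}, {np.nanmax(m):7.3f}]")
# NDVI/GNDVI/NDRE are bounded in [-1, 1]; TVI is unbounded (canopy pixels
# score high on all five). Soil sits near SAVI 0.15 and canopy near 0.64,
# which is why a mid-range SAVI threshold separates them cleanly.
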