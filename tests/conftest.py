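import numpy as np
import pytest

from pulsepheno import TrialDesign, generate_layout, render_orthomosaic
from pulsepheno.synthetic_trial import SceneSpec


@pytest.fixture(scope="session")
def small_design():
    return TrialDesign(n_entries=4, plot_rows=3, plot_cols=4, n_replicates=3,
                       crop="pea", seed=7)


@pytest.fixture(scope="session")
def small_plot_map(small_design):
    return generate_layout(small_design)


@pytest.fixture(scope="session")
def noiseless_scene(small_plot_map):
    """Flowering pea scene with zero noise and a per-plot cover gradient."""
    scene = SceneSpec(noise_sd=0.0)
    cover = np.linspace(0.3, 0.9, len(small_plot_map))
    return render_orthomosaic(small_plot_map, scene, cover, seed=7, crop="pea")


@pytest.fixture(scope="session")
def noiseless_chickpea_scene(small_plot_map):
    scene = SceneSpec(noise_sd=0.0)
    cover = np.linspace(0.3, 0.9, len(small_plot_map))
    return render_orthomosaic(small_plot_map, scene, cover, seed=7, crop="chickpea")
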