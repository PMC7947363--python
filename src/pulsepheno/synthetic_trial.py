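"""Synthetic multispectral breeding-trial generator.

Emulates UAV five-band orthomosaics of randomized-complete-block (RCBD)
pulse-crop yield trials — canopy reflectance over soil background, white pea
flowers at the flowering stage, an in-scene calibration panel — together with
ground-truth bookkeeping (per-plot canopy pixel counts, true vegetation-index
values) and trait tables (seed yield, days to 50% flowering, days to
physiological maturity) statistically linked to canopy vigor. Every
downstream stage of the pipeline is testable against this truth without any
field imagery.

Scale and structure follow typical advanced yield trials: 21-40 entries x 3
replicates per location, 1-3 locations, plots in a regular grid of ranges
separated by alleys. Rendering is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .radiometric import BAND_ORDER, BandStack, PanelReference, compute_vi_maps
from .plot_extraction import PlotLayout, rotate_stack

__all__ = [
    "TrialDesign",
    "SceneSpec",
    "SyntheticScene",
    "SimulatedTrial",
    "generate_layout",
    "sample_canopy_cover",
    "render_orthomosaic",
    "truth_features",
    "generate_traits",
    "noise_sd_for_signal_fraction",
    "simulate_trial",
    "spectrum_vi",
    "growth_fraction",
]

LOCATION_NAMES = ("Pullman", "Genesee", "Fairfield")
STAGES = ("early", "flowering", "pod_seed")

# Nominal growing-degree-day timing of the three acquisition stages and the
# logistic canopy growth curve used for multi-date series.
_STAGE_GDD = {"early": 450.0, "flowering": 760.0, "pod_seed": 1000.0}
_GROWTH_MID_GDD = 550.0
_GROWTH_SCALE_GDD = 110.0

DEFAULT_CANOPY = (0.04, 0.08, 0.05, 0.30, 0.50)
DEFAULT_SOIL = (0.10, 0.15, 0.20, 0.25, 0.30)
# White flowers: high, near-equal visible reflectance; NIR kept above soil so
# the SAVI canopy threshold alone does not remove them and the dedicated
# flower-exclusion rule does real work.
DEFAULT_FLOWER = (0.55, 0.55, 0.55, 0.65, 0.85)
DEFAULT_GAIN = (3800.0, 4000.0, 3900.0, 4100.0, 4200.0)


def growth_fraction(stage: str) -> float:
    """Fraction of full canopy cover reached at a growth stage (logistic curve)."""
    t = _STAGE_GDD[stage]
    return float(1.0 / (1.0 + np.exp(-(t - _GROWTH_MID_GDD) / _GROWTH_SCALE_GDD)))


@dataclass
class TrialDesign:
    """RCBD trial: ``n_entries`` breeding lines x ``n_replicates`` blocks per location.

    ``plot_rows`` (ranges) x ``plot_cols`` (plots per range) must equal
    ``n_entries * n_replicates``; each replicate occupies a contiguous block of
    plots in range-major order and the within-block entry order is a seeded
    permutation that differs across replicates and locations.
    """

    n_entries: int
    plot_rows: int
    plot_cols: int
    n_replicates: int = 3
    n_locations: int = 1
    crop: str = "pea"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop not in ("pea", "chickpea"):
            raise ValueError(f"crop must be 'pea' or 'chickpea', got {self.crop!r}")
        if not 1 <= self.n_locations <= len(LOCATION_NAMES):
            raise ValueError("n_locations must be between 1 and 3")
        n_plots = self.plot_rows * self.plot_cols
        n_units = self.n_entries * self.n_replicates
        if n_plots != n_units:
            raise ValueError(
                f"grid has plot_rows*plot_cols = {n_plots} plots but the design needs "
                f"n_entries*n_replicates = {n_units} experimental units"
            )

    @property
    def locations(self) -> tuple[str, ...]:
        return LOCATION_NAMES[: self.n_locations]


@dataclass
class SceneSpec:
    """Geometry, spectra and noise of one synthetic orthomosaic.

    Per-band spectra are mean reflectance in [0, 1] in the order
    blue, green, red, red-edge, NIR. Digital numbers are
    ``gain_b * (reflectance + N(0, noise_sd))`` per band; the gain justifies
    (and is undone by) a linear panel calibration.
    """

    plot_size_px: tuple[int, int] = (36, 16)
    alley_px: int = 6
    margin_px: int = 24
    panel_origin: tuple[int, int] = (5, 5)
    panel_size: int = 12
    canopy_cover_fraction: float = 0.65
    canopy_spectrum: tuple[float, ...] = DEFAULT_CANOPY
    soil_spectrum: tuple[float, ...] = DEFAULT_SOIL
    flower_spectrum: tuple[float, ...] = DEFAULT_FLOWER
    panel_reflectance: float = 0.99
    noise_sd: float = 0.005
    growth_stage: str = "flowering"
    flower_fraction: float = 0.05
    gain: tuple[float, ...] = DEFAULT_GAIN
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("canopy_spectrum", "soil_spectrum", "flower_spectrum"):
            spec = np.asarray(getattr(self, name), dtype=float)
            if spec.shape != (5,) or np.any(spec < 0) or np.any(spec > 1):
                raise ValueError(f"{name} must be five per-band reflectances in [0, 1]")
        if not (0.0 < self.panel_reflectance <= 1.0):
            raise ValueError("panel_reflectance must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.growth_stage not in STAGES:
            raise ValueError(f"growth_stage must be one of {STAGES}")
        if self.alley_px % 2 != 0:
            raise ValueError("alley_px must be even so plots centre exactly in cells")
        flower = np.asarray(self.flower_spectrum[:3])
        if flower.min() < 0.3 or np.ptp(flower) > 0.15:
            raise ValueError("flower_spectrum visible bands must be high and near-equal (white)")
        canopy = self.canopy_spectrum
        if not canopy[4] > 2 * canopy[2]:
            raise ValueError("canopy_spectrum must have NIR well above red")

    @property
    def roi_shrink(self) -> int:
        """Per-side margin (px) that maps a plot cell onto exactly the sown plot box."""
        return self.alley_px // 2


@dataclass
class SyntheticScene:
    """One rendered orthomosaic with its layout, panel and per-plot truth."""

    stack: BandStack
    layout: PlotLayout
    panel: PanelReference
    truth: pd.DataFrame
    gain: np.ndarray
    scene: SceneSpec
    stage: str
    location: str


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def generate_layout(design: TrialDesign) -> pd.DataFrame:
    """Plot -> (entry, replicate) map for every location of an RCBD trial.

    Returns one row per plot with columns ``location, plot, range, column,
    entry, rep``. Plots are numbered range-major (0-based); replicate ``r``
    occupies the contiguous plots ``[r*n_entries, (r+1)*n_entries)`` and
    entries within each replicate are a seeded permutation, re-randomized per
    replicate and location. Identical seeds give identical maps.
    """
    entries = np.array([f"E{i + 1:02d}" for i in range(design.n_entries)])
    rows = []
    for li, loc in enumerate(design.locations):
        order = np.empty(design.n_entries * design.n_replicates, dtype=object)
        reps = np.empty_like(order)
        for r in range(design.n_replicates):
            perm = _rng(design.seed, 11, li, r).permutation(design.n_entries)
            order[r * design.n_entries : (r + 1) * design.n_entries] = entries[perm]
            reps[r * design.n_entries : (r + 1) * design.n_entries] = r + 1
        for p in range(order.size):
            rows.append(
                {
                    "location": loc,
                    "plot": p,
                    "range": p // design.plot_cols,
                    "column": p % design.plot_cols,
                    "entry": order[p],
                    "rep": int(reps[p]),
                }
            )
    return pd.DataFrame(rows)


def sample_canopy_cover(
    design: TrialDesign,
    plot_map: pd.DataFrame,
    mean: float = 0.65,
    entry_sd: float = 0.12,
    location_sd: float = 0.05,
    plot_sd: float = 0.04,
) -> pd.Series:
    """Per-plot full-canopy cover fraction with entry, location and plot effects.

    Entry effects are shared across locations (the genetic signal the trial is
    designed to detect); location and residual plot effects are additive
    Gaussian noise. Values are clipped to [0.15, 0.95] — the floor keeps every
    plot with a resolvable canopy (and above any flower fraction) so per-plot
    statistics stay defined. Indexed like ``plot_map``.
    """
    entries = sorted(plot_map["entry"].unique())
    e_eff = dict(zip(entries, _rng(design.seed, 21).normal(mean, entry_sd, len(entries))))
    locs = list(design.locations)
    l_eff = dict(zip(locs, _rng(design.seed, 22).normal(0.0, location_sd, len(locs))))
    resid = _rng(design.seed, 23).normal(0.0, plot_sd, len(plot_map))
    cover = np.array(
        [e_eff[e] + l_eff[l] for e, l in zip(plot_map["entry"], plot_map["location"])]
    )
    return pd.Series(np.clip(cover + resid, 0.15, 0.95), index=plot_map.index, name="cover")


def spectrum_vi(spectrum: Sequence[float], savi_l: float = 0.5) -> dict[str, float]:
    """Vegetation-index values of a single pure spectrum (1-pixel evaluation)."""
    stack = BandStack(np.asarray(spectrum, dtype=float).reshape(5, 1, 1), state="calibrated")
    vi = compute_vi_maps(stack, savi_l=savi_l)
    return {name: float(m[0, 0]) for name, m in vi.maps.items()}


def _clustered_pixels(
    shape: tuple[int, int], n_target: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exactly ``n_target`` pixel indices forming clustered blobs.

    Seed points are dilated by taking the ``n_target`` pixels nearest to any
    seed (Euclidean distance transform with a random tie-break), so the count
    is exact and the texture is blobby rather than salt-and-pepper.
    """
    n_px = shape[0] * shape[1]
    if n_target <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if n_target >= n_px:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return rr.ravel(), cc.ravel()
    n_seeds = max(1, n_target // 60)
    seeds = np.zeros(shape, dtype=bool)
    idx = rng.choice(n_px, size=n_seeds, replace=False)
    seeds.ravel()[idx] = True
    dist = ndimage.distance_transform_edt(~seeds)
    order = np.argsort(dist.ravel() + rng.uniform(0, 1e-6, n_px), kind="stable")
    chosen = order[:n_target]
    return chosen // shape[1], chosen % shape[1]


def render_orthomosaic(
    plot_map: pd.DataFrame,
    scene: SceneSpec,
    cover,
    seed: int,
    stage: str | None = None,
    crop: str = "pea",
    location: str | None = None,
) -> SyntheticScene:
    """Render one location's orthomosaic as raw digital numbers plus truth.

    ``plot_map`` holds one location's rows from :func:`generate_layout`;
    ``cover`` is a scalar or per-plot canopy cover fraction in [0, 1] used as
    given (no growth scaling here). Each plot cell receives clustered
    canopy-spectrum pixels at its cover fraction over soil background; at the
    flowering stage white flower pixels replace ``flower_fraction`` (of plot
    area) of the canopy for pea. A uniform panel patch of known reflectance
    sits in the image margin. DN = gain_b * (reflectance + N(0, noise_sd)).

    The returned truth counts canopy pixels excluding flowers and carries the
    true (noise-free) mean and sum of each vegetation index over that canopy.
    """
    stage = stage or scene.growth_stage
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if location is None:
        locs = plot_map["location"].unique()
        if len(locs) != 1:
            raise ValueError("plot_map spans several locations; pass one location")
        location = str(locs[0])
        plots = plot_map
    else:
        plots = plot_map[plot_map["location"] == location]
    plots = plots.sort_values("plot").reset_index(drop=True)
    n_plots = len(plots)
    n_rows = int(plots["range"].max()) + 1
    n_cols = int(plots["column"].max()) + 1

    cover = np.broadcast_to(np.asarray(cover, dtype=float), (n_plots,)).copy()
    if np.any(cover < 0) or np.any(cover > 1):
        raise ValueError("canopy cover fractions must lie in [0, 1]")
    flowering = stage == "flowering" and crop == "pea"
    if flowering and np.any(scene.flower_fraction > cover):
        raise ValueError(
            f"flower fraction {scene.flower_fraction} exceeds the canopy cover "
            f"fraction of at least one plot (min cover {cover.min():.3f})"
        )

    ph, pw = scene.plot_size_px
    a2 = scene.alley_px // 2
    cell_h, cell_w = ph + scene.alley_px, pw + scene.alley_px
    m = scene.margin_px
    height = 2 * m + n_rows * cell_h
    width = 2 * m + n_cols * cell_w

    canopy = np.asarray(scene.canopy_spectrum, dtype=float)
    soil = np.asarray(scene.soil_spectrum, dtype=float)
    flower = np.asarray(scene.flower_spectrum, dtype=float)
    refl = np.empty((5, height, width), dtype=float)
    refl[:] = soil[:, None, None]

    pr, pc = scene.panel_origin
    if pr + scene.panel_size > m:
        raise ValueError("panel does not fit inside the top margin")
    refl[:, pr : pr + scene.panel_size, pc : pc + scene.panel_size] = scene.panel_reflectance
    panel = PanelReference(pr, pr + scene.panel_size, pc, pc + scene.panel_size,
                           reflectance=scene.panel_reflectance)

    canopy_vi = spectrum_vi(scene.canopy_spectrum)
    records = []
    for k in range(n_plots):
        i, j = int(plots.loc[k, "range"]), int(plots.loc[k, "column"])
        r0 = m + i * cell_h + a2
        c0 = m + j * cell_w + a2
        target = int(round(cover[k] * ph * pw))
        rng_k = _rng(seed, 31, i, j)
        rr, cc = _clustered_pixels((ph, pw), target, rng_k)
        refl[:, r0 + rr, c0 + cc] = canopy[:, None]
        n_flower = 0
        if flowering and target > 0:
            n_flower = min(int(round(scene.flower_fraction * ph * pw)), target)
            if n_flower > 0:
                pick = rng_k.choice(target, size=n_flower, replace=False)
                refl[:, r0 + rr[pick], c0 + cc[pick]] = flower[:, None]
        canopy_px = target - n_flower
        rec = {
            "location": location,
            "plot": int(plots.loc[k, "plot"]),
            "range": i,
            "column": j,
            "entry": plots.loc[k, "entry"],
            "rep": int(plots.loc[k, "rep"]),
            "stage": stage,
            "cover": cover[k],
            "canopy_px": canopy_px,
            "flower_px": n_flower,
            "canopy_area": canopy_px,
        }
        for name, v in canopy_vi.items():
            rec[f"mean_{name}"] = v if canopy_px > 0 else np.nan
            rec[f"sum_{name}"] = v * canopy_px if canopy_px > 0 else np.nan
        records.append(rec)
    truth = pd.DataFrame(records)

    gain = np.asarray(scene.gain, dtype=float)
    dn = refl
    if scene.noise_sd > 0:
        noise = _rng(seed, 32).normal(0.0, scene.noise_sd, refl.shape)
        dn = np.clip(refl + noise, 0.0, None)
    dn = dn * gain[:, None, None]

    corners = np.array(
        [
            [m, m],
            [m, m + n_cols * cell_w],
            [m + n_rows * cell_h, m + n_cols * cell_w],
            [m + n_rows * cell_h, m],
        ],
        dtype=float,
    )
    layout = PlotLayout(
        corners=corners,
        n_ranges=n_rows,
        n_plots_per_range=n_cols,
        shrink_tb=scene.roi_shrink,
        shrink_lr=scene.roi_shrink,
        rotation_deg=scene.rotation_deg,
    )
    stack = BandStack(dn, state="raw", meta={"location": location, "stage": stage})
    if scene.rotation_deg != 0.0:
        stack = rotate_stack(stack, scene.rotation_deg)
    return SyntheticScene(
        stack=stack, layout=layout, panel=panel, truth=truth,
        gain=gain, scene=scene, stage=stage, location=location,
    )


def truth_features(truths: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pivot per-stage truth tables to one wide row per plot.

    Feature columns are suffixed with the stage, e.g. ``sum_ndvi_flowering``,
    matching the feature naming the prediction stage expects.
    """
    by_stage: dict[str, list[pd.DataFrame]] = {}
    for t in truths:
        stage = t["stage"].iloc[0]
        feat_cols = ["canopy_area"] + [
            c for c in t.columns if c.startswith(("mean_", "sum_"))
        ]
        f = t.set_index(["location", "plot", "entry", "rep"])[feat_cols]
        f.columns = [f"{c}_{stage}" for c in f.columns]
        by_stage.setdefault(stage, []).append(f)
    stacked = [pd.concat(frames) for frames in by_stage.values()]
    wide = pd.concat(stacked, axis=1).reset_index()
    return wide


def noise_sd_for_signal_fraction(signal: np.ndarray, fraction: float) -> float:
    """Noise s.d. making ``fraction`` the share of variance due to ``signal``."""
    if not 0 < fraction <= 1:
        raise ValueError("signal fraction must lie in (0, 1]")
    var = float(np.var(np.asarray(signal, dtype=float)))
    return float(np.sqrt(var * (1.0 - fraction) / fraction))


def generate_traits(
    features: pd.DataFrame,
    coefficients: Mapping[str, float],
    noise_sd: float,
    seed: int,
    f50_days: tuple[float, float] = (60.0, 9.0),
    pm_days: tuple[float, float] = (95.0, 7.0),
    phenology_noise_days: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Trait table (yield, F50, PM) as linear functions of canopy covariates.

    ``yield_i = b0 + sum_k b_k * x_ik + N(0, noise_sd^2)`` with coefficients
    keyed by feature column name (``"intercept"`` for b0). Days to 50%
    flowering declines with early-stage vigor and days to maturity rises with
    late-stage vigor (each ``(base_days, swing_days)`` on the standardized
    vigor covariate), mirroring the early-negative / late-positive correlation
    pattern of vigor with phenology. Returns the table plus the parameters
    that reproduce it exactly given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    missing = [k for k in coefficients if k != "intercept" and k not in features.columns]
    if missing:
        raise ValueError(f"coefficients reference unknown covariates: {missing}")

    n = len(features)
    y = np.full(n, float(coefficients.get("intercept", 0.0)))
    for key, beta in coefficients.items():
        if key == "intercept":
            continue
        y = y + beta * features[key].to_numpy(dtype=float)
    rng = _rng(seed, 41)
    eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    # phenology links: earliest rendered stage drives F50 (negative),
    # latest drives PM (positive)
    stages_present = [s for s in STAGES if any(c.endswith(f"_{s}") for c in features.columns)]
    early_col = f"canopy_area_{stages_present[0]}"
    late_col = f"sum_ndvi_{stages_present[-1]}"

    def _z(col: str) -> np.ndarray:
        v = features[col].to_numpy(dtype=float)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    prng = _rng(seed, 42)
    f50 = f50_days[0] - f50_days[1] * _z(early_col) + prng.normal(0, phenology_noise_days, n)
    pm = pm_days[0] + pm_days[1] * _z(late_col) + prng.normal(0, phenology_noise_days, n)

    out = features[["location", "plot", "entry", "rep"]].copy()
    out["yield"] = y + eps
    out["f50"] = f50
    out["pm"] = pm
    params = {
        "coefficients": dict(coefficients),
        "noise_sd": noise_sd,
        "seed": seed,
        "f50_covariate": early_col,
        "pm_covariate": late_col,
    }
    return out, params


@dataclass
class SimulatedTrial:
    """Full multi-location, multi-date synthetic trial bundle."""

    design: TrialDesign
    scene: SceneSpec
    plot_map: pd.DataFrame
    scenes: list[SyntheticScene] = field(default_factory=list)
    features_truth: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    trait_params: dict | None = None


def simulate_trial(
    design: TrialDesign,
    scene: SceneSpec | None = None,
    stages: Sequence[str] = ("flowering", "pod_seed"),
    signal_fraction: float = 0.85,
    yield_mean: float = 1500.0,
    yield_sd: float = 300.0,
) -> SimulatedTrial:
    """Simulate the whole trial: layouts, one orthomosaic per (location, stage),
    and traits whose yield signal comes from sum NDVI and canopy area.

    Per-plot canopy cover follows entry/location/plot effects scaled along a
    logistic growth curve across stages. Yield is ``yield_mean + yield_sd * z``
    where ``z`` standardizes the sum of standardized sum-NDVI and canopy-area
    covariates at the first stage in ``stages``, plus Gaussian noise sized so
    the signal explains ``signal_fraction`` of the yield variance.
    """
    scene = scene or SceneSpec()
    plot_map = generate_layout(design)
    cover = sample_canopy_cover(design, plot_map)
    scenes: list[SyntheticScene] = []
    truths = []
    for loc in design.locations:
        sel = plot_map["location"] == loc
        base = cover[sel].to_numpy()
        for stage in stages:
            frac = growth_fraction(stage) / growth_fraction("pod_seed")
            scn = render_orthomosaic(
                plot_map[sel],
                scene,
                np.clip(base * frac, 0.0, 0.98),
                seed=design.seed + 1000 * design.locations.index(loc),
                stage=stage,
                crop=design.crop,
                location=loc,
            )
            scenes.append(scn)
            truths.append(scn.truth)

    feats = truth_features(truths)
    stage0 = stages[0]

    def _z(col: str) -> np.ndarray:
        v = feats[col].to_numpy(dtype=float)
        return (v - v.mean()) / v.std()

    signal = _z(f"sum_ndvi_{stage0}") + _z(f"canopy_area_{stage0}")
    signal = yield_sd * (signal - signal.mean()) / signal.std()
    noise_sd = noise_sd_for_signal_fraction(signal, signal_fraction)
    traits, params = _traits_from_signal(
        feats, signal, yield_mean, noise_sd, design.seed,
        covariates=(f"sum_ndvi_{stage0}", f"canopy_area_{stage0}"),
    )
    return SimulatedTrial(
        design=design,
        scene=scene,
        plot_map=plot_map,
        scenes=scenes,
        features_truth=feats,
        traits=traits,
        trait_params=params,
    )


def _traits_from_signal(
    feats: pd.DataFrame,
    signal: np.ndarray,
    yield_mean: float,
    noise_sd: float,
    seed: int,
    covariates: tuple[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Express a standardized two-covariate signal as explicit linear
    coefficients and delegate to :func:`generate_traits`."""
    x1 = feats[covariates[0]].to_numpy(dtype=float)
    x2 = feats[covariates[1]].to_numpy(dtype=float)
    # signal = a1*z(x1) + a2*z(x2) with equal weight before rescaling; recover
    # the raw-scale coefficients by least squares (exact: signal lies in the
    # span of x1, x2 and a constant)
    design_mat = np.column_stack([np.ones_like(x1), x1, x2])
    beta, *_ = np.linalg.lstsq(design_mat, signal + yield_mean, rcond=None)
    coeffs = {"intercept": float(beta[0]), covariates[0]: float(beta[1]),
              covariates[1]: float(beta[2])}
    return generate_traits(feats, coeffs, noise_sd, seed)
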