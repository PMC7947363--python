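"""End-to-end workflow: simulate -> calibrate -> indices -> extract ->
correlate -> predict, with a reproducibility manifest.

``run_pipeline`` drives the whole analysis on a synthetic trial and writes
every intermediate artifact (rasters, feature tables, correlation reports,
model evaluations) plus a JSON manifest with per-artifact checksums: two runs
with the same master seed produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_bandstack, write_yaml
from .plot_extraction import (
    build_master_mask,
    exclude_flowers,
    extract_features,
    rotate_stack,
    segment_plots,
    suggest_threshold_otsu,
)
from .radiometric import PanelReference, calibrate, compute_vi_maps
from .synthetic_trial import (
    SceneSpec,
    SimulatedTrial,
    SyntheticScene,
    TrialDesign,
    simulate_trial,
)
from .trait_stats import correlate
from .yield_model import (
    LassoConfig,
    evaluate_cultivar_mode,
    evaluate_plot_mode,
    normalize,
)

logger = logging.getLogger("pulsepheno")

__all__ = ["PipelineConfig", "run_pipeline", "process_scene", "assemble_features",
           "predict_yield"]


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    output_dir: str = "pulsepheno_run"
    seed: int = 0
    crop: str = "pea"
    # trial simulation
    n_entries: int = 21
    n_replicates: int = 3
    n_locations: int = 3
    plot_rows: int = 7
    plot_cols: int = 9
    stages: tuple[str, ...] = ("flowering", "pod_seed")
    signal_fraction: float = 0.85
    # image processing
    savi_threshold: float = 0.35
    savi_l: float = 0.5
    flower_min_visible_reflectance: float = 0.35
    # modelling
    lasso: LassoConfig = field(default_factory=LassoConfig)
    write_qc: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "lasso" in d and isinstance(d["lasso"], dict):
            d["lasso"] = LassoConfig(**d["lasso"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def process_scene(
    scene: SyntheticScene,
    savi_threshold: float,
    crop: str,
    savi_l: float = 0.5,
    flower_min_visible_reflectance: float = 0.35,
) -> pd.DataFrame:
    """Run one orthomosaic through calibration, masking and feature extraction.

    If the scene was pre-rotated, it is first rotated back and the layout
    corners and panel region are translated by the canvas-expansion offset of
    the rotation round trip.
    """
    stack, layout, panel = scene.stack, scene.layout, scene.panel
    if layout.rotation_deg != 0.0:
        h0 = 2 * scene.scene.margin_px + layout.n_ranges * (
            scene.scene.plot_size_px[0] + scene.scene.alley_px
        )
        w0 = 2 * scene.scene.margin_px + layout.n_plots_per_range * (
            scene.scene.plot_size_px[1] + scene.scene.alley_px
        )
        stack = rotate_stack(stack, -layout.rotation_deg)
        dr = (stack.shape[0] - h0) / 2.0
        dc = (stack.shape[1] - w0) / 2.0
        layout = dataclasses.replace(
            layout, corners=layout.corners + np.array([dr, dc]), rotation_deg=0.0
        )
        # contract the panel region to dodge interpolation at its border
        panel = PanelReference(
            panel.row0 + int(round(dr)) + 2, panel.row1 + int(round(dr)) - 2,
            panel.col0 + int(round(dc)) + 2, panel.col1 + int(round(dc)) - 2,
            reflectance=panel.reflectance,
        )

    calibrated = calibrate(stack, panel)
    vi = compute_vi_maps(calibrated, savi_l=savi_l)
    otsu = None
    try:
        otsu = suggest_threshold_otsu(vi.savi)
    except ValueError:
        pass
    logger.info(
        "scene %s/%s: SAVI threshold %.3f (Otsu suggestion: %s)",
        scene.location, scene.stage, savi_threshold,
        "n/a" if otsu is None else f"{otsu:.3f}",
    )
    mask = build_master_mask(vi.savi, savi_threshold)
    mask = exclude_flowers(mask, calibrated, crop=crop,
                           flower_min_visible_reflectance=flower_min_visible_reflectance)
    grid = segment_plots(layout, calibrated.shape)
    meta = scene.truth[["plot", "entry", "rep", "location"]]
    return extract_features(vi, mask, grid, layout, metadata=meta,
                            date=scene.stage, stage=scene.stage)


def assemble_features(per_scene: list[pd.DataFrame]) -> pd.DataFrame:
    """Pivot per-(location, stage) feature tables to one wide row per plot,
    feature columns suffixed with the stage."""
    by_stage: dict[str, list[pd.DataFrame]] = {}
    for t in per_scene:
        stage = t["stage"].iloc[0]
        feat_cols = [c for c in t.columns if c.startswith(("canopy_area", "mean_", "sum_"))]
        f = t.set_index(["location", "plot", "entry", "rep"])[feat_cols]
        f.columns = [f"{c}_{stage}" for c in f.columns]
        by_stage.setdefault(stage, []).append(f)
    stacked = [pd.concat(frames) for frames in by_stage.values()]
    return pd.concat(stacked, axis=1).reset_index()


def predict_yield(
    wide: pd.DataFrame,
    traits: pd.DataFrame,
    config: LassoConfig,
    group_cols: tuple[str, ...] = ("location",),
) -> dict:
    """Combined-data plot-mode and cultivar-mode lasso evaluation.

    Features and yield are standardized within each normalization group
    (location for combined data) and the groups pooled before model fitting.
    Cultivar mode first averages replicates per (entry, location).
    """
    feat_cols = [c for c in wide.columns if c.startswith(("canopy_area", "mean_", "sum_"))]
    df = wide.merge(traits[["location", "plot", "yield"]], on=["location", "plot"])
    norm, _ = normalize(df, feat_cols + ["yield"], group_cols=list(group_cols))
    plot_eval = evaluate_plot_mode(norm[feat_cols], norm["yield"], config)

    cult = (
        df.groupby(["entry", "location"], as_index=False)[feat_cols + ["yield"]].mean()
    )
    cult_group = [g for g in group_cols if g in cult.columns]
    cult_norm, _ = normalize(cult, feat_cols + ["yield"], group_cols=cult_group)
    cultivar_eval = evaluate_cultivar_mode(cult_norm[feat_cols], cult_norm["yield"], config)
    return {"plot": plot_eval, "cultivar": cultivar_eval}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _qc_overlay(vi_savi, grid, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(vi_savi, cmap="RdYlGn", interpolation="nearest")
    for poly in grid.cell_polygons:
        closed = np.vstack([poly, poly[:1]])
        ax.plot(closed[:, 1], closed[:, 0], "w-", lw=0.5)
    ax.set_title("SAVI with plot grid")
    fig.savefig(path, dpi=100, metadata={"Software": "pulsepheno"})
    plt.close(fig)


def _pred_obs_figure(predictions: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(predictions["observed"], predictions["predicted"], s=12)
    lo = min(predictions.min())
    hi = max(predictions.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.set_xlabel("observed yield (standardized)")
    ax.set_ylabel("predicted yield (standardized)")
    fig.savefig(path, dpi=100, metadata={"Software": "pulsepheno"})
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write artifacts plus a run manifest.

    Returns a dict with the simulated trial, feature table, correlation
    report, model evaluations and the manifest. Any stage failure raises with
    the stage name in the message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_name = "configure"
    try:
        cfg_dict = config.to_dict()
        cfg_dict["output_dir"] = "."  # keep artifacts independent of where they ran
        write_yaml(out / "config.yaml", cfg_dict)

        stage_name = "simulate"
        design = TrialDesign(
            n_entries=config.n_entries,
            plot_rows=config.plot_rows,
            plot_cols=config.plot_cols,
            n_replicates=config.n_replicates,
            n_locations=config.n_locations,
            crop=config.crop,
            seed=config.seed,
        )
        trial = simulate_trial(design, stages=config.stages,
                               signal_fraction=config.signal_fraction)
        for scn in trial.scenes:
            write_bandstack(out / f"ortho_{scn.location}_{scn.stage}.tif", scn.stack)
        trial.traits.to_csv(out / "traits.csv", index=False)
        trial.features_truth.to_csv(out / "truth_features.csv", index=False)
        logger.info("simulate: %d scenes, %d plots/location",
                    len(trial.scenes), len(trial.scenes[0].truth))

        stage_name = "extract"
        per_scene = []
        for scn in trial.scenes:
            tbl = process_scene(
                scn, config.savi_threshold, config.crop, config.savi_l,
                config.flower_min_visible_reflectance,
            )
            per_scene.append(tbl)
        long_table = pd.concat(per_scene, ignore_index=True)
        long_table.to_csv(out / "plot_features.csv", index=False)
        wide = assemble_features(per_scene)
        wide.to_csv(out / "plot_features_wide.csv", index=False)

        if config.write_qc:
            scn = trial.scenes[0]
            cal = calibrate(scn.stack, scn.panel)
            vi = compute_vi_maps(cal, savi_l=config.savi_l)
            _qc_overlay(vi.savi, segment_plots(scn.layout, cal.shape),
                        out / "qc_grid_overlay.png")

        stage_name = "correlate"
        feat_cols = [c for c in wide.columns if c.startswith(("canopy_area", "mean_", "sum_"))]
        merged = wide.merge(trial.traits.drop(columns=["entry", "rep"]),
                            on=["location", "plot"])
        reports = []
        for mode in ("plot", "cultivar"):
            reports.append(correlate(merged, feat_cols, ["yield", "f50", "pm"], mode=mode))
        corr = pd.concat(reports, ignore_index=True)
        corr.to_csv(out / "correlations.csv", index=False)

        stage_name = "predict"
        evals = predict_yield(wide, trial.traits, config.lasso)
        rows = []
        for mode, ev in evals.items():
            s = ev.summary()
            rows.append({"location": "combined", **s})
        pd.DataFrame(rows).to_csv(out / "model_evaluation.csv", index=False)
        model_json = {
            mode: {
                "summary": ev.summary(),
                "selection_frequency": ev.selection_frequency.round(6).to_dict(),
                "reported_features": ev.reported_features,
            }
            for mode, ev in evals.items()
        }
        (out / "model_evaluation.json").write_text(json.dumps(model_json, indent=2))
        if config.write_qc and evals["cultivar"].predictions is not None:
            _pred_obs_figure(evals["cultivar"].predictions, out / "pred_vs_obs.png")

        stage_name = "manifest"
        artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
        manifest = {
            "pulsepheno": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                yaml.safe_dump(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "elapsed_s": round(time.time() - t0, 2),
            "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
        }
        # elapsed time must not break byte-identity checks between runs
        checksum_view = {k: v for k, v in manifest.items() if k != "elapsed_s"}
        (out / "manifest.json").write_text(json.dumps(checksum_view, indent=2))
        logger.info("pipeline complete in %.1fs", time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    return {
        "trial": trial,
        "features": wide,
        "features_long": long_table,
        "correlations": corr,
        "evaluations": evals,
        "manifest": checksum_view,
    }
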