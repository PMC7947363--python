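"""Radiometric calibration and vegetation-index maps.

Five-band UAV orthomosaics arrive as digital numbers (DN). An in-scene
reflectance panel of known albedo converts DN to surface reflectance band by
band; the calibrated stack then yields per-pixel vegetation-index maps
(NDVI, GNDVI, SAVI, NDRE, TVI) used for canopy masking and plot features.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

BAND_ORDER = ("blue", "green", "red", "rededge", "nir")

__all__ = [
    "BAND_ORDER",
    "BandStack",
    "PanelReference",
    "VIMapSet",
    "calibrate",
    "compute_vi_maps",
]


@dataclass
class BandStack:
    """Co-registered five-band raster.

    ``data`` has shape ``(5, rows, cols)`` in the fixed band order
    blue, green, red, red-edge, NIR; pixel grid is row-major, 0-based,
    origin top-left. ``state`` is ``"raw"`` (digital numbers) or
    ``"calibrated"`` (reflectance, nominally in [0, ~1.2]).
    """

    data: np.ndarray
    state: str = "raw"
    bands: tuple[str, ...] = BAND_ORDER
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.bands):
            raise ValueError(
                f"expected ({len(self.bands)}, rows, cols) array, got {self.data.shape}"
            )
        if tuple(self.bands) != BAND_ORDER:
            missing = set(BAND_ORDER) - set(self.bands)
            if missing:
                raise ValueError(f"missing bands: {sorted(missing)}")
            # reorder to canonical band order
            idx = [self.bands.index(b) for b in BAND_ORDER]
            self.data = self.data[idx]
            self.bands = BAND_ORDER
        if self.state not in ("raw", "calibrated"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.data[self.bands.index(name)]

    def replace(self, **kwargs) -> "BandStack":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PanelReference:
    """Calibration-panel region (half-open pixel bounds) and its known albedo."""

    row0: int
    row1: int
    col0: int
    col1: int
    reflectance: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.reflectance <= 1.0):
            raise ValueError(f"panel reflectance must be in (0, 1], got {self.reflectance}")
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("panel region is empty")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


def calibrate(stack: BandStack, panel: PanelReference) -> BandStack:
    """Convert digital numbers to reflectance via the in-scene panel.

    Per band b: ``reflectance = DN * panel.reflectance / mean(DN over panel)``,
    a linear-through-origin model matching a linear camera response. The
    per-band panel means are logged in ``meta["panel_means"]``.

    Raises ``ValueError`` if the stack is already calibrated, the panel region
    lies outside the image, or a panel mean is non-positive (naming the band).
    """
    if stack.state != "raw":
        raise ValueError("stack is already calibrated")
    rows, cols = stack.shape
    if panel.row1 > rows or panel.col1 > cols or panel.row0 < 0 or panel.col0 < 0:
        raise ValueError("panel region lies outside the image")
    rs, cs = panel.slices()
    panel_means = {}
    out = np.empty_like(stack.data)
    for i, name in enumerate(stack.bands):
        m = float(np.nanmean(stack.data[i, rs, cs]))
        if not np.isfinite(m) or m <= 0:
            raise ValueError(f"degenerate panel mean in band {name!r}: {m}")
        panel_means[name] = m
        out[i] = stack.data[i] * (panel.reflectance / m)
    meta = dict(stack.meta)
    meta["panel_means"] = panel_means
    meta["panel_reflectance"] = panel.reflectance
    return BandStack(out, state="calibrated", meta=meta)


@dataclass
class VIMapSet:
    """One 2-D map per vegetation index, same shape as the source stack.

    Pixels with a zero denominator are NaN (missing), never 0, and are
    excluded from all downstream means and sums.
    """

    ndvi: np.ndarray
    gndvi: np.ndarray
    savi: np.ndarray
    ndre: np.ndarray
    tvi: np.ndarray
    savi_l: float = 0.5

    @property
    def maps(self) -> Mapping[str, np.ndarray]:
        return {
            "ndvi": self.ndvi,
            "gndvi": self.gndvi,
            "savi": self.savi,
            "ndre": self.ndre,
            "tvi": self.tvi,
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.ndvi.shape


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out[denom == 0] = np.nan
    return out


def compute_vi_maps(stack: BandStack, savi_l: float = 0.5) -> VIMapSet:
    """Compute NDVI, GNDVI, SAVI, NDRE and TVI maps from a calibrated stack.

    NDVI  = (NIR - R) / (NIR + R)
    GNDVI = (NIR - G) / (NIR + G)
    NDRE  = (NIR - RE) / (NIR + RE)
    SAVI  = (1 + L) (NIR - R) / (NIR + R + L), soil factor L = ``savi_l``
    TVI   = 0.5 [120 (NIR - G) - 200 (R - G)]
    """
    if stack.state != "calibrated":
        raise ValueError("vegetation indices require a calibrated stack")
    g = stack.band("green")
    r = stack.band("red")
    re = stack.band("rededge")
    nir = stack.band("nir")

    ndvi = _normalized_difference(nir, r)
    gndvi = _normalized_difference(nir, g)
    ndre = _normalized_difference(nir, re)

    denom = nir + r + savi_l
    with np.errstate(divide="ignore", invalid="ignore"):
        savi = (1.0 + savi_l) * (nir - r) / denom
    savi[denom == 0] = np.nan

    tvi = 0.5 * (120.0 * (nir - g) - 200.0 * (r - g))
    return VIMapSet(ndvi=ndvi, gndvi=gndvi, savi=savi, ndre=ndre, tvi=tvi, savi_l=savi_l)
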