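"""Plot segmentation and per-plot feature extraction.

The field orthomosaic is first rotated to near-axis alignment, a canopy
master mask is thresholded on the SAVI map (with white pea flowers excluded
by a visible-reflectance rule), the field quadrilateral given by four user
corners is split into a grid of plot cells, each cell's region of interest is
shrunk to avoid edge effects, and 11 features per plot are extracted: canopy
area (pixels) plus the mean and sum of each of the five vegetation indices
over the canopy pixels of the ROI.

Pixel convention throughout: row-major, 0-based, origin top-left; cell
membership is decided at pixel centres so cells tile the quadrilateral
disjointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import filters, transform

from .radiometric import BandStack, VIMapSet

__all__ = [
    "PlotLayout",
    "PlotGrid",
    "SHRINK_PRESETS",
    "rotate_stack",
    "rotate_mask",
    "build_master_mask",
    "suggest_threshold_otsu",
    "exclude_flowers",
    "segment_plots",
    "shrink_roi",
    "extract_features",
    "FEATURE_COLUMNS",
]

VI_NAMES = ("ndvi", "gndvi", "savi", "ndre", "tvi")
FEATURE_COLUMNS = ["canopy_area"] + [f"mean_{v}" for v in VI_NAMES] + [
    f"sum_{v}" for v in VI_NAMES
]

# Edge-shrink presets (top/bottom, left/right) in pixels used for the two
# acquisition eras (different ground sampling distances).
SHRINK_PRESETS = {"2017": (11, 28), "2018_2019": (20, 50)}


def _convex(corners: np.ndarray) -> bool:
    c = np.asarray(corners, dtype=float)
    signs = []
    for i in range(4):
        a, b, d = c[i], c[(i + 1) % 4], c[(i + 2) % 4]
        e1, e2 = b - a, d - b
        signs.append(np.sign(e1[0] * e2[1] - e1[1] * e2[0]))
    signs = [s for s in signs if s != 0]
    return len(signs) == 4 and len(set(signs)) == 1


@dataclass
class PlotLayout:
    """Field geometry: four corners, grid dimensions and ROI shrink margins.

    ``corners`` are four (row, col) points ordered TL, TR, BR, BL in the
    rotation-corrected frame and must form a convex quadrilateral.
    ``rotation_deg`` is the angle by which the raw image was (or must be)
    rotated before these corners apply.
    """

    corners: np.ndarray
    n_ranges: int
    n_plots_per_range: int
    shrink_tb: int = 20
    shrink_lr: int = 50
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (4, 2):
            raise ValueError("corners must be four (row, col) points")
        if not _convex(self.corners):
            raise ValueError("corners must form a convex quadrilateral (TL, TR, BR, BL)")
        if self.n_ranges < 1 or self.n_plots_per_range < 1:
            raise ValueError("grid dimensions must be at least 1x1")
        if self.shrink_tb < 0 or self.shrink_lr < 0:
            raise ValueError("shrink margins must be nonnegative")


def rotate_stack(stack: BandStack, degrees: float) -> BandStack:
    """Rotate every band by ``degrees`` (counter-clockwise) about the centre.

    The canvas expands to contain the rotated image; uncovered pixels are NaN
    (missing). Bands use bilinear interpolation. 0 degrees is the identity.
    """
    if not np.isfinite(degrees):
        raise ValueError("rotation angle must be finite")
    if degrees == 0.0:
        return stack
    rotated = [
        transform.rotate(
            band, degrees, resize=True, order=1, cval=np.nan,
            preserve_range=True, mode="constant",
        )
        for band in stack.data
    ]
    meta = dict(stack.meta)
    meta["rotated_deg"] = meta.get("rotated_deg", 0.0) + degrees
    return BandStack(np.stack(rotated), state=stack.state, meta=meta)


def rotate_mask(mask: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate a binary mask with nearest-neighbour interpolation, fill 0."""
    if degrees == 0.0:
        return mask
    out = transform.rotate(
        mask.astype(float), degrees, resize=True, order=0, cval=0.0,
        preserve_range=True, mode="constant",
    )
    return out > 0.5


def build_master_mask(savi_map: np.ndarray, threshold: float) -> np.ndarray:
    """Canopy master mask: SAVI strictly above ``threshold``; missing -> background."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        mask = savi_map > threshold
    return mask & np.isfinite(savi_map)


def suggest_threshold_otsu(savi_map: np.ndarray) -> float:
    """Otsu's threshold on the finite SAVI values — a logged suggestion only,
    never applied silently (the operator chooses the threshold)."""
    vals = savi_map[np.isfinite(savi_map)]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("SAVI map has no contrast for Otsu suggestion")
    return float(filters.threshold_otsu(vals))


def exclude_flowers(
    mask: np.ndarray,
    stack: BandStack,
    crop: str = "pea",
    flower_min_visible_reflectance: float = 0.35,
) -> np.ndarray:
    """Remove white-flower pixels from the canopy mask (dry pea only).

    White flowers are bright in every visible band, so a pixel whose minimum
    of blue, green and red reflectance exceeds the threshold is dropped. For
    chickpea the operation is the identity: its flowers are too small to
    resolve in the imagery, so no exclusion is applied.
    """
    if crop == "chickpea":
        return mask
    if stack.state != "calibrated":
        raise ValueError("flower exclusion needs a calibrated (reflectance) stack")
    visible = np.stack([stack.band(b) for b in ("blue", "green", "red")])
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        white = np.nanmin(visible, axis=0) > flower_min_visible_reflectance
    return mask & ~white


def _inverse_bilinear(points: np.ndarray, corners: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map points to unit-square coordinates (u along ranges, v along plots)
    of the bilinear patch spanned by corners TL, TR, BR, BL.

    Solves the per-point quadratic of the inverse bilinear map in closed form,
    vectorized over all points. Points outside the patch get coordinates
    outside [0, 1].
    """
    a, b, c, d = (corners[i] for i in range(4))
    e = b - a  # TL -> TR (v direction)
    f = d - a  # TL -> BL (u direction)
    g = a - b + c - d
    h = points - a

    def cross(p, q):
        return p[..., 0] * q[..., 1] - p[..., 1] * q[..., 0]

    k2 = cross(g, f)
    k1 = cross(h, g) + cross(e, f)
    k0 = cross(h, e)

    u = np.empty(len(points))
    area = abs(cross(e, f))
    if abs(k2) < 1e-12 * max(area, 1.0):
        # parallelogram: linear equation
        with np.errstate(divide="ignore", invalid="ignore"):
            u[:] = np.where(k1 != 0, -k0 / k1, np.nan)
    else:
        disc = k1 * k1 - 4.0 * k2 * k0
        disc = np.where(disc < 0, np.nan, disc)
        sq = np.sqrt(disc)
        u1 = (-k1 + sq) / (2.0 * k2)
        u2 = (-k1 - sq) / (2.0 * k2)
        # exactly one root lies in the patch for convex corners
        good1 = (u1 >= -1e-9) & (u1 <= 1.0 + 1e-9)
        u = np.where(good1, u1, u2)

    # v from whichever component of (E + u G) is better conditioned
    denom_r = e[0] + u * g[0]
    denom_c = e[1] + u * g[1]
    num_r = h[:, 0] - u * f[0]
    num_c = h[:, 1] - u * f[1]
    use_r = np.abs(denom_r) >= np.abs(denom_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(use_r, num_r / denom_r, num_c / denom_c)
    return u, v


@dataclass
class PlotGrid:
    """Rasterized plot cells: label image (-1 = outside the field) and the
    bilinear cell polygons, ordered range-major."""

    labels: np.ndarray
    n_ranges: int
    n_plots_per_range: int
    cell_polygons: list[np.ndarray]

    @property
    def n_cells(self) -> int:
        return self.n_ranges * self.n_plots_per_range

    def cell_mask(self, k: int) -> np.ndarray:
        return self.labels == k


def segment_plots(layout: PlotLayout, shape: tuple[int, int]) -> PlotGrid:
    """Split the field quadrilateral into ``n_ranges x n_plots_per_range`` cells.

    Cell (i, j) corners come from bilinear interpolation of the four field
    corners at fractions (i/n_ranges, j/n_plots_per_range). Membership is
    decided per pixel centre through the inverse bilinear map, so the cells
    are exactly disjoint and their union is exactly the set of pixels whose
    centre falls inside the quadrilateral. Cells are ordered range-major.
    """
    nr, nc = layout.n_ranges, layout.n_plots_per_range
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    centres = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    u, v = _inverse_bilinear(centres, layout.corners)

    finite = np.isfinite(u) & np.isfinite(v)
    u = np.where(finite, u, -1.0)
    v = np.where(finite, v, -1.0)
    inside = (u >= 0) & (u < 1) & (v >= 0) & (v < 1)
    i = np.clip((u * nr).astype(int), 0, nr - 1)
    j = np.clip((v * nc).astype(int), 0, nc - 1)
    labels = np.where(inside, i * nc + j, -1).reshape(rows, cols).astype(np.int32)

    def corner(ui: float, vj: float) -> np.ndarray:
        a, b, c, d = (layout.corners[k] for k in range(4))
        return ((1 - ui) * (1 - vj) * a + (1 - ui) * vj * b + ui * vj * c + ui * (1 - vj) * d)

    polys = []
    for ii in range(nr):
        for jj in range(nc):
            u0, u1 = ii / nr, (ii + 1) / nr
            v0, v1 = jj / nc, (jj + 1) / nc
            polys.append(np.array([corner(u0, v0), corner(u0, v1),
                                   corner(u1, v1), corner(u1, v0)]))
    return PlotGrid(labels=labels, n_ranges=nr, n_plots_per_range=nc, cell_polygons=polys)


def shrink_roi(
    cell_mask: np.ndarray, shrink_tb: int, shrink_lr: int, plot_id=None
) -> np.ndarray:
    """Contract a plot cell to its region of interest.

    The cell's bounding box loses ``shrink_tb`` rows at top and bottom and
    ``shrink_lr`` columns at left and right; the ROI is the contracted box
    intersected with the cell. Zero margins are the identity. Raises if the
    interior is empty, naming the plot.
    """
    rows = np.flatnonzero(cell_mask.any(axis=1))
    cols = np.flatnonzero(cell_mask.any(axis=0))
    label = "cell" if plot_id is None else f"plot {plot_id}"
    if rows.size == 0:
        raise ValueError(f"{label}: empty cell mask")
    r0, r1 = rows[0] + shrink_tb, rows[-1] + 1 - shrink_tb
    c0, c1 = cols[0] + shrink_lr, cols[-1] + 1 - shrink_lr
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"{label}: shrink margins ({shrink_tb}, {shrink_lr}) leave an empty interior"
        )
    roi = np.zeros_like(cell_mask)
    roi[r0:r1, c0:c1] = cell_mask[r0:r1, c0:c1]
    return roi


def extract_features(
    vi_maps: VIMapSet,
    canopy_mask: np.ndarray,
    grid: PlotGrid,
    layout: PlotLayout,
    metadata: pd.DataFrame | None = None,
    date: str = "",
    stage: str = "",
) -> pd.DataFrame:
    """Per-plot canopy area and mean/sum of each vegetation index.

    For each plot (range-major order): the ROI is the shrunk cell, canopy
    pixels are ``ROI & mask``, ``canopy_area`` is their count, and each VI
    contributes its mean and sum over those pixels (missing VI pixels are
    excluded). Plots with no canopy get area 0 and missing means/sums.
    ``metadata`` (optional) supplies one row per plot in the same order with
    columns such as plot, entry, rep, location.
    """
    if canopy_mask.shape != vi_maps.shape or grid.labels.shape != vi_maps.shape:
        raise ValueError("mask, grid and VI maps must share one shape")
    records = []
    for k in range(grid.n_cells):
        cell = grid.cell_mask(k)
        roi = shrink_roi(cell, layout.shrink_tb, layout.shrink_lr, plot_id=k)
        canopy = roi & canopy_mask
        area = int(canopy.sum())
        rec = {"plot": k, "entry": "", "rep": 0, "location": "",
               "date": date, "stage": stage, "canopy_area": area}
        for name, vi in vi_maps.maps.items():
            if area == 0:
                rec[f"mean_{name}"] = np.nan
                rec[f"sum_{name}"] = np.nan
            else:
                vals = vi[canopy]
                rec[f"mean_{name}"] = float(np.nanmean(vals))
                rec[f"sum_{name}"] = float(np.nansum(vals))
        records.append(rec)
    table = pd.DataFrame(records)
    if metadata is not None:
        meta = metadata.reset_index(drop=True)
        for col in ("plot", "entry", "rep", "location"):
            if col in meta.columns:
                table[col] = meta[col].to_numpy()
        if "date" in meta.columns and not date:
            table["date"] = meta["date"].to_numpy()
    cols = ["plot", "entry", "rep", "location", "date", "stage"] + FEATURE_COLUMNS
    return table[cols]
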