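"""Per-plot trait extraction from co-registered rasters.

Three plot-scale traits are extracted per growth stage:

* **PH** (plant height, cm) — the crop surface model (DSM − DEM) is masked to
  plant pixels by the NGRDI > 0 rule, reduced to a set of neighbourhood canopy
  maxima (max-aggregating resample + non-overlapping 3x3-window maxima), the
  maxima are interpolated by ordinary kriging, and the surface maximum is the
  representative plot height.  Averaging the raw canopy raster instead would
  mix upper-leaf and lower-leaf pixels and systematically underestimate PH;
  the maxima/kriging route keeps only upper-canopy evidence while still using
  the spatial arrangement of several plants.
* **CC** (canopy cover) — fraction of the shrunk plot polygon classified as
  plant by the NDVI > 0.1 rule.
* **NDVI** — mean NDVI over the plant pixels of the shrunk plot polygon.

Boundary conventions are strict: NGRDI = 0 and NDVI = 0.1 classify as
non-plant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .kriging import krige
from .raster import PlotROI, Raster


class NoPlantError(ValueError):
    """An operation needing plant pixels found none inside the ROI."""

    def __init__(self, plot_id: str, message: str | None = None):
        self.plot_id = plot_id
        super().__init__(message or f"plot {plot_id}: no plant pixels in ROI")


def _normalized_difference(a: Raster, b: Raster) -> Raster:
    a.require_same_grid(b)
    total = a.values + b.values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total != 0, (a.values - b.values) / total, np.nan)
    return a.with_values(out)


def compute_ngrdi(green: Raster, red: Raster) -> Raster:
    """Normalized green-red difference index; positive on vegetation."""
    return _normalized_difference(green, red)


def compute_ndvi(nir: Raster, red: Raster) -> Raster:
    """Normalized difference vegetation index in [-1, 1]."""
    return _normalized_difference(nir, red)


def plant_mask_from_ngrdi(ngrdi: Raster) -> Raster:
    """1 where NGRDI > 0 (plant), 0 where <= 0 (soil); nodata preserved."""
    v = ngrdi.values
    return ngrdi.with_values(np.where(np.isnan(v), np.nan, (v > 0).astype(float)))


def plant_mask_from_ndvi(ndvi: Raster, threshold: float = 0.1) -> Raster:
    """1 where NDVI > threshold (strict), 0 otherwise; nodata preserved."""
    v = ndvi.values
    return ndvi.with_values(np.where(np.isnan(v), np.nan, (v > threshold).astype(float)))


def compute_csm(dsm: Raster, dem: Raster) -> Raster:
    """Crop surface model: canopy height above ground (cm), DSM - DEM."""
    dsm.require_same_grid(dem)
    return dsm.with_values(dsm.values - dem.values)


@dataclass
class MaxPointSet:
    """Neighbourhood canopy maxima with world coordinates (m) and heights (cm)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __len__(self) -> int:
        return len(self.z)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def block_maxima(
    csm_ph: Raster, roi: PlotROI, resample_cell: float = 5.0, window: int = 3
) -> MaxPointSet:
    """Per-block canopy maxima of a plant-masked CSM inside the shrunk ROI.

    The CSM is resampled to ``resample_cell`` cm with max-preserving
    aggregation and tiled into non-overlapping ``window`` x ``window`` blocks;
    each block with at least one valid pixel emits the world coordinates and
    value of its maximum native pixel (so every emitted height is a CSM cell
    value at that exact location).  Partial edge blocks are kept.
    """
    if resample_cell < csm_ph.cell_size:
        raise ValueError("resample_cell must be >= the native cell size")
    sub = csm_ph.crop_to_bounds(roi.roi_plot.bounds)
    values = sub.values.copy()
    values[~roi.pixel_mask(sub, shrunk=True)] = np.nan

    factor = max(1, int(round(resample_cell / csm_ph.cell_size)))
    tile = factor * window  # native pixels per block
    n_rows, n_cols = values.shape
    pad_r = (-n_rows) % tile
    pad_c = (-n_cols) % tile
    padded = np.pad(values, ((0, pad_r), (0, pad_c)), constant_values=np.nan)
    R, C = padded.shape[0] // tile, padded.shape[1] // tile
    blocks = padded.reshape(R, tile, C, tile).transpose(0, 2, 1, 3).reshape(R, C, tile * tile)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN blocks
        block_max = np.nanmax(blocks, axis=2)
    valid = np.isfinite(block_max)
    if not valid.any():
        raise NoPlantError(roi.plot_id)
    flat = np.where(np.isnan(blocks), -np.inf, blocks)
    local = np.argmax(flat, axis=2)
    br, bc = np.nonzero(valid)
    i = br * tile + local[br, bc] // tile
    j = bc * tile + local[br, bc] % tile
    cs = sub.cell_m
    return MaxPointSet(
        x=sub.origin[0] + (j + 0.5) * cs,
        y=sub.origin[1] + (i + 0.5) * cs,
        z=block_max[br, bc],
    )


def krige_plot_height(
    points: MaxPointSet, roi: PlotROI, grid_cell: float = 10.0
) -> float:
    """Representative plot height: max of the kriged surface over the ROI.

    With fewer than 5 points there is no basis for a variogram fit and the
    maximum observed height is returned directly.
    """
    if len(points) == 0:
        raise ValueError(f"plot {roi.plot_id}: empty point set")
    if len(points) < 5:
        return float(points.z.max())
    minx, miny, maxx, maxy = roi.roi_plot.bounds
    step = grid_cell / 100.0
    gx = np.arange(minx + step / 2, maxx, step)
    gy = np.arange(miny + step / 2, maxy, step)
    xs, ys = np.meshgrid(gx, gy)
    inside = shapely.contains_xy(roi.roi_plot, xs.ravel(), ys.ravel())
    query = np.column_stack([xs.ravel()[inside], ys.ravel()[inside]])
    # data locations are appended so the exact-interpolation property
    # guarantees surface max >= max observed height
    query = np.vstack([query, points.xy]) if len(query) else points.xy
    pred = krige(points.xy, points.z, query)
    return float(pred.max())


@dataclass
class PHParams:
    """Tunables of the plant-height route (all lengths in cm)."""

    resample_cell: float = 5.0
    window: int = 3
    grid_cell: float = 10.0


@dataclass
class PlotPH:
    plot_id: str
    ph: float  # cm; NaN when status != "ok"
    status: str  # "ok" | "no-plant"
    n_points: int = 0


def extract_plot_ph(
    dsm: Raster, dem: Raster, green: Raster, red: Raster,
    roi: PlotROI, params: PHParams | None = None,
) -> PlotPH:
    """Full plant-height route for one plot; no-plant becomes a missing record."""
    params = params or PHParams()
    csm = compute_csm(dsm, dem)
    mask = plant_mask_from_ngrdi(compute_ngrdi(green, red))
    csm_ph = csm.with_values(np.where(mask.values == 1.0, csm.values, np.nan))
    try:
        pts = block_maxima(csm_ph, roi, params.resample_cell, params.window)
    except NoPlantError:
        return PlotPH(roi.plot_id, float("nan"), "no-plant")
    ph = krige_plot_height(pts, roi, params.grid_cell)
    return PlotPH(roi.plot_id, ph, "ok", n_points=len(pts))


def plot_cc(ndvi_mask: Raster, roi: PlotROI) -> float:
    """Canopy cover: plant-pixel fraction of the shrunk plot polygon."""
    sub = ndvi_mask.crop_to_bounds(roi.roi_plot.bounds)
    inside = roi.pixel_mask(sub, shrunk=True)
    if not inside.any():
        raise ValueError(f"plot {roi.plot_id}: ROI contains no pixels")
    vals = sub.values[inside]
    return float(np.nansum(vals == 1.0) / len(vals))


def plot_mean_ndvi(ndvi: Raster, ndvi_mask: Raster, roi: PlotROI) -> float:
    """Mean NDVI over plant pixels inside the shrunk plot polygon."""
    ndvi.require_same_grid(ndvi_mask)
    sub_ndvi = ndvi.crop_to_bounds(roi.roi_plot.bounds)
    sub_mask = ndvi_mask.crop_to_bounds(roi.roi_plot.bounds)
    inside = roi.pixel_mask(sub_ndvi, shrunk=True)
    plant = inside & (sub_mask.values == 1.0)
    if not plant.any():
        raise NoPlantError(roi.plot_id)
    return float(np.nanmean(sub_ndvi.values[plant]))


def extract_stage_traits(
    dsm: Raster, dem: Raster, bands: dict, plots: list[PlotROI],
    params: PHParams | None = None,
) -> pd.DataFrame:
    """CC, mean NDVI and PH for every plot of one growth stage.

    ``bands`` maps "green"/"red"/"nir" to co-registered reflectance rasters.
    Plots without plant pixels yield NaN traits with ``ph_status = "no-plant"``.
    """
    ndvi = compute_ndvi(bands["nir"], bands["red"])
    ndvi_mask = plant_mask_from_ndvi(ndvi)
    records = []
    for roi in plots:
        rec = {"plot_id": roi.plot_id, "genotype": roi.genotype, "group": roi.group}
        rec["cc"] = plot_cc(ndvi_mask, roi)
        try:
            rec["ndvi"] = plot_mean_ndvi(ndvi, ndvi_mask, roi)
        except NoPlantError:
            rec["ndvi"] = float("nan")
        res = extract_plot_ph(dsm, dem, bands["green"], bands["red"], roi, params)
        rec["ph"], rec["ph_status"], rec["n_points"] = res.ph, res.status, res.n_points
        records.append(rec)
    return pd.DataFrame(records)
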