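"""Single-band raster container and plot regions of interest.

World coordinates are metres, with x increasing along columns and y
increasing along rows (image convention: the origin is the top-left corner
of pixel (0, 0)).  Cell size is carried in cm/pixel because plant heights
and flight-resolution figures in this domain are conventionally quoted in
centimetres.  Missing data is NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape


class GridMismatchError(ValueError):
    """Rasters combined in one operation must share grid and extent."""


@dataclass
class Raster:
    """A rectangular single-band grid with a world transform.

    Parameters
    ----------
    values : 2D float array; NaN marks nodata.
    cell_size : pixel edge length in cm.
    origin : (x, y) world coordinates (m) of the top-left corner of pixel (0, 0).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2D grid")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_m(self) -> float:
        """Pixel edge length in metres."""
        return self.cell_size / 100.0

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "Raster") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}@{self.cell_size}cm/{self.origin} "
                f"vs {other.shape}@{other.cell_size}cm/{other.origin}"
            )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of every pixel center, as 2D arrays."""
        n_rows, n_cols = self.shape
        cs = self.cell_m
        x = self.origin[0] + (np.arange(n_cols) + 0.5) * cs
        y = self.origin[1] + (np.arange(n_rows) + 0.5) * cs
        return np.meshgrid(x, y)

    def window(self, row0: int, row1: int, col0: int, col1: int) -> "Raster":
        """Sub-raster over the half-open pixel range [row0:row1, col0:col1]."""
        row0, col0 = max(row0, 0), max(col0, 0)
        cs = self.cell_m
        return Raster(
            self.values[row0:row1, col0:col1].copy(),
            self.cell_size,
            (self.origin[0] + col0 * cs, self.origin[1] + row0 * cs),
        )

    def crop_to_bounds(self, bounds: tuple[float, float, float, float]) -> "Raster":
        """Smallest pixel-aligned window covering world bounds (minx, miny, maxx, maxy)."""
        minx, miny, maxx, maxy = bounds
        cs = self.cell_m
        col0 = int(np.floor((minx - self.origin[0]) / cs))
        col1 = int(np.ceil((maxx - self.origin[0]) / cs))
        row0 = int(np.floor((miny - self.origin[1]) / cs))
        row1 = int(np.ceil((maxy - self.origin[1]) / cs))
        n_rows, n_cols = self.shape
        return self.window(row0, min(row1, n_rows), col0, min(col1, n_cols))

    def with_values(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class PlotROI:
    """One breeding plot: identity, genotype/group labels and geometry.

    ``roi_plot`` is the plot polygon shrunk inward by ``border_shrink`` metres
    (0.25 m by default) so that leaves crossing plot borders late in the
    season do not contaminate neighbouring plots.
    """

    plot_id: str
    genotype: str
    group: str
    polygon: Polygon
    border_shrink: float = 0.25
    roi_plot: Polygon = field(init=False)

    def __post_init__(self) -> None:
        shrunk = self.polygon.buffer(-self.border_shrink, join_style="mitre")
        if shrunk.is_empty or shrunk.area <= 0:
            raise ValueError(
                f"plot {self.plot_id}: border shrink {self.border_shrink} m "
                "leaves no interior region"
            )
        self.roi_plot = shrunk

    def pixel_mask(self, raster: Raster, shrunk: bool = True) -> np.ndarray:
        """Boolean mask of raster pixels whose center lies inside the ROI."""
        poly = self.roi_plot if shrunk else self.polygon
        xs, ys = raster.pixel_centers()
        return shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(raster.shape)


# ---------------------------------------------------------------------------
# I/O: TIFF with grid metadata in the description tag; plots as GeoJSON.

_META_KEY = "uavtraits_grid"


def write_raster(path: str | Path, raster: Raster) -> None:
    import tifffile

    meta = {_META_KEY: {"cell_size_cm": raster.cell_size, "origin_m": list(raster.origin)}}
    tifffile.imwrite(path, raster.values.astype(np.float32), description=json.dumps(meta))


def read_raster(path: str | Path) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        values = tif.asarray().astype(float)
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc).get(_META_KEY, {})
    return Raster(
        values,
        cell_size=float(meta.get("cell_size_cm", 1.0)),
        origin=tuple(meta.get("origin_m", (0.0, 0.0))),
    )


def write_plots_geojson(path: str | Path, plots: list[PlotROI], extra: dict | None = None) -> None:
    """Plot polygons with genotype/group attributes as a GeoJSON FeatureCollection.

    ``extra`` maps plot_id -> additional properties (e.g. ground-truth values).
    """
    features = []
    for roi in plots:
        props = {
            "plot_id": roi.plot_id,
            "genotype": roi.genotype,
            "group": roi.group,
            "border_shrink_m": roi.border_shrink,
        }
        if extra and roi.plot_id in extra:
            props.update(extra[roi.plot_id])
        features.append(
            {"type": "Feature", "geometry": mapping(roi.polygon), "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_plots_geojson(path: str | Path) -> list[PlotROI]:
    data = json.loads(Path(path).read_text())
    plots = []
    for feat in data["features"]:
        props = feat["properties"]
        plots.append(
            PlotROI(
                plot_id=str(props["plot_id"]),
                genotype=str(props.get("genotype", props["plot_id"])),
                group=str(props.get("group", "GRP1")),
                polygon=shape(feat["geometry"]),
                border_shrink=float(props.get("border_shrink_m", 0.25)),
            )
        )
    return plots
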