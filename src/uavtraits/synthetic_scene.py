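"""Seeded synthetic maize-trial scenes and labeled trait time series.

The real inputs of this pipeline are photogrammetric products (DEM, per-stage
DSMs, reflectance bands) over a grid of small breeding plots.  No such imagery
ships with the package, so this module synthesises scenes with the statistical
structure the extraction stages assume and with exact ground truth attached:

* plots of 2.4 m x 2.0 m sown at 6 plants/m^2 in rows 0.6 m apart;
* each plant rendered as a truncated-paraboloid crown,
  h(r) = H * max(0, 1 - (r/R)^2), so the apex height H is known analytically;
* the canopy surface is the pointwise maximum over plant crowns added to a
  smooth low-relief DEM (DSM == DEM exactly on soil);
* uniform plant/soil reflectances chosen so that NGRDI > 0 and NDVI > 0.1
  hold exactly on canopy pixels and fail on soil.

Plant centers are snapped to pixel centers so that the rendered canopy
maximum equals the drawn apex height exactly; the truth table is filled from
the rendered rasters, making it a construction oracle for the extraction
stages.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .raster import PlotROI, Raster, write_plots_geojson, write_raster

GROUP_LABELS = ("GRP1", "GRP2", "GRP3", "GRP4")
#: field-trial mix of genetic-background groups (low/high stalk stiffness,
#: long growing period, mixed), matching a 107:28:163:90 plot split.
_GROUP_PROPS = (0.276, 0.072, 0.420, 0.232)

_DEFAULT_STAGES = (("S1", 24), ("S2", 44), ("S3", 57), ("S4", 84))
#: per-stage apex-height ranges (cm), spanning the spread a maize trial shows
#: from jointing to maturity.
_DEFAULT_HEIGHT_RANGES = {
    "S1": (5.0, 26.0),
    "S2": (69.0, 184.0),
    "S3": (117.0, 251.0),
    "S4": (148.0, 365.0),
}


def _index_ratio(a: float, b: float) -> float:
    """Normalized difference (a - b) / (a + b), 0 where undefined."""
    return (a - b) / (a + b) if a + b else 0.0


@dataclass
class SceneConfig:
    """Layout, canopy and radiometry parameters of a synthetic trial."""

    n_plot_rows: int = 2
    n_plot_cols: int = 2
    plot_width: float = 2.4  # m, along x (rows of plants run along y)
    plot_depth: float = 2.0  # m, along y
    border_shrink: float = 0.25  # m
    row_spacing: float = 0.6  # m
    plant_density: float = 6.0  # plants / m^2
    cell_size: float = 2.0  # cm / pixel
    stages: tuple = _DEFAULT_STAGES
    dem_relief_amplitude: float = 2.0  # cm, peak-to-peak
    plant_reflectance: dict = dc_field(
        default_factory=lambda: {"green": 0.12, "red": 0.06, "nir": 0.45}
    )
    soil_reflectance: dict = dc_field(
        default_factory=lambda: {"green": 0.10, "red": 0.12, "nir": 0.14}
    )
    height_range: dict = dc_field(default_factory=lambda: dict(_DEFAULT_HEIGHT_RANGES))
    crown_radius: float = 0.4  # m
    noise_sd: float = 2.0  # cm, per-plant apex jitter
    alley: float = 0.4  # m between adjacent plots
    margin: float = 0.5  # m of bare soil around the field
    #: optional explicit plants: plot_id -> [(x_m, y_m, apex_cm), ...],
    #: same apex at every stage; placed in addition to density-driven sowing.
    plants_override: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_plot_rows < 1 or self.n_plot_cols < 1:
            raise ValueError("field must contain at least one plot")
        if min(self.plot_width, self.plot_depth, self.row_spacing, self.crown_radius) <= 0:
            raise ValueError("plot dimensions, row spacing and crown radius must be positive")
        if self.plot_width - 2 * self.border_shrink <= 0:
            raise ValueError("border_shrink leaves no plot interior")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.plant_density < 0 or self.noise_sd < 0:
            raise ValueError("plant_density and noise_sd must be non-negative")
        for name, refl in (("plant", self.plant_reflectance), ("soil", self.soil_reflectance)):
            for band in ("green", "red", "nir"):
                if not 0.0 <= refl[band] <= 1.0:
                    raise ValueError(f"{name} {band} reflectance outside [0, 1]")
        p, s = self.plant_reflectance, self.soil_reflectance
        ngrdi_p = _index_ratio(p["green"], p["red"])
        ngrdi_s = _index_ratio(s["green"], s["red"])
        ndvi_p = _index_ratio(p["nir"], p["red"])
        ndvi_s = _index_ratio(s["nir"], s["red"])
        if not (ngrdi_p > 0 >= ngrdi_s):
            raise ValueError("reflectances do not separate plant from soil under NGRDI > 0")
        if not (ndvi_p > 0.1 >= ndvi_s):
            raise ValueError("reflectances do not separate plant from soil under NDVI > 0.1")
        das = [d for _, d in self.stages]
        if sorted(das) != das or len(set(das)) != len(das):
            raise ValueError("stage DAS must be strictly increasing")


@dataclass
class FieldScene:
    """A rendered trial: rasters, plot geometry and exact ground truth."""

    config: SceneConfig
    dem: Raster
    dsm: dict  # stage -> Raster (cm)
    bands: dict  # stage -> {"green"|"red"|"nir": Raster in [0, 1]}
    plots: list  # list[PlotROI]
    truth: pd.DataFrame  # columns: plot_id, stage, true_max_height_cm, true_plant_fraction

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_raster(out / "dem.tif", self.dem)
        for stage, ras in self.dsm.items():
            write_raster(out / f"dsm_{stage}.tif", ras)
        for stage, bands in self.bands.items():
            for name, ras in bands.items():
                write_raster(out / f"{name}_{stage}.tif", ras)
        truth_by_plot: dict[str, dict] = {}
        for rec in self.truth.to_dict("records"):
            truth_by_plot.setdefault(rec["plot_id"], {})[
                f"true_max_height_cm_{rec['stage']}"
            ] = rec["true_max_height_cm"]
        write_plots_geojson(out / "plots.geojson", self.plots, extra=truth_by_plot)
        self.truth.to_csv(out / "truth.csv", index=False)


def _smooth_relief(shape: tuple[int, int], amplitude_cm: float, rng: np.random.Generator,
                   sigma_px: float) -> np.ndarray:
    if amplitude_cm == 0:
        return np.zeros(shape)
    noise = gaussian_filter(rng.standard_normal(shape), sigma=sigma_px, mode="reflect")
    span = noise.max() - noise.min()
    if span == 0:
        return np.zeros(shape)
    return (noise - noise.min()) / span * amplitude_cm


def _sow_plot(cfg: SceneConfig, x0: float, y0: float, rng: np.random.Generator) -> np.ndarray:
    """Plant (x, y) positions for one plot with origin (x0, y0), jittered."""
    if cfg.plant_density == 0:
        return np.empty((0, 2))
    n_rows = max(1, int(round(cfg.plot_width / cfg.row_spacing)))
    row_x = x0 + cfg.plot_width / 2 + (np.arange(n_rows) - (n_rows - 1) / 2) * cfg.row_spacing
    in_row_spacing = 1.0 / (cfg.plant_density * cfg.row_spacing)
    n_per_row = max(1, int(round(cfg.plot_depth / in_row_spacing)))
    plant_y = y0 + cfg.plot_depth / 2 + (
        np.arange(n_per_row) - (n_per_row - 1) / 2
    ) * in_row_spacing
    xs, ys = np.meshgrid(row_x, plant_y)
    pos = np.column_stack([xs.ravel(), ys.ravel()])
    pos += rng.uniform(-0.04, 0.04, size=pos.shape)  # sowing jitter, well under spacing
    pos[:, 0] = np.clip(pos[:, 0], x0 + 0.05, x0 + cfg.plot_width - 0.05)
    pos[:, 1] = np.clip(pos[:, 1], y0 + 0.05, y0 + cfg.plot_depth - 0.05)
    return pos


def _render_crowns(canopy: np.ndarray, plants: np.ndarray, apexes: np.ndarray,
                   crown_radius_m: float, cell_m: float) -> None:
    """Add truncated-paraboloid crowns to ``canopy`` (pointwise max), in place.

    Plant centers are snapped to pixel centers so each apex value appears
    verbatim in the rendered surface.
    """
    n_rows, n_cols = canopy.shape
    r_px = crown_radius_m / cell_m
    half = int(np.ceil(r_px))
    for (x, y), apex in zip(plants, apexes):
        j0 = int(np.clip(np.floor(x / cell_m), 0, n_cols - 1))
        i0 = int(np.clip(np.floor(y / cell_m), 0, n_rows - 1))
        i_lo, i_hi = max(i0 - half, 0), min(i0 + half + 1, n_rows)
        j_lo, j_hi = max(j0 - half, 0), min(j0 + half + 1, n_cols)
        di = np.arange(i_lo, i_hi) - i0
        dj = np.arange(j_lo, j_hi) - j0
        r2 = (di[:, None] ** 2 + dj[None, :] ** 2) / r_px**2
        crown = apex * np.maximum(0.0, 1.0 - r2)
        patch = canopy[i_lo:i_hi, j_lo:j_hi]
        np.maximum(patch, crown, out=patch)


def generate_field_scene(cfg: SceneConfig, seed: int) -> FieldScene:
    """Render a full multi-stage trial from ``cfg``, deterministically per seed."""
    rng = np.random.default_rng(seed)
    cell_m = cfg.cell_size / 100.0
    field_w = 2 * cfg.margin + cfg.n_plot_cols * cfg.plot_width + (cfg.n_plot_cols - 1) * cfg.alley
    field_h = 2 * cfg.margin + cfg.n_plot_rows * cfg.plot_depth + (cfg.n_plot_rows - 1) * cfg.alley
    n_cols = int(np.ceil(field_w / cell_m))
    n_rows = int(np.ceil(field_h / cell_m))

    dem_values = _smooth_relief((n_rows, n_cols), cfg.dem_relief_amplitude, rng,
                                sigma_px=max(4.0, 0.5 / cell_m))
    dem = Raster(dem_values, cfg.cell_size)

    plots: list[PlotROI] = []
    plot_origins: dict[str, tuple[float, float]] = {}
    plot_plants: dict[str, np.ndarray] = {}
    plot_vigor: dict[str, float] = {}
    idx = 0
    for r in range(cfg.n_plot_rows):
        for c in range(cfg.n_plot_cols):
            idx += 1
            pid = f"P{idx:03d}"
            x0 = cfg.margin + c * (cfg.plot_width + cfg.alley)
            y0 = cfg.margin + r * (cfg.plot_depth + cfg.alley)
            group = GROUP_LABELS[rng.choice(4, p=_GROUP_PROPS)]
            plots.append(
                PlotROI(
                    plot_id=pid,
                    genotype=f"G{idx:03d}",
                    group=group,
                    polygon=box(x0, y0, x0 + cfg.plot_width, y0 + cfg.plot_depth),
                    border_shrink=cfg.border_shrink,
                )
            )
            plot_origins[pid] = (x0, y0)
            plot_plants[pid] = _sow_plot(cfg, x0, y0, rng)
            plot_vigor[pid] = rng.uniform(0.15, 0.85)

    # per plot x stage apex heights: plot vigor anchors the level within the
    # stage's range; per-plant jitter adds within-plot spread
    stage_apexes: dict[str, dict[str, np.ndarray]] = {}
    for stage, _das in cfg.stages:
        lo, hi = cfg.height_range.get(stage, (50.0, 200.0))
        per_plot = {}
        for roi in plots:
            plants = plot_plants[roi.plot_id]
            base = lo + plot_vigor[roi.plot_id] * (hi - lo)
            apexes = base + rng.normal(0.0, cfg.noise_sd, size=len(plants))
            per_plot[roi.plot_id] = np.clip(apexes, 0.0, None)
        stage_apexes[stage] = per_plot

    dsm: dict[str, Raster] = {}
    bands: dict[str, dict[str, Raster]] = {}
    truth_records = []
    p_refl, s_refl = cfg.plant_reflectance, cfg.soil_reflectance
    for stage, _das in cfg.stages:
        canopy = np.zeros((n_rows, n_cols))
        for roi in plots:
            _render_crowns(canopy, plot_plants[roi.plot_id],
                           stage_apexes[stage][roi.plot_id], cfg.crown_radius, cell_m)
            override = cfg.plants_override.get(roi.plot_id)
            if override:
                arr = np.asarray(override, dtype=float)
                _render_crowns(canopy, arr[:, :2], arr[:, 2], cfg.crown_radius, cell_m)
        dsm[stage] = Raster(dem_values + canopy, cfg.cell_size)
        plant_px = canopy > 0
        bands[stage] = {
            name: Raster(np.where(plant_px, p_refl[name], s_refl[name]), cfg.cell_size)
            for name in ("green", "red", "nir")
        }
        canopy_raster = Raster(canopy, cfg.cell_size)
        for roi in plots:
            # max height over the full plot; plant fraction over the shrunk
            # ROI, the same region canopy cover is measured on
            sub = canopy_raster.crop_to_bounds(roi.polygon.bounds)
            full = roi.pixel_mask(sub, shrunk=False)
            shrunk = roi.pixel_mask(sub, shrunk=True)
            truth_records.append(
                {
                    "plot_id": roi.plot_id,
                    "stage": stage,
                    "true_max_height_cm": float(sub.values[full].max()) if full.any() else 0.0,
                    "true_plant_fraction": float((sub.values[shrunk] > 0).mean())
                    if shrunk.any() else 0.0,
                }
            )
    truth = pd.DataFrame(truth_records)
    return FieldScene(config=cfg, dem=dem, dsm=dsm, bands=bands, plots=plots, truth=truth)


# ---------------------------------------------------------------------------
# Labeled trait time series with planted cluster structure.


@dataclass
class TraitSeriesSpec:
    """Planted-prototype specification for trait time-series fixtures.

    Each intended cluster contributes ``members_per_cluster[i]`` series equal
    to ``prototypes[i]`` plus i.i.d. Gaussian noise; each member's
    genetic-background group is drawn from the cluster's ``group_mixture`` row.
    """

    prototypes: np.ndarray  # (k, n_stages)
    members_per_cluster: tuple
    noise_sd: float
    group_mixture: np.ndarray | None = None  # (k, 4), rows sum to 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.prototypes = np.atleast_2d(np.asarray(self.prototypes, dtype=float))
        if self.prototypes.size == 0:
            raise ValueError("prototypes must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.members_per_cluster) != len(self.prototypes):
            raise ValueError("one member count per prototype required")
        if any(m < 1 for m in self.members_per_cluster):
            raise ValueError("each cluster needs at least one member")
        if self.group_mixture is None:
            self.group_mixture = np.full((len(self.prototypes), 4), 0.25)
        self.group_mixture = np.asarray(self.group_mixture, dtype=float)
        if self.group_mixture.shape != (len(self.prototypes), 4):
            raise ValueError("group_mixture must be (n_clusters, 4)")
        if not np.allclose(self.group_mixture.sum(axis=1), 1.0):
            raise ValueError("group_mixture rows must sum to 1")


def generate_trait_matrix(spec: TraitSeriesSpec):
    """Build (TraitMatrix, true_labels, group_labels) from planted prototypes."""
    from .shape_clustering import TraitMatrix

    rng = np.random.default_rng(spec.seed)
    series, true_labels, groups = [], [], []
    for ci, (proto, m) in enumerate(zip(spec.prototypes, spec.members_per_cluster)):
        noise = rng.normal(0.0, spec.noise_sd, size=(m, len(proto)))
        series.append(proto[None, :] + noise)
        true_labels.extend([ci] * m)
        groups.extend(
            GROUP_LABELS[g] for g in rng.choice(4, size=m, p=spec.group_mixture[ci])
        )
    matrix = np.vstack(series)
    names = [f"G{i + 1:03d}" for i in range(len(matrix))]
    true_labels = np.asarray(true_labels)
    group_labels = np.asarray(groups)
    tm = TraitMatrix(
        series=matrix, trait="synthetic", names=names,
        groups=group_labels, true_labels=true_labels,
    )
    return tm, true_labels, group_labels
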