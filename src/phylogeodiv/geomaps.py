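"""Range rasterization and per-pixel diversity maps.

Species ranges are rasterized onto a shared lon/lat grid (cell membership by
cell-center test on half-open cells), per-species metrics are stacked into
per-pixel sum/mean/SD/richness maps, sampling polygons (bounding boxes of
sampled coordinates clipped to the range) yield the proportion of each range
that was genetically sampled, and study richness can be divided by a total
richness layer.  Grids are plain 2-D arrays with row 0 at the southern edge;
I/O uses the ESRI ASCII-grid format (ncols/nrows/xllcorner/yllcorner/
cellsize header).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "GridStack",
    "rasterize_range",
    "stack_stats",
    "sampling_polygon",
    "proportion_species_sampled",
    "block_aggregate",
    "read_ascii_grid",
    "write_ascii_grid",
    "render_heatmap",
]


class GeoError(ValueError):
    """Raised for invalid grid input."""


@dataclass(frozen=True)
class GridSpec:
    """A lon/lat raster grid: origin at the lower-left (south-west) corner.

    Cells are half-open intervals [edge, edge + cell_size) in both axes and
    are indexed (row, col) with row 0 at the southern edge.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.ncols < 1 or self.nrows < 1:
            raise GeoError("invalid grid specification")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lons = self.origin_lon + (np.arange(self.ncols) + 0.5) * self.cell_size
        lats = self.origin_lat + (np.arange(self.nrows) + 0.5) * self.cell_size
        return lons, lats

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        col = int(math.floor((lon - self.origin_lon) / self.cell_size))
        row = int(math.floor((lat - self.origin_lat) / self.cell_size))
        return row, col

    def cell_areas(self, geographic: bool = True) -> np.ndarray:
        """Per-row cell areas; cosine-latitude weighted for geographic grids."""
        _, lats = self.cell_centers()
        if geographic:
            w = np.cos(np.radians(lats))
        else:
            w = np.ones_like(lats)
        return np.repeat(w[:, None], self.ncols, axis=1)


@dataclass
class GridStack:
    """Aligned per-species presence grids with one metric value per species."""

    spec: GridSpec
    presence: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for sp, g in self.presence.items():
            if g.shape != self.spec.shape:
                raise GeoError(f"presence grid for {sp!r} has wrong shape")
            if not np.isin(g, (0, 1)).all():
                raise GeoError(f"presence grid for {sp!r} must be 0/1")


def rasterize_range(
    rect: tuple[float, float, float, float], spec: GridSpec
) -> np.ndarray:
    """Presence grid for a rectangular range (lon_min, lon_max, lat_min, lat_max).

    A cell is present iff its center lies inside the rectangle.  A rectangle
    that covers no cell center yields an all-zero grid with a warning.
    """
    lon0, lon1, lat0, lat1 = rect
    if lon1 <= lon0 or lat1 <= lat0:
        raise GeoError("rectangle must have positive extent")
    lons, lats = spec.cell_centers()
    in_lon = (lons >= lon0) & (lons < lon1)
    in_lat = (lats >= lat0) & (lats < lat1)
    grid = (in_lat[:, None] & in_lon[None, :]).astype(np.uint8)
    if grid.sum() == 0:
        warnings.warn("range covers no cell center; presence grid is empty")
    return grid


def stack_stats(
    stack: GridStack, metric: dict[str, float]
) -> dict[str, np.ndarray]:
    """Per-pixel sum, mean, population SD, and richness of a metric.

    For each cell the statistics run over the species present there; cells
    with no species are NaN (richness 0); single-species cells have SD 0.
    """
    missing = [sp for sp in stack.presence if sp not in metric]
    if missing:
        raise GeoError(f"metric missing for species: {sorted(missing)}")
    shape = stack.spec.shape
    richness = np.zeros(shape)
    total = np.zeros(shape)
    total_sq = np.zeros(shape)
    for sp, pres in stack.presence.items():
        v = float(metric[sp])
        richness += pres
        total += pres * v
        total_sq += pres * v * v
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(richness > 0, total / richness, np.nan)
        var = np.where(richness > 0, total_sq / richness - mean**2, np.nan)
        sd = np.sqrt(np.clip(var, 0.0, None))
    out_sum = np.where(richness > 0, total, np.nan)
    return {"sum": out_sum, "mean": mean, "sd": sd, "richness": richness}


def sampling_polygon(
    coords: np.ndarray,
    presence: np.ndarray,
    spec: GridSpec,
    geographic: bool = True,
) -> tuple[np.ndarray, float]:
    """Sampled-area grid and proportion of range sampled.

    The sampling polygon is the axis-aligned bounding box of the sampled
    (lat, lon) coordinates, rasterized and intersected with the species'
    presence grid.  The proportion sampled is the area-weighted sampled cell
    count over the range cell count (cosine-latitude weights on geographic
    grids).  With no coordinate inside the range the proportion is 0.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 1:
        raise GeoError("coords must be an (n, 2) array of (lat, lon)")
    if presence.shape != spec.shape:
        raise GeoError("presence grid does not match grid spec")
    lat0, lat1 = coords[:, 0].min(), coords[:, 0].max()
    lon0, lon1 = coords[:, 1].min(), coords[:, 1].max()
    eps = spec.cell_size * 1e-9
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        box = rasterize_range((lon0 - eps, lon1 + eps, lat0 - eps, lat1 + eps),
                              spec)
    sampled = box * presence
    areas = spec.cell_areas(geographic=geographic)
    range_area = float((presence * areas).sum())
    if range_area == 0:
        raise GeoError("presence grid is empty")
    prop = float((sampled * areas).sum() / range_area)
    if sampled.sum() == 0:
        warnings.warn("no sampled coordinate falls inside the range")
        prop = 0.0
    return sampled, prop


def proportion_species_sampled(
    study_richness: np.ndarray, total_richness: np.ndarray
) -> np.ndarray:
    """Per-cell study/total richness; 0/0 cells are NaN."""
    if study_richness.shape != total_richness.shape:
        raise GeoError("richness grids must be aligned")
    if (total_richness < study_richness).any():
        raise GeoError("total richness below study richness in some cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total_richness > 0,
                       study_richness / total_richness, np.nan)
    return out


def block_aggregate(grid: np.ndarray, factor: int) -> np.ndarray:
    """Mean within factor x factor blocks (NaN-aware), trimming the remainder.

    Exposed for coarse-graining maps to absorb range-map uncertainty.
    """
    if factor < 1:
        raise GeoError("aggregation factor must be >= 1")
    nr, nc = grid.shape
    nr2, nc2 = nr // factor, nc // factor
    trimmed = grid[: nr2 * factor, : nc2 * factor]
    blocks = trimmed.reshape(nr2, factor, nc2, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(blocks, axis=(1, 3))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(grid: np.ndarray, spec: GridSpec, path: str | Path,
                     nodata: float = -9999.0) -> None:
    if grid.shape != spec.shape:
        raise GeoError("grid does not match spec")
    out = np.where(np.isnan(grid), nodata, grid)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.origin_lon!r}\n"
        f"yllcorner {spec.origin_lat!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    # ASCII grids store row 0 at the NORTH edge; flip our south-up layout
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    header = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    spec = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"],
        cell_size=header["cellsize"],
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
    )
    data = np.atleast_2d(data)[::-1]  # back to south-up
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    if data.shape != spec.shape:
        raise GeoError(f"grid shape {data.shape} does not match header")
    return data, spec


def render_heatmap(grid: np.ndarray, spec: GridSpec, path: str | Path,
                   title: str = "") -> None:
    """Optional PNG rendering of a metric map (warm colors = high values)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    extent = (
        spec.origin_lon, spec.origin_lon + spec.ncols * spec.cell_size,
        spec.origin_lat, spec.origin_lat + spec.nrows * spec.cell_size,
    )
    im = ax.imshow(grid, origin="lower", extent=extent, cmap="inferno",
                   aspect="auto")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
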