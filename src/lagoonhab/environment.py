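"""Environmental covariates on the 500-m analysis grid.

The grid covers the lagoon and extends 2.5 km seaward of the barrier reef.
Per cell: log median depth and slope, Euclidean distances (km) to the coast
(islets under 1 km² excluded), to the barrier reef (signed, negative
seaward), to the nearest intermediate reef patch and to the nearest seagrass
patch, and percent seagrass coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .core import LagoonGeometry, Raster

log = logging.getLogger(__name__)

ISLET_EXCLUSION_KM2 = 1.0


@dataclass
class GridDefinition:
    origin: tuple[float, float]
    resolution: float
    nrow: int
    ncol: int
    cells: pd.DataFrame  # cell_id, row, col, x, y (centroid), water_fraction

    def cell_of(self, x, y) -> np.ndarray:
        """Row-major cell id containing each point (-1 outside)."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        j = np.floor((x - self.origin[0]) / self.resolution).astype(int)
        i = np.floor((y - self.origin[1]) / self.resolution).astype(int)
        ok = (i >= 0) & (i < self.nrow) & (j >= 0) & (j < self.ncol)
        out = np.where(ok, i * self.ncol + j, -1)
        return out


def build_grid(
    geometry: LagoonGeometry,
    resolution: float = 500.0,
    offshore_buffer: float = 2500.0,
) -> GridDefinition:
    """Lay a row-major 500-m grid over the lagoon plus an offshore fringe.

    Cells fully on land get water_fraction 0 and are excluded; cells whose
    centroid lies more than ``offshore_buffer`` beyond the barrier reef are
    dropped.
    """
    bounds = geometry.domain.bounds
    if bounds[2] - bounds[0] < 1000:
        raise ValueError("geometry does not look projected in metres")
    land = geometry.land_union()
    barrier = geometry.barrier_union()

    x0 = np.floor(bounds[0] / resolution) * resolution
    y0 = np.floor(bounds[1] / resolution) * resolution
    ncol = int(np.ceil((bounds[2] - x0) / resolution))
    nrow = int(np.ceil((bounds[3] - y0) / resolution))

    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cx = x0 + (jj + 0.5) * resolution
    cy = y0 + (ii + 0.5) * resolution
    pts = shapely.points(cx.ravel(), cy.ravel())

    seaward = geometry.is_seaward(cx.ravel(), cy.ravel())
    d_bar = shapely.distance(pts, barrier)
    keep = ~(seaward & (d_bar > offshore_buffer))

    # water fraction: 1 unless the cell touches land
    wf = np.ones(pts.shape[0])
    on_land = shapely.covers(land, pts)
    near = shapely.dwithin(pts, land, resolution)  # candidates for partial overlap
    cand = np.flatnonzero(near & keep)
    if len(cand):
        boxes = shapely.box(
            cx.ravel()[cand] - resolution / 2,
            cy.ravel()[cand] - resolution / 2,
            cx.ravel()[cand] + resolution / 2,
            cy.ravel()[cand] + resolution / 2,
        )
        inter = shapely.area(shapely.intersection(boxes, land))
        wf[cand] = 1.0 - inter / resolution**2
    wf[on_land & ~near] = 0.0

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(nrow * ncol),
            "row": ii.ravel(),
            "col": jj.ravel(),
            "x": cx.ravel(),
            "y": cy.ravel(),
            "water_fraction": np.clip(wf, 0.0, 1.0),
        }
    )
    cells = cells[keep & (cells["water_fraction"].to_numpy() > 0)].reset_index(drop=True)
    return GridDefinition((x0, y0), resolution, nrow, ncol, cells)


def compute_slope(bathymetry: Raster) -> Raster:
    """Seabed slope in degrees from central differences (one-sided at edges).

    NaN cells (land) propagate to their neighbourhood.
    """
    z = bathymetry.data
    gy, gx = np.gradient(z, bathymetry.res)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return Raster(slope, bathymetry.x0, bathymetry.y0, bathymetry.res)


def derive_covariates(
    grid: GridDefinition,
    bathymetry: Raster,
    geometry: LagoonGeometry,
) -> pd.DataFrame:
    """Per-cell covariate table keyed by cell_id.

    Median depth/slope aggregate the bathymetry cells whose centres fall in
    the grid cell, then log(x + 1). Distances are centroid-to-nearest-geometry
    Euclidean, in km. Cells with no bathymetry coverage are dropped (count
    logged).
    """
    if bathymetry.res > grid.resolution:
        raise ValueError("bathymetry must be at least as fine as the grid")
    cells = grid.cells
    cx, cy = cells["x"].to_numpy(), cells["y"].to_numpy()
    pts = shapely.points(cx, cy)

    # raster-cell medians within each grid cell
    slope = compute_slope(bathymetry)
    bx, by = bathymetry.cell_centers()
    cell_ids = grid.cell_of(bx.ravel(), by.ravel())
    depth_flat, slope_flat = bathymetry.data.ravel(), slope.data.ravel()
    ok = (cell_ids >= 0) & ~np.isnan(depth_flat)
    med = (
        pd.DataFrame(
            {"cell_id": cell_ids[ok], "depth": depth_flat[ok], "slope": slope_flat[ok]}
        )
        .groupby("cell_id")
        .median()
    )

    # mainland + large islets only
    big_land = [geometry.coastline] + [
        g for g in geometry.islets if g.area / 1e6 >= ISLET_EXCLUSION_KM2
    ]
    coast = unary_union(big_land)
    barrier = geometry.barrier_union()
    seaward = geometry.is_seaward(cx, cy)

    d_coast = shapely.distance(pts, coast) / 1000.0
    d_bar = shapely.distance(pts, barrier) / 1000.0
    d_bar_signed = np.where(seaward, -d_bar, d_bar)

    if geometry.intermediate_reefs:
        reefs = unary_union(geometry.intermediate_reefs)
        d_reef = shapely.distance(pts, reefs) / 1000.0
    else:
        d_reef = np.full(len(cells), np.nan)

    if geometry.seagrass:
        sg = unary_union([g for g, _ in geometry.seagrass])
        d_sg = shapely.distance(pts, sg) / 1000.0
        cov = np.zeros(len(cells))
        near = shapely.dwithin(pts, sg, grid.resolution)
        cand = np.flatnonzero(near)
        if len(cand):
            half = grid.resolution / 2
            boxes = shapely.box(cx[cand] - half, cy[cand] - half, cx[cand] + half, cy[cand] + half)
            cov[cand] = shapely.area(shapely.intersection(boxes, sg)) / grid.resolution**2 * 100.0
    else:
        d_sg = np.full(len(cells), np.nan)
        cov = np.zeros(len(cells))

    tab = pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "x": cx,
            "y": cy,
            "water_fraction": cells["water_fraction"].to_numpy(),
            "dist_coast": d_coast,
            "dist_barrier_signed": d_bar_signed,
            "dist_reef": d_reef,
            "dist_seagrass": d_sg,
            "seagrass_cov": np.clip(cov, 0.0, 100.0),
        }
    ).set_index("cell_id")
    tab = tab.join(med, how="left")
    n_missing = int(tab["depth"].isna().sum())
    if n_missing:
        log.warning("dropping %d grid cells without bathymetry coverage", n_missing)
        tab = tab.dropna(subset=["depth"])
    tab["depth_log"] = np.log(tab["depth"] + 1.0)
    tab["slope_log"] = np.log(tab["slope"] + 1.0)
    return tab.reset_index()
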