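"""Shared spatial containers: a lightweight metric raster and the lagoon geometry bundle.

All coordinates live in a local projected plane in metres (x east, y north).
Geographic coordinates appear only at I/O boundaries, through a fixed affine
anchor (`LOCAL_ORIGIN_LONLAT`), which is adequate for a synthetic study area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

#: lon/lat anchored near the New Caledonian west coast; metres-per-degree at -21.5S
LOCAL_ORIGIN_LONLAT = (164.5, -22.2)
_M_PER_DEG_LAT = 110_852.0
_M_PER_DEG_LON = 103_663.0
#: fixed local timezone offset (hours east of UTC) for all synthetic timestamps
UTC_OFFSET_H = 11


def xy_to_lonlat(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lon0, lat0 = LOCAL_ORIGIN_LONLAT
    return lon0 + np.asarray(x) / _M_PER_DEG_LON, lat0 + np.asarray(y) / _M_PER_DEG_LAT


@dataclass
class Raster:
    """Row-major grid of values on a regular metric lattice.

    ``data[i, j]`` covers the square ``[x0 + j*res, x0 + (j+1)*res) x
    [y0 + i*res, y0 + (i+1)*res)``; row 0 is the southernmost row.
    """

    data: np.ndarray
    x0: float
    y0: float
    res: float

    @property
    def nrow(self) -> int:
        return self.data.shape[0]

    @property
    def ncol(self) -> int:
        return self.data.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.ncol) + 0.5) * self.res
        ys = self.y0 + (np.arange(self.nrow) + 0.5) * self.res
        return np.meshgrid(xs, ys)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup; NaN outside the raster extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        j = np.floor((x - self.x0) / self.res).astype(int)
        i = np.floor((y - self.y0) / self.res).astype(int)
        ok = (i >= 0) & (i < self.nrow) & (j >= 0) & (j < self.ncol)
        out = np.full(x.shape, np.nan)
        out[ok] = self.data[i[ok], j[ok]]
        return out

    def to_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        header = (
            f"ncols {self.ncol}\nnrows {self.nrow}\n"
            f"xllcorner {self.x0}\nyllcorner {self.y0}\n"
            f"cellsize {self.res}\nNODATA_value -9999\n"
        )
        body = np.where(np.isnan(self.data), -9999.0, self.data)
        with open(path, "w") as fh:
            fh.write(header)
            # ASCII grids are written north-to-south
            np.savetxt(fh, body[::-1], fmt="%.4f")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                k, v = fh.readline().split()
                meta[k.lower()] = float(v)
            body = np.loadtxt(fh)
        body = np.atleast_2d(body)[::-1].copy()
        body[body == meta["nodata_value"]] = np.nan
        return cls(body, meta["xllcorner"], meta["yllcorner"], meta["cellsize"])


@dataclass
class Pass:
    """A navigable gap in the barrier reef."""

    x_mid: float
    y_mid: float
    width_km: float


@dataclass
class LagoonGeometry:
    """Vector layers describing a reef-lagoon corridor in a metric plane.

    ``coastline`` is the mainland polygon (land), ``islets`` are detached land
    patches, ``barrier_reef`` the emergent outer reef segments (passes are the
    gaps between them), ``intermediate_reefs`` shallow patch reefs inside the
    lagoon, and ``seagrass`` shallow (<5 m) meadow polygons with a density
    class. ``lagoon`` is the water polygon between the coastline and the
    barrier; everything seaward of the barrier is open ocean / fore-reef shelf.
    """

    coastline: BaseGeometry
    barrier_reef: list[BaseGeometry]
    passes: list[Pass]
    intermediate_reefs: list[BaseGeometry]
    islets: list[BaseGeometry]
    seagrass: list[tuple[BaseGeometry, str]]
    lagoon: BaseGeometry
    domain: BaseGeometry
    crs: str = "local-metric"
    region_truth: dict = field(default_factory=dict)
    pass_channels: list = field(default_factory=list)

    def land_union(self):
        from shapely.ops import unary_union

        return unary_union([self.coastline, *self.islets])

    def barrier_union(self):
        from shapely.ops import unary_union

        return unary_union(self.barrier_reef)

    def is_seaward(self, x, y) -> np.ndarray:
        """True where a point lies ocean-side of the barrier reef."""
        import shapely

        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        inside = shapely.covers(self.lagoon, pts) | shapely.covers(self.land_union(), pts)
        inside |= shapely.covers(self.barrier_union(), pts)
        for ch in self.pass_channels:
            inside |= shapely.covers(ch, pts)
        return ~np.atleast_1d(inside)

    def write_geojson(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        layers = {
            "coastline": [self.coastline],
            "islets": self.islets,
            "barrier_reef": self.barrier_reef,
            "intermediate_reefs": self.intermediate_reefs,
            "lagoon": [self.lagoon],
        }
        for name, geoms in layers.items():
            _dump_geojson(outdir / f"{name}.geojson", geoms)
        _dump_geojson(
            outdir / "seagrass.geojson",
            [g for g, _ in self.seagrass],
            props=[{"density": d} for _, d in self.seagrass],
        )
        with open(outdir / "passes.json", "w") as fh:
            json.dump(
                [{"x_mid": p.x_mid, "y_mid": p.y_mid, "width_km": p.width_km} for p in self.passes],
                fh,
                indent=1,
            )


def _dump_geojson(path, geoms, props=None) -> None:
    feats = []
    for i, g in enumerate(geoms):
        feats.append(
            {
                "type": "Feature",
                "properties": (props[i] if props else {}),
                "geometry": mapping(g),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path) -> list[BaseGeometry]:
    with open(path) as fh:
        fc = json.load(fh)
    return [shape(f["geometry"]) for f in fc["features"]]


def as_local_time(ts) -> "np.ndarray":
    """Hours-of-day (float) of naive local timestamps."""
    import pandas as pd

    ts = pd.DatetimeIndex(ts)
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0
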