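"""Ecoregion delineation: slice the lagoon corridor, summarize each slice on
nine topographic variables, and cluster slices with Ward's method.

Slices are parallel bands angled at 45 degrees to the coastline's principal
axis; the number of bands is the corridor's along-axis extent divided by the
nominal slice width. Candidate partitions (k = 3, 4, 5 by default) are scored
by mean silhouette width; clusters are not constrained to be spatially
contiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.cluster.hierarchy import fcluster, linkage
from shapely.geometry import Point
from shapely.ops import unary_union
from sklearn.metrics import silhouette_score

from .core import LagoonGeometry

log = logging.getLogger(__name__)

PROFILE_VARS = [
    "dist_reef_mean",
    "dist_reef_sd",
    "slope_mean",
    "slope_sd",
    "depth_mean",
    "depth_sd",
    "mean_northing",
    "surface_area_km2",
    "barrier_opening_km",
]


def _principal_axis(geometry: LagoonGeometry) -> float:
    """Angle (radians) of the least-squares principal axis of the coastline."""
    xy = shapely.get_coordinates(geometry.coastline.exterior)
    xy = xy - xy.mean(axis=0)
    cov = xy.T @ xy
    w, v = np.linalg.eigh(cov)
    ax = v[:, np.argmax(w)]
    return float(np.arctan2(ax[1], ax[0]))


def slice_lagoon(
    geometry: LagoonGeometry,
    width: float = 20_000.0,
    angle_deg: float = 45.0,
) -> pd.DataFrame:
    """Cut the analysis domain into ordered bands at ``angle_deg`` to the
    coastline's principal axis.

    Returns a frame with slice_id (ordered along-coast) and polygon. A domain
    shorter than one slice yields a single slice (warning).
    """
    alpha = _principal_axis(geometry)
    u = np.array([np.cos(alpha), np.sin(alpha)])
    # band-normal direction: boundary lines at angle_deg to the axis
    beta = alpha + np.radians(angle_deg) + np.pi / 2
    n = np.array([np.cos(beta), np.sin(beta)])

    lag_xy = shapely.get_coordinates(geometry.lagoon.exterior)
    # anchor the band grid on the shared coast curve, so slice edges are set
    # by the along-coast extent rather than the seaward tilt of the bands
    coast_curve = shapely.intersection(
        geometry.lagoon.exterior, geometry.coastline.exterior
    )
    coast_xy = shapely.get_coordinates(coast_curve)
    if len(coast_xy) < 2:
        coast_xy = lag_xy
    axis_extent = np.ptp(coast_xy @ u)
    n_slices = int(round(axis_extent / width))
    if n_slices < 1:
        log.warning("domain shorter than one slice; returning a single slice")
        n_slices = 1

    c_coast = coast_xy @ n
    dom_xy_all = shapely.get_coordinates(geometry.domain.exterior)
    c_dom = dom_xy_all @ n
    edges = np.linspace(c_coast.min(), c_coast.max(), n_slices + 1)
    edges[0] = min(edges[0], c_dom.min()) - 1.0
    edges[-1] = max(edges[-1], c_dom.max()) + 1.0

    dom = geometry.domain
    dom_xy = shapely.get_coordinates(dom.exterior)
    half_diag = np.ptp(dom_xy @ u) + np.ptp(dom_xy @ n)
    center = dom_xy.mean(axis=0)

    m = np.array([-n[1], n[0]])  # boundary-line direction (45 deg to the axis)
    rows = []
    for k in range(n_slices):
        lo, hi = edges[k], edges[k + 1]
        band = shapely.polygons(
            np.array(
                [
                    center + n * (lo - center @ n) + m * half_diag,
                    center + n * (lo - center @ n) - m * half_diag,
                    center + n * (hi - center @ n) - m * half_diag,
                    center + n * (hi - center @ n) + m * half_diag,
                ]
            )
        )
        poly = shapely.intersection(band, dom)
        if shapely.is_empty(poly):
            continue
        order_key = float(shapely.centroid(poly).coords[0] @ u)
        rows.append({"polygon": poly, "order_key": order_key, "c_lo": lo, "c_hi": hi})
    rows.sort(key=lambda r: r["order_key"])
    return pd.DataFrame(
        [
            {"slice_id": i, "polygon": r["polygon"], "c_lo": r["c_lo"], "c_hi": r["c_hi"]}
            for i, r in enumerate(rows)
        ]
    )


def summarize_slices(
    slices: pd.DataFrame,
    covariates: pd.DataFrame,
    geometry: LagoonGeometry,
    cell_area_km2: float = 0.25,
) -> pd.DataFrame:
    """Nine-variable profile per slice, over lagoon water cells.

    Unweighted mean/sd of distance-to-reef, slope and depth; mean projected
    northing; lagoon water surface area; and the summed widths of barrier
    passes whose midpoint falls in the slice. Empty slices are dropped with a
    warning.
    """
    # lagoon water cells: strictly inside the barrier (crest cells sit at 0)
    inside = covariates[covariates["dist_barrier_signed"] > 0]
    pts = shapely.points(inside["x"].to_numpy(), inside["y"].to_numpy())
    assigned_passes: set[int] = set()
    rows = []
    for _, sl in slices.iterrows():
        hit = shapely.covers(sl["polygon"], pts)
        sub = inside[hit]
        if len(sub) == 0:
            log.warning("slice %s has no water cells; dropped", sl["slice_id"])
            continue
        opening = 0.0
        for pi, p in enumerate(geometry.passes):
            if pi in assigned_passes:
                continue
            if sl["polygon"].covers(Point(p.x_mid, p.y_mid)):
                opening += p.width_km
                assigned_passes.add(pi)
        rows.append(
            {
                "slice_id": sl["slice_id"],
                "dist_reef_mean": sub["dist_reef"].mean(),
                "dist_reef_sd": sub["dist_reef"].std(ddof=1) if len(sub) > 1 else 0.0,
                "slope_mean": sub["slope"].mean(),
                "slope_sd": sub["slope"].std(ddof=1) if len(sub) > 1 else 0.0,
                "depth_mean": sub["depth"].mean(),
                "depth_sd": sub["depth"].std(ddof=1) if len(sub) > 1 else 0.0,
                "mean_northing": sub["y"].mean(),
                "surface_area_km2": float(
                    (sub["water_fraction"] * cell_area_km2).sum()
                ),
                "barrier_opening_km": opening,
                "n_cells": len(sub),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EcoregionPartition:
    k: int | None
    assignment: pd.Series  # slice_id -> ecoregion label (1..k)
    silhouette: dict  # k -> mean silhouette width
    linkage_matrix: np.ndarray | None
    polygons: dict | None = None  # label -> dissolved polygon
    message: str = ""


def cluster_slices(
    profiles: pd.DataFrame,
    k_candidates=(3, 4, 5),
    slices: pd.DataFrame | None = None,
) -> EcoregionPartition:
    """Ward clustering of z-scored slice profiles; silhouette picks k.

    Constant variables are dropped with a warning; identical profiles yield a
    'no structure' report. Silhouette ties break toward smaller k.
    """
    k_candidates = sorted(k_candidates)
    if len(profiles) < max(k_candidates) + 1:
        raise ValueError("need at least max(k)+1 slice profiles")
    X = profiles[[v for v in PROFILE_VARS if v in profiles.columns]].to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        log.warning("dropping %d constant profile variables", int((~keep).sum()))
    if not keep.any() or len(np.unique(X, axis=0)) == 1:
        return EcoregionPartition(
            None,
            pd.Series(1, index=profiles["slice_id"]),
            {},
            None,
            message="no structure: all slice profiles identical",
        )
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    lm = linkage(Z, method="ward")
    sil, labels = {}, {}
    for k in k_candidates:
        lab = fcluster(lm, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(Z, lab))
        labels[k] = lab
    best_k = max(sil, key=lambda k: (sil[k], -k))
    assignment = pd.Series(labels[best_k], index=profiles["slice_id"], name="ecoregion")
    polygons = None
    if slices is not None:
        merged = slices.merge(
            assignment.rename("ecoregion"), left_on="slice_id", right_index=True
        )
        polygons = {
            int(lab): unary_union(list(g["polygon"]))
            for lab, g in merged.groupby("ecoregion")
        }
    return EcoregionPartition(int(best_k), assignment, sil, lm, polygons)


def label_cells(
    covariates: pd.DataFrame,
    slices: pd.DataFrame,
    partition: EcoregionPartition,
) -> pd.Series:
    """Ecoregion label per grid cell via the slice containing its centroid;
    cells outside every slice inherit the nearest slice's label."""
    pts = shapely.points(covariates["x"].to_numpy(), covariates["y"].to_numpy())
    lab = np.zeros(len(covariates), dtype=int)
    assigned = np.zeros(len(covariates), dtype=bool)
    for _, sl in slices.iterrows():
        hit = shapely.covers(sl["polygon"], pts) & ~assigned
        lab[hit] = partition.assignment.loc[sl["slice_id"]]
        assigned |= hit
    if not assigned.all():
        rest = np.flatnonzero(~assigned)
        polys = list(slices["polygon"])
        d = np.stack([shapely.distance(pts[rest], p) for p in polys])
        nearest = np.asarray(slices["slice_id"])[d.argmin(axis=0)]
        lab[rest] = partition.assignment.loc[nearest].to_numpy()
    return pd.Series(lab, index=covariates.index, name="ecoregion")
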