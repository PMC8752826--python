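"""Slicing geometry, slice profiles, and Ward/silhouette clustering."""

import numpy as np
import pandas as pd
import pytest
import shapely

import lagoonhab as lh
from lagoonhab.ecoregions import (
    cluster_slices,
    label_cells,
    slice_lagoon,
    summarize_slices,
)
from lagoonhab.synthetic import RegionSpec


def _profiles_from(geometry, bathy):
    from lagoonhab.environment import build_grid, derive_covariates

    grid = build_grid(geometry)
    cov = derive_covariates(grid, bathy, geometry)
    slices = slice_lagoon(geometry)
    return slices, cov, summarize_slices(slices, cov, geometry)


class TestSlicing:
    def test_280km_corridor_gives_14_slices(self, lagoon):
        geometry, _ = lagoon
        slices = slice_lagoon(geometry)
        assert len(slices) == 14

    def test_short_corridor_gives_single_slice(self):
        regions = (RegionSpec(20.0, 6.0, 10.0, 0.5, 0.0, (2.0,)),)
        geometry, _ = lh.generate_lagoon(regions, seed=0)
        slices = slice_lagoon(geometry)
        assert len(slices) == 1

    def test_slices_partition_the_domain(self, lagoon):
        """Pairwise disjoint bands whose union returns the clipped domain
        (area bookkeeping within 0.1%)."""
        geometry, _ = lagoon
        slices = slice_lagoon(geometry)
        polys = list(slices["polygon"])
        total = sum(p.area for p in polys)
        union = shapely.unary_union(polys)
        assert abs(total - union.area) / union.area < 1e-3
        assert abs(union.area - geometry.domain.area) / geometry.domain.area < 1e-3


class TestProfiles:
    def test_constant_depth_slice_has_zero_sd(self):
        regions = (RegionSpec(45.0, 6.0, 10.0, 0.0, 0.0, (2.0,), uniform_depth=True),)
        geometry, bathy = lh.generate_lagoon(regions, seed=0)
        _, _, prof = _profiles_from(geometry, bathy)
        # only cells straddling the reef crest deviate from the flat field
        assert (prof["depth_sd"] < 1.0).all()

    def test_barrier_opening_sums_pass_widths(self, lagoon, covariates):
        """Each pass contributes its width to exactly one slice, so slice
        openings sum to the total planted pass width."""
        geometry, _ = lagoon
        _, cov = covariates
        slices = slice_lagoon(geometry)
        prof = summarize_slices(slices, cov, geometry)
        total = prof["barrier_opening_km"].sum()
        assert np.isclose(total, sum(p.width_km for p in geometry.passes))
        assert np.isclose(total, 10.08 + 6.99 + 7.0)

    def test_hand_placed_cells_average_exactly(self):
        """A fabricated 4-cell slice reproduces hand-computed means/sds."""
        poly = shapely.box(0, 0, 2000, 2000)
        slices = pd.DataFrame({"slice_id": [0], "polygon": [poly]})
        cov = pd.DataFrame(
            {
                "x": [250.0, 750.0, 250.0, 750.0],
                "y": [250.0, 250.0, 750.0, 750.0],
                "water_fraction": [1.0, 1.0, 1.0, 0.5],
                "dist_reef": [1.0, 2.0, 3.0, 4.0],
                "slope": [0.1, 0.2, 0.3, 0.4],
                "depth": [5.0, 6.0, 7.0, 8.0],
                "dist_barrier_signed": [1.0, 1.0, 1.0, 1.0],
            }
        )
        geom = lh.LagoonGeometry(
            coastline=shapely.box(-10, -10, -5, -5),
            barrier_reef=[],
            passes=[lh.Pass(500.0, 500.0, 3.0), lh.Pass(900.0, 900.0, 4.0)],
            intermediate_reefs=[],
            islets=[],
            seagrass=[],
            lagoon=poly,
            domain=poly,
        )
        prof = summarize_slices(slices, cov, geom)
        assert np.isclose(prof.loc[0, "dist_reef_mean"], 2.5)
        assert np.isclose(prof.loc[0, "dist_reef_sd"], np.std([1, 2, 3, 4], ddof=1))
        assert np.isclose(prof.loc[0, "depth_mean"], 6.5)
        assert np.isclose(prof.loc[0, "mean_northing"], 500.0)
        assert np.isclose(prof.loc[0, "surface_area_km2"], 3.5 * 0.25)
        assert np.isclose(prof.loc[0, "barrier_opening_km"], 7.0)


class TestClustering:
    def test_planted_three_region_lagoon_recovered(self, lagoon, covariates):
        geometry, _ = lagoon
        _, cov = covariates
        slices = slice_lagoon(geometry)
        prof = summarize_slices(slices, cov, geometry)
        part = cluster_slices(prof, slices=slices)
        assert part.k == 3
        from sklearn.metrics import adjusted_rand_score

        cents = [shapely.centroid(p) for p in slices["polygon"]]
        xb = geometry.region_truth["boundaries_m"]
        truth = [
            int(np.searchsorted(xb[1:-1], c.x - max(c.y, 0.0))) for c in cents
        ]
        ari = adjusted_rand_score(
            [truth[i] for i in prof["slice_id"]],
            part.assignment.loc[prof["slice_id"]].tolist(),
        )
        assert ari == 1.0

    def test_identical_profiles_report_no_structure(self):
        prof = pd.DataFrame(
            {
                "slice_id": range(8),
                **{v: [1.0] * 8 for v in [
                    "dist_reef_mean", "dist_reef_sd", "slope_mean", "slope_sd",
                    "depth_mean", "depth_sd", "mean_northing",
                    "surface_area_km2", "barrier_opening_km",
                ]},
            }
        )
        part = cluster_slices(prof)
        assert part.k is None
        assert "no structure" in part.message

    def test_duplicating_profiles_preserves_partition(self, lagoon, covariates):
        geometry, _ = lagoon
        _, cov = covariates
        slices = slice_lagoon(geometry)
        prof = summarize_slices(slices, cov, geometry)
        doubled = pd.concat([prof, prof.assign(slice_id=prof.slice_id + 100)],
                            ignore_index=True)
        p1 = cluster_slices(prof)
        p2 = cluster_slices(doubled)
        assert p2.k == p1.k
        a = p2.assignment
        # each clone pair lands in the same cluster
        for sid in prof["slice_id"]:
            assert a.loc[sid] == a.loc[sid + 100]

    def test_permutation_invariance(self, lagoon, covariates):
        geometry, _ = lagoon
        _, cov = covariates
        slices = slice_lagoon(geometry)
        prof = summarize_slices(slices, cov, geometry)
        rng = np.random.default_rng(0)
        perm = prof.sample(frac=1.0, random_state=3).reset_index(drop=True)
        p1 = cluster_slices(prof)
        p2 = cluster_slices(perm)
        assert p1.k == p2.k
        from sklearn.metrics import adjusted_rand_score

        merged = pd.DataFrame(
            {"a": p1.assignment, "b": p2.assignment.reindex(p1.assignment.index)}
        )
        assert adjusted_rand_score(merged["a"], merged["b"]) == 1.0

    def test_ward_merge_heights_monotone(self, lagoon, covariates):
        geometry, _ = lagoon
        _, cov = covariates
        slices = slice_lagoon(geometry)
        prof = summarize_slices(slices, cov, geometry)
        part = cluster_slices(prof)
        heights = part.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_too_few_profiles_rejected(self):
        prof = pd.DataFrame(
            {"slice_id": range(4), "depth_mean": [1, 2, 3, 4.0],
             "depth_sd": [0.1] * 4}
        )
        with pytest.raises(ValueError):
            cluster_slices(prof)


def test_label_cells_covers_every_cell(lagoon, covariates):
    geometry, _ = lagoon
    _, cov = covariates
    slices = slice_lagoon(geometry)
    prof = summarize_slices(slices, cov, geometry)
    part = cluster_slices(prof, slices=slices)
    lab = label_cells(cov, slices, part)
    assert lab.isin(set(part.assignment.unique())).all()
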