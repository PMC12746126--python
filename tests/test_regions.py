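import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon

from microscape import regions
from microscape.errors import ConfigurationError
from microscape.regions import (
    RegionModel,
    alpha_shape,
    assign_domains,
    assign_regions,
    cell_density,
    local_density,
    reconstruct_tumor_boundaries,
    regional_composition,
)


def disk_points(rng, cx, cy, radius, n):
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def brute_force_eps_clusters(points, eps, min_samples):
    """Oracle: connected components of the eps-graph over core points."""
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = dist <= eps
    core = neighbors.sum(axis=1) >= min_samples  # includes self, as DBSCAN does
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in np.where(neighbors[j])[0]:
                if core[k] and labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    # border points: attach to any neighboring core point's cluster
    for i in range(n):
        if labels[i] == -1:
            for k in np.where(neighbors[i])[0]:
                if core[k]:
                    labels[i] = labels[k]
                    break
    return labels, cluster


class TestRegionModel:
    def test_defaults_valid(self):
        model = RegionModel()
        assert model.alpha == 2 * model.dbscan_eps

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"peritumoral_band": 0},
            {"vessel_radius": -1},
            {"dbscan_eps": 0},
            {"dbscan_min_samples": 2},
            {"necrosis_density_quantile": 1.5},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            RegionModel(**kwargs)


class TestReconstructBoundaries:
    def test_below_min_samples_is_empty(self):
        pts = np.random.default_rng(0).random((5, 2)) * 100
        model = RegionModel(dbscan_min_samples=10)
        assert reconstruct_tumor_boundaries(pts, model) == []

    def test_single_disk_one_polygon(self, rng):
        pts = disk_points(rng, 0, 0, 100, 200)
        model = RegionModel(dbscan_eps=30, dbscan_min_samples=10)
        polys = reconstruct_tumor_boundaries(pts, model)
        assert len(polys) == 1
        inside = sum(polys[0].covers(Point(p)) for p in pts)
        assert inside >= 0.95 * len(pts)

    def test_two_distant_disks_two_polygons(self, rng):
        pts = np.vstack(
            [disk_points(rng, 0, 0, 100, 200), disk_points(rng, 1000, 0, 100, 200)]
        )
        model = RegionModel(dbscan_eps=30, dbscan_min_samples=10)
        polys = reconstruct_tumor_boundaries(pts, model)
        assert len(polys) == 2
        # oracle: brute-force eps-connectivity must also find two clusters
        _, n_clusters = brute_force_eps_clusters(pts, eps=30, min_samples=10)
        assert n_clusters == 2

    def test_polygons_sorted_by_area(self, rng):
        pts = np.vstack(
            [disk_points(rng, 0, 0, 150, 300), disk_points(rng, 2000, 0, 60, 100)]
        )
        model = RegionModel(dbscan_eps=40, dbscan_min_samples=10)
        polys = reconstruct_tumor_boundaries(pts, model)
        areas = [p.area for p in polys]
        assert areas == sorted(areas, reverse=True)

    def test_point_order_invariance(self, rng):
        pts = disk_points(rng, 0, 0, 100, 150)
        model = RegionModel(dbscan_eps=30, dbscan_min_samples=10)
        a = reconstruct_tumor_boundaries(pts, model)
        b = reconstruct_tumor_boundaries(pts[::-1], model)
        assert len(a) == len(b) == 1
        assert a[0].equals(b[0])

    def test_dbscan_matches_bruteforce_on_small_instances(self, rng):
        from sklearn.cluster import DBSCAN

        pts = np.vstack(
            [
                disk_points(rng, 0, 0, 80, 150),
                disk_points(rng, 600, 300, 80, 150),
                rng.random((50, 2)) * 2000 + 3000,  # sparse noise far away
            ]
        )
        eps, min_samples = 30, 10
        sk = DBSCAN(eps=eps, min_samples=min_samples).fit(pts).labels_
        oracle, _ = brute_force_eps_clusters(pts, eps, min_samples)
        # partitions must agree up to label permutation on clustered points
        for lab in np.unique(sk):
            if lab == -1:
                continue
            members = oracle[sk == lab]
            assert len(np.unique(members[members >= 0])) == 1
        assert np.array_equal(sk == -1, oracle == -1) or (
            # border-point attachments may differ; cores must agree exactly
            np.mean((sk == -1) == (oracle == -1)) > 0.98
        )


class TestAlphaShape:
    def test_concavity_captured(self, rng):
        # C-shaped cloud: concave hull area well below convex hull area
        theta = rng.uniform(0, 1.5 * np.pi, 600)
        radius = rng.uniform(80, 100, 600)
        pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        polys = alpha_shape(pts, alpha=25)
        concave_area = sum(p.area for p in polys)
        convex_area = shapely.MultiPoint(pts).convex_hull.area
        assert concave_area < 0.75 * convex_area

    def test_degenerate_input(self):
        assert alpha_shape(np.array([[0.0, 0.0], [1.0, 1.0]]), alpha=5) == []


def _square_cluster(cx, cy, half, spacing=10.0):
    xs = np.arange(cx - half, cx + half + spacing, spacing)
    ys = np.arange(cy - half, cy + half + spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


class TestAssignRegions:
    model = RegionModel(dbscan_eps=30, dbscan_min_samples=10)

    def _setup(self):
        tumor = _square_cluster(0, 0, 100)
        polys = reconstruct_tumor_boundaries(tumor, self.model)
        assert len(polys) == 1
        return tumor, polys

    def test_inside_polygon_is_tumor(self):
        tumor, polys = self._setup()
        labels = assign_regions(np.array([[0.0, 0.0]]), polys, self.model)
        assert labels[0] == "tumor"

    def test_band_is_peritumoral(self):
        tumor, polys = self._setup()
        cells = np.vstack([tumor, [[110.0, 0.0]]])  # 10 μm outside the boundary
        labels = assign_regions(cells, polys, self.model)
        assert labels.iloc[-1] == "peritumoral"

    def test_debris_and_sparse_is_necrotic(self):
        tumor, polys = self._setup()
        lone = np.array([[140.0, 0.0]])  # sparse: nearest neighbors are far
        cells = np.vstack([tumor, lone])
        debris = np.zeros(len(cells), dtype=bool)
        debris[-1] = True
        labels = assign_regions(cells, polys, self.model, debris_flags=debris)
        assert labels.iloc[-1] == "necrotic"

    def test_debris_without_sparsity_stays_peritumoral(self):
        tumor, polys = self._setup()
        # a debris-positive cell embedded in the dense tumor-adjacent grid
        dense_band = _square_cluster(130, 0, 20, spacing=8.0)
        cells = np.vstack([tumor, dense_band])
        debris = np.zeros(len(cells), dtype=bool)
        debris[len(tumor)] = True
        labels = assign_regions(cells, polys, self.model, debris_flags=debris)
        assert labels.iloc[len(tumor)] == "peritumoral"

    def test_vessel_proximity_is_perivascular(self):
        tumor, polys = self._setup()
        cells = np.array([[200.0, 0.0]])
        labels = assign_regions(
            cells, polys, self.model, vessel_cells=np.array([[210.0, 0.0]])
        )
        assert labels[0] == "perivascular"

    def test_far_cell_is_distal(self):
        tumor, polys = self._setup()
        labels = assign_regions(np.array([[1000.0, 1000.0]]), polys, self.model)
        assert labels[0] == "distal"

    def test_partition_exhaustive_exclusive(self, rng):
        tumor, polys = self._setup()
        cells = rng.random((300, 2)) * 600 - 300
        labels = assign_regions(cells, polys, self.model,
                                vessel_cells=np.array([[250.0, 250.0]]),
                                debris_flags=rng.random(300) < 0.1)
        assert set(labels) <= set(regions.REGIONS)
        assert len(labels) == 300

    def test_mismatched_debris_length_rejected(self):
        tumor, polys = self._setup()
        with pytest.raises(ValueError):
            assign_regions(tumor, polys, self.model, debris_flags=[True])

    def test_no_polygons_gives_no_tumor_or_band(self):
        labels = assign_regions(np.array([[0.0, 0.0]]), [], self.model)
        assert labels[0] == "distal"


class TestRegionAccuracyOnSyntheticTissue:
    def test_tumor_and_peritumoral_recovery(self, gated_tissue):
        _, scaled, _ = gated_tissue
        model = RegionModel()
        xy = scaled[["x", "y"]].to_numpy()
        tumor_xy = xy[(scaled["phenotype"] == "Tumor").to_numpy()]
        vessel_xy = xy[(scaled["phenotype"] == "Endothelial").to_numpy()]
        polys = reconstruct_tumor_boundaries(tumor_xy, model)
        assigned = assign_regions(
            xy, polys, model, vessel_cells=vessel_xy,
            debris_flags=scaled["true_debris"].to_numpy(),
        ).to_numpy()
        truth = scaled["true_region"].to_numpy()
        for cls in ("tumor", "peritumoral"):
            mask = truth == cls
            assert mask.sum() > 0
            assert (assigned[mask] == cls).mean() >= 0.90

    def test_necrotic_within_band(self, gated_tissue):
        _, scaled, _ = gated_tissue
        truth = scaled["true_region"].to_numpy()
        # planted necrotic cells sit inside the geometric peritumoral band
        assert not np.any((truth == "necrotic") & ~scaled["true_debris"].to_numpy())


class TestRegionalComposition:
    def test_quoted_normalization(self):
        counts = {"A": 50, "B": 30, "C": 10, "D": 5, "E": 5}
        phenos, groups = [], []
        for dom, k in counts.items():
            phenos += ["CD8 T"] * k
            groups += [dom] * k
        comp = regional_composition(groups, phenos)
        np.testing.assert_allclose(
            comp.loc["CD8 T", ["A", "B", "C", "D", "E"]], [0.5, 0.3, 0.1, 0.05, 0.05]
        )

    def test_single_domain_all_ones(self):
        comp = regional_composition(["A"] * 10, ["T"] * 5 + ["B"] * 5)
        np.testing.assert_allclose(comp["A"], 1.0)

    def test_absent_type_is_na(self):
        comp = regional_composition(["A", "B"], ["T", "T"], cell_types=["T", "missing"])
        assert comp.loc["missing"].isna().all()

    def test_rows_sum_to_one(self, rng):
        groups = rng.choice(list("ABC"), 200)
        phenos = rng.choice(["T", "B", "M"], 200)
        comp = regional_composition(groups, phenos)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)


class TestCellDensity:
    def test_simple(self):
        poly = Polygon([(0, 0), (500, 0), (500, 500), (0, 500)])
        assert cell_density(500, poly) == pytest.approx(2000.0)

    def test_zero_cells(self):
        poly = Polygon([(0, 0), (500, 0), (500, 500), (0, 500)])
        assert cell_density(0, poly) == 0.0

    def test_shoelace_square(self):
        coords = [(0, 0), (500, 0), (500, 500), (0, 500)]
        # oracle: width * height = 0.25 mm^2
        assert cell_density(1000, coords) == pytest.approx(1000 / 0.25)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cell_density(10, [(0, 0), (1, 1), (2, 2)])


class TestLocalDensity:
    def test_uniform_grid_density(self):
        pts = _square_cluster(0, 0, 100, spacing=10.0)
        dens = local_density(pts, k=4)
        # interior grid points: 4th NN at 10 μm -> 4 / (pi * 100)
        interior = (np.abs(pts) < 50).all(axis=1)
        np.testing.assert_allclose(dens[interior], 4 / (np.pi * 100), rtol=1e-6)


class TestAssignDomains:
    def test_point_in_polygon(self):
        polys = {
            "A": Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
            "B": Polygon([(20, 0), (30, 0), (30, 10), (20, 10)]),
        }
        labels = assign_domains(
            np.array([[5.0, 5.0], [25.0, 5.0], [50.0, 50.0]]), polys
        )
        assert list(labels) == ["A", "B", "none"]
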