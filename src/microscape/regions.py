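"""Tumor-boundary reconstruction and microanatomical region assignment.

Tumor boundaries are rebuilt from tumor-cell centroids by DBSCAN clustering
followed by a concave (alpha-shape) hull per cluster.  Every cell is then
assigned exactly one region with precedence

    tumor > necrotic > perivascular > peritumoral > distal

where "tumor" is containment in a reconstructed polygon, "necrotic" requires
being inside the peritumoral band with a positive DNA-debris flag and a local
cell density in the sparse tail of the field's density distribution,
"perivascular" is proximity to an endothelial (CD31+) cell, and
"peritumoral" is the band immediately adjacent to a tumor boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union
from sklearn.cluster import DBSCAN

from .errors import ConfigurationError

REGIONS = ("tumor", "peritumoral", "necrotic", "perivascular", "distal")


@dataclass
class RegionModel:
    """Parameters of boundary reconstruction and region assignment (μm)."""

    peritumoral_band: float = 50.0
    vessel_radius: float = 50.0
    necrosis_density_quantile: float = 0.2
    dbscan_eps: float = 30.0
    dbscan_min_samples: int = 10
    boundary_alpha: float | None = None  # default 2 * dbscan_eps
    density_k: int = 10  # k-NN order for the local density estimate

    def __post_init__(self):
        if self.peritumoral_band <= 0 or self.vessel_radius <= 0:
            raise ConfigurationError("band and vessel radius must be positive")
        if self.dbscan_eps <= 0:
            raise ConfigurationError("dbscan_eps must be positive")
        if self.dbscan_min_samples < 3:
            raise ConfigurationError("dbscan_min_samples must be >= 3")
        if not 0 < self.necrosis_density_quantile < 1:
            raise ConfigurationError("necrosis_density_quantile must be in (0, 1)")

    @property
    def alpha(self) -> float:
        return self.boundary_alpha if self.boundary_alpha is not None else 2.0 * self.dbscan_eps


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    return pts


def alpha_shape(points, alpha: float) -> list[Polygon]:
    """Concave hull(s): union of Delaunay triangles with circumradius <= alpha.

    Holes are filled (a tumor bed containing a gap is still tumor).  Falls
    back to the convex hull when the triangle filter removes everything or
    the point set is degenerate.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        return []
    try:
        tri = Delaunay(pts)
    except QhullError:
        return []
    a, b, c = (pts[tri.simplices[:, i]] for i in range(3))
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area > 0, la * lb * lc / (4.0 * area), np.inf)
    keep = circumradius <= alpha
    if not keep.any():
        hull = MultiPoint(pts).convex_hull
        return [hull] if isinstance(hull, Polygon) else []
    triangles = [Polygon(pts[s]) for s in tri.simplices[keep]]
    union = unary_union(triangles)
    polys = [union] if isinstance(union, Polygon) else list(union.geoms)
    return [Polygon(p.exterior) for p in polys if isinstance(p, Polygon)]


def reconstruct_tumor_boundaries(tumor_cells, model: RegionModel) -> list[Polygon]:
    """DBSCAN on tumor-cell centroids, then a concave hull per cluster.

    Returns polygons sorted largest-area first; fewer tumor cells than
    ``dbscan_min_samples`` gives an empty list (not an error).
    """
    pts = _as_points(tumor_cells)
    if len(pts) < model.dbscan_min_samples:
        return []
    labels = DBSCAN(eps=model.dbscan_eps, min_samples=model.dbscan_min_samples).fit(
        pts
    ).labels_
    polygons: list[Polygon] = []
    for cluster in np.unique(labels):
        if cluster == -1:
            continue
        polygons.extend(alpha_shape(pts[labels == cluster], model.alpha))
    polygons.sort(key=lambda p: p.area, reverse=True)
    return polygons


def local_density(points, k: int = 10) -> np.ndarray:
    """k-NN local density (cells per μm²): k / (π · r_k²)."""
    pts = _as_points(points)
    n = len(pts)
    if n == 0:
        return np.empty(0)
    k_eff = min(k, n - 1)
    if k_eff < 1:
        return np.zeros(n)
    tree = cKDTree(pts)
    r_k = tree.query(pts, k=k_eff + 1)[0][:, -1]
    with np.errstate(divide="ignore"):
        return np.where(r_k > 0, k_eff / (np.pi * r_k**2), np.inf)


def assign_regions(
    cells,
    polygons: Sequence[Polygon],
    model: RegionModel,
    vessel_cells=None,
    debris_flags=None,
) -> pd.Series:
    """One microanatomical region label per cell (see module precedence)."""
    pts = _as_points(cells)
    n = len(pts)
    if debris_flags is None:
        debris = np.zeros(n, dtype=bool)
    else:
        debris = np.asarray(debris_flags, dtype=bool)
        if len(debris) != n:
            raise ValueError("debris_flags length does not match cell table")
    geoms = shapely.points(pts)
    if polygons:
        tumor_union = unary_union(list(polygons))
        inside = shapely.covers(tumor_union, geoms)
        dist_to_tumor = shapely.distance(geoms, tumor_union)
    else:
        inside = np.zeros(n, dtype=bool)
        dist_to_tumor = np.full(n, np.inf)
    in_band = ~inside & (dist_to_tumor <= model.peritumoral_band)

    density = local_density(pts, k=model.density_k)
    sparse = density <= np.quantile(density, model.necrosis_density_quantile)

    vessel_cells = np.asarray(
        vessel_cells if vessel_cells is not None else np.empty((0, 2)), dtype=float
    )
    if vessel_cells.size:
        vtree = cKDTree(_as_points(vessel_cells))
        near_vessel = vtree.query(pts, k=1)[0] <= model.vessel_radius
    else:
        near_vessel = np.zeros(n, dtype=bool)

    labels = np.full(n, "distal", dtype=object)
    labels[in_band] = "peritumoral"
    labels[~inside & near_vessel] = "perivascular"
    labels[in_band & debris & sparse] = "necrotic"
    labels[inside] = "tumor"
    return pd.Series(labels, name="region")


def regional_composition(
    group_labels,
    phenotypes,
    cell_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell-type distribution across regions or domains.

    Each row (cell type) is normalized by that type's total count, so rows
    sum to 1; a requested type with zero cells yields an all-NA row.
    """
    group_labels = np.asarray(group_labels)
    phenotypes = np.asarray(phenotypes)
    if len(group_labels) != len(phenotypes):
        raise ValueError("group labels and phenotypes must have equal length")
    table = pd.crosstab(pd.Series(phenotypes, name="cell_type"),
                        pd.Series(group_labels, name="group"))
    if cell_types is not None:
        table = table.reindex(index=list(cell_types), fill_value=0)
    totals = table.sum(axis=1)
    fractions = table.div(totals.replace(0, np.nan), axis=0)
    return fractions


def cell_density(n_cells: int, polygon) -> float:
    """Cells per mm² inside a polygon whose coordinates are in μm.

    Area is the shoelace area of the polygon (via its exterior ring);
    degenerate polygons raise.
    """
    if n_cells < 0:
        raise ValueError("cell count must be non-negative")
    if isinstance(polygon, Polygon):
        area_um2 = polygon.area
    else:
        coords = _as_points(polygon)
        x, y = coords[:, 0], coords[:, 1]
        area_um2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area_um2 <= 0:
        raise ValueError("polygon has non-positive area")
    return n_cells / (area_um2 / 1e6)


def assign_domains(
    cells, domain_polygons: Mapping[str, Polygon], fallback: str = "none"
) -> pd.Series:
    """Domain id per cell from annotation polygons (first containing wins)."""
    pts = _as_points(cells)
    geoms = shapely.points(pts)
    labels = np.full(len(pts), fallback, dtype=object)
    unassigned = np.ones(len(pts), dtype=bool)
    for domain_id, poly in domain_polygons.items():
        hit = unassigned & shapely.covers(poly, geoms)
        labels[hit] = domain_id
        unassigned &= ~hit
    return pd.Series(labels, name="domain")
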