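"""Spatial summaries: KDE density maps, adaptive Delaunay graphs,
fixed-radius neighborhood composition, nearest-neighbor distances, ratios.

Coordinates are micrometers throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.stats import gaussian_kde

from .errors import InsufficientCellsError

KDE_MIN_CELLS = 50
CLIP_PERCENTILE = 98.0
MASK_PERCENTILE = 10.0
DEFAULT_RADIUS = 50.0
DEFAULT_FILTER_FACTOR = 3.0


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x/y coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    return pts


@dataclass
class DensityMap:
    """Gaussian-KDE density on a regular grid, clipped and masked.

    ``density`` holds the clipped values (row i = y index, column j = x index);
    ``mask`` is True where the raw density falls below the mask floor.  Clip
    ceiling (98th percentile) and mask floor (10th percentile) are computed
    from densities evaluated at the input cell positions, then applied to the
    grid.  ``density_raw`` retains the unclipped surface.
    """

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    density_raw: np.ndarray
    mask: np.ndarray
    clip_value: float
    mask_value: float
    bandwidth_factor: float
    grid_spacing: float

    @property
    def origin(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.y[0])

    @property
    def masked_density(self) -> np.ndarray:
        out = self.density.copy()
        out[self.mask] = np.nan
        return out


def kde_map(
    points,
    grid_spacing: float = 10.0,
    pad_bandwidths: float = 4.0,
    clip_percentile: float = CLIP_PERCENTILE,
    mask_percentile: float = MASK_PERCENTILE,
) -> DensityMap:
    """Gaussian KDE map of cell centroids (Scott's-rule bandwidth).

    Refuses fewer than 50 points.  The grid covers the point bounding box
    padded by ``pad_bandwidths`` marginal bandwidths on every side.
    """
    pts = _as_points(points)
    if len(pts) < KDE_MIN_CELLS:
        raise InsufficientCellsError(
            f"insufficient cells for KDE: {len(pts)} < {KDE_MIN_CELLS}"
        )
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    kde = gaussian_kde(pts.T)
    bw = np.sqrt(np.diag(kde.covariance))  # per-axis kernel SD in μm
    at_cells = kde(pts.T)
    clip_value = float(np.percentile(at_cells, clip_percentile))
    mask_value = float(np.percentile(at_cells, mask_percentile))
    pad = pad_bandwidths * bw
    x = np.arange(pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0] + grid_spacing,
                  grid_spacing)
    y = np.arange(pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1] + grid_spacing,
                  grid_spacing)
    gx, gy = np.meshgrid(x, y)
    raw = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gy.shape)
    return DensityMap(
        x=x,
        y=y,
        density=np.minimum(raw, clip_value),
        density_raw=raw,
        mask=raw < mask_value,
        clip_value=clip_value,
        mask_value=mask_value,
        bandwidth_factor=float(kde.factor),
        grid_spacing=float(grid_spacing),
    )


@dataclass
class SpatialGraph:
    """Undirected graph over cell indices with edge lengths in μm."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int, i < j
    lengths: np.ndarray  # (m,)

    @classmethod
    def empty(cls, n_nodes: int = 0) -> "SpatialGraph":
        return cls(n_nodes, np.empty((0, 2), dtype=int), np.empty(0))


def delaunay_edges(points) -> np.ndarray:
    """Unique undirected edges (i < j) of the Delaunay triangulation."""
    pts = _as_points(points)
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
    return np.array(sorted(edges), dtype=int)


def delaunay_filtered(
    points, filter_factor: float = DEFAULT_FILTER_FACTOR
) -> SpatialGraph:
    """Delaunay graph with long edges removed adaptively.

    An edge survives iff its length is at most ``filter_factor`` times the
    smaller of its two endpoints' nearest-neighbor distances, so connections
    to distant outliers are dropped and only short-range structure remains.
    Degenerate inputs (< 3 points, collinear) yield an empty graph with a
    warning.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        warnings.warn("fewer than 3 points; returning empty graph")
        return SpatialGraph.empty(len(pts))
    try:
        edges = delaunay_edges(pts)
    except QhullError:
        warnings.warn("degenerate (collinear) point set; returning empty graph")
        return SpatialGraph.empty(len(pts))
    tree = cKDTree(pts)
    nn_dist = tree.query(pts, k=2)[0][:, 1]
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    local_scale = np.minimum(nn_dist[edges[:, 0]], nn_dist[edges[:, 1]])
    keep = lengths <= filter_factor * local_scale
    return SpatialGraph(len(pts), edges[keep], lengths[keep])


def neighborhood_composition(
    targets,
    others,
    labels,
    radius: float = DEFAULT_RADIUS,
) -> pd.DataFrame:
    """Composition of cells within ``radius`` (inclusive) of any target cell.

    Each candidate cell counts once however many targets it is near.  Returns
    a frame indexed by label with ``count`` and ``fraction`` columns
    (fractions over all neighbors sum to 1 when any neighbor exists).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    others = _as_points(others)
    labels = np.asarray(labels)
    if len(labels) != len(others):
        raise ValueError("labels and others must have equal length")
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        warnings.warn("no target cells; returning empty composition")
        return pd.DataFrame(columns=["count", "fraction"])
    targets = _as_points(targets)
    tree = cKDTree(targets)
    dist = tree.query(others, k=1)[0]
    is_neighbor = dist <= radius
    counts = pd.Series(labels[is_neighbor]).value_counts().sort_index()
    out = counts.to_frame("count")
    out["fraction"] = out["count"] / out["count"].sum() if len(out) else np.nan
    out.index.name = "cell_type"
    return out


def nn_distances(
    from_cells,
    to_cells,
    exclude_self: bool = False,
    log: bool = False,
) -> np.ndarray:
    """Per-source-cell nearest Euclidean distance to the target set (μm).

    With ``exclude_self`` the source and target sets are taken to be the same
    cells in the same order and each cell's zero self-distance is skipped.
    The ``log`` option returns ln(distance + 1 μm).  An empty target set
    yields an all-NaN vector with a warning.
    """
    src = _as_points(from_cells)
    tgt = np.asarray(to_cells, dtype=float)
    if tgt.size == 0:
        warnings.warn("empty target set; returning NaN distances")
        return np.full(len(src), np.nan)
    tgt = _as_points(tgt)
    tree = cKDTree(tgt)
    if exclude_self:
        if len(tgt) < 2:
            warnings.warn("single cell cannot have a non-self neighbor")
            return np.full(len(src), np.nan)
        dist = tree.query(src, k=2)[0][:, 1]
    else:
        dist = tree.query(src, k=1)[0]
    if log:
        dist = np.log(dist + 1.0)
    return dist


def proximity_summary(distances) -> dict:
    """Mean/median/n summary of a nearest-neighbor distance vector."""
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return {"n": 0, "mean": float("nan"), "median": float("nan")}
    return {"n": int(d.size), "mean": float(d.mean()), "median": float(np.median(d))}


def subtype_ratio(count_a: int, count_b: int) -> float:
    """count_a / count_b; NaN (never infinity) when the denominator is zero."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_b == 0:
        return float("nan")
    return count_a / count_b
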