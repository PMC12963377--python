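"""B-cell-independent demarcation of lymphoid aggregates (LAs).

LAs are detected from the spatial co-occurrence of the chemokines CCL19 and
CXCL13 rather than from B-cell content, in four stages:

1. seed selection — every CCL19-positive cell with a CXCL13-positive cell
   within ``pair_radius`` (default 50 µm, centre-to-centre, inclusive);
2. density clustering — DBSCAN over seed cells with eps ``dbscan_radius``
   (default 75 µm) and core condition "at least ``min_cluster_cells``
   (default 15) seeds in the neighbourhood counting the cell itself";
3. centroid merging — single-linkage transitive merge of clusters whose
   centroids lie within ``merge_distance`` (default 400 µm), computed once
   on the original centroids;
4. geometry and assignment — an alpha-shape concave hull of each merged
   cluster's seed cells, dilated by ``hull_buffer`` (default 100 µm); every
   cell of any type whose centre falls inside or on the polygon is assigned
   to the LA.

All distance comparisons are boundary-inclusive (``<=``), matching the plain
reading of "within".  The stage composition is deterministic for a fixed
input and configuration; iteration orders are tied to ascending ``cell_id``.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .config import Config
from .errors import ValidationError
from .io import OUTSIDE, CellMap

logger = logging.getLogger(__name__)


@dataclass
class LACluster:
    """A DBSCAN cluster of chemokine seed cells."""

    cluster_id: int
    member_ids: list[str]
    centroid: tuple[float, float]
    source_cluster_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.source_cluster_ids:
            self.source_cluster_ids = [self.cluster_id]


@dataclass
class LymphoidAggregate:
    """A demarcated LA: polygon, assigned member cells, per-type counts."""

    la_id: int
    polygon: Polygon
    area_um2: float
    member_ids: list[str]
    counts_by_type: dict[str, int]
    source_cluster_ids: list[int]
    seed_centroid: tuple[float, float]
    convex_fallback: bool = False


# ---------------------------------------------------------------------------
# stage 1: chemokine seed selection

def select_chemokine_seed_cells(cellmap: CellMap,
                                pair_radius: float = 50.0,
                                positivity_min: int = 1,
                                self_pairing: bool = True) -> list[str]:
    """CCL19-positive cells within ``pair_radius`` of a CXCL13-positive cell.

    Positivity is ``count >= positivity_min``.  A CCL19+CXCL13 double-positive
    cell pairs with itself when ``self_pairing`` is enabled (the default);
    otherwise it needs a distinct CXCL13-positive cell in range.  Returns
    seed cell ids sorted ascending.
    """
    ccl19 = cellmap.positive("CCL19", positivity_min)
    cxcl13 = cellmap.positive("CXCL13", positivity_min)
    ids = cellmap.cells["cell_id"].to_numpy()
    if not ccl19.any() or not cxcl13.any():
        return []
    xy = cellmap.coordinates()
    tree = cKDTree(xy[cxcl13])
    n_in_range = tree.query_ball_point(xy[ccl19], r=pair_radius,
                                       return_length=True)
    both = (ccl19 & cxcl13)[ccl19]  # among CCL19+ cells, which are double+
    if self_pairing:
        is_seed = n_in_range >= 1
    else:
        # a double-positive cell finds itself at distance 0; discount it
        is_seed = n_in_range >= np.where(both, 2, 1)
    return sorted(ids[ccl19][is_seed])


# ---------------------------------------------------------------------------
# stage 2: DBSCAN over seeds

def _dbscan(xy: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Deterministic DBSCAN; neighbourhood counts include the point itself.

    Points are expanded in index order (callers pass id-sorted arrays), so a
    border point reachable from two clusters joins the first-discovered one.
    Returns labels; noise is -1.
    """
    n = len(xy)
    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, r=eps)
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        queue = deque([i])
        while queue:
            j = queue.popleft()
            for k in sorted(neighbors[j]):
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        queue.append(k)
        cluster += 1
    return labels


def cluster_seed_cells(cellmap: CellMap,
                       seed_ids: list[str],
                       radius: float = 75.0,
                       min_cells: int = 15) -> list[LACluster]:
    """Cluster seed cells with DBSCAN(eps=radius, core ⇔ ≥ min_cells seeds
    in the eps-ball counting self); noise seeds are discarded."""
    if not seed_ids:
        return []
    seed_ids = sorted(seed_ids)
    df = cellmap.cells.set_index("cell_id").loc[seed_ids]
    xy = df[["x", "y"]].to_numpy(dtype=float)
    labels = _dbscan(xy, eps=radius, min_samples=min_cells)
    clusters: list[LACluster] = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        mask = labels == lab
        members = [seed_ids[i] for i in np.flatnonzero(mask)]
        cx, cy = xy[mask].mean(axis=0)
        clusters.append(LACluster(cluster_id=lab, member_ids=members,
                                  centroid=(float(cx), float(cy))))
    return clusters


# ---------------------------------------------------------------------------
# stage 3: centroid merging

def merge_clusters(clusters: list[LACluster],
                   cellmap: CellMap,
                   merge_distance: float = 400.0) -> list[LACluster]:
    """Merge clusters whose centroids are within ``merge_distance``.

    Single-linkage connected components on the original centroids, computed
    once (no iterative recomputation); the merged centroid is recomputed from
    the union of members afterwards.
    """
    if len(clusters) <= 1:
        return list(clusters)
    cents = np.array([c.centroid for c in clusters])
    tree = cKDTree(cents)
    pairs = tree.query_pairs(r=merge_distance, output_type="ndarray")
    n = len(clusters)
    if len(pairs):
        graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                           shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, comp = connected_components(graph, directed=False)
    coords = cellmap.cells.set_index("cell_id")[["x", "y"]]
    merged: list[LACluster] = []
    for new_id in range(n_comp):
        group = [clusters[i] for i in np.flatnonzero(comp == new_id)]
        members = sorted(set().union(*[set(c.member_ids) for c in group]))
        xy = coords.loc[members].to_numpy(dtype=float)
        merged.append(LACluster(
            cluster_id=new_id,
            member_ids=members,
            centroid=tuple(xy.mean(axis=0)),
            source_cluster_ids=sorted(cid for c in group
                                      for cid in c.source_cluster_ids),
        ))
    return merged


# ---------------------------------------------------------------------------
# stage 4: concave-hull polygons

def _circumradius(pa: np.ndarray, pb: np.ndarray, pc: np.ndarray) -> float:
    a = np.linalg.norm(pb - pc)
    b = np.linalg.norm(pa - pc)
    c = np.linalg.norm(pa - pb)
    area2 = abs((pb[0] - pa[0]) * (pc[1] - pa[1])
                - (pc[0] - pa[0]) * (pb[1] - pa[1]))
    if area2 == 0:
        return math.inf
    return a * b * c / (2.0 * area2)


def _alpha_shape(points: np.ndarray, alpha: float) -> Polygon | None:
    """Alpha shape (union of Delaunay triangles with circumradius <= alpha).

    Returns None when the result is empty, disconnected, or invalid, in which
    case the caller falls back to the convex hull.
    """
    try:
        tri = Delaunay(points)
    except Exception:
        return None
    keep = []
    for simplex in tri.simplices:
        pa, pb, pc = points[simplex]
        if _circumradius(pa, pb, pc) <= alpha:
            keep.append(Polygon([pa, pb, pc]))
    if not keep:
        return None
    union = unary_union(keep)
    if not isinstance(union, Polygon) or union.is_empty or not union.is_valid:
        return None
    return union


def build_la_polygon(member_coords: np.ndarray,
                     hull_buffer: float = 100.0,
                     hull_alpha: float = 150.0) -> tuple[Polygon, bool]:
    """Buffered concave hull of a point set.

    Degenerate inputs are handled in closed form: one point gives a disc of
    radius ``hull_buffer``; two points or a collinear set give a capsule.
    When the alpha shape is empty, disconnected or fails to cover every
    input point after buffering, the convex hull is used instead (logged).
    Round buffer joins use 32 segments per quarter turn, so closed-form
    areas are matched to well under 1%.

    Returns ``(polygon, convex_fallback_used)``.
    """
    pts = np.asarray(member_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValidationError("build_la_polygon requires at least one point")
    unique = np.unique(pts, axis=0)
    fallback = False
    if len(unique) == 1:
        base = Point(unique[0])
    elif len(unique) == 2:
        base = LineString(unique)
    else:
        hull = MultiPoint(unique).convex_hull
        if not isinstance(hull, Polygon):  # collinear
            base = hull  # LineString -> capsule after buffering
        else:
            base = _alpha_shape(unique, hull_alpha)
            if base is None:
                base = hull
                fallback = True
                logger.info("alpha shape degenerate for %d points; "
                            "convex hull fallback", len(unique))
    poly = base.buffer(hull_buffer, quad_segs=32)
    if not shapely.intersects_xy(poly, pts[:, 0], pts[:, 1]).all():
        # isolated points dropped by the alpha filter: fall back to convex
        hull = MultiPoint(unique).convex_hull
        poly = hull.buffer(hull_buffer, quad_segs=32)
        fallback = True
        logger.info("buffered alpha shape missed input points; convex fallback")
    return poly, fallback


# ---------------------------------------------------------------------------
# stage 5: cell assignment

def assign_cells_to_las(cellmap: CellMap,
                        polygons: list[tuple[int, Polygon, tuple[float, float]]],
                        ) -> pd.Series:
    """Assign every cell to an LA or to the outside compartment.

    ``polygons`` holds ``(la_id, polygon, source_centroid)``.  A cell belongs
    to an LA iff its point lies inside or on the polygon; a cell covered by
    several overlapping polygons goes to the LA whose source-cluster centroid
    is nearest (ties to the lower ``la_id``).  Returns a Series indexed by
    ``cell_id`` with the LA id or :data:`~lymphagg.io.OUTSIDE`.
    """
    ids = cellmap.cells["cell_id"].to_numpy()
    xy = cellmap.coordinates()
    assignment = np.full(len(ids), OUTSIDE, dtype=int)
    best_dist = np.full(len(ids), np.inf)
    for la_id, poly, centroid in sorted(polygons, key=lambda t: t[0]):
        inside = shapely.intersects_xy(poly, xy[:, 0], xy[:, 1])
        if not inside.any():
            continue
        d = np.hypot(xy[inside, 0] - centroid[0], xy[inside, 1] - centroid[1])
        idx = np.flatnonzero(inside)
        better = d < best_dist[idx]  # strict: ties keep the lower la_id
        take = idx[better]
        assignment[take] = la_id
        best_dist[take] = d[better]
    return pd.Series(assignment, index=ids, name="la_id")


# ---------------------------------------------------------------------------
# full pipeline

def detect_lymphoid_aggregates(cellmap: CellMap,
                               config: Config | None = None,
                               ) -> tuple[list[LymphoidAggregate], pd.Series]:
    """Run the full LA demarcation pipeline on one sample.

    Returns the detected aggregates and the per-cell membership Series
    (``cell_id`` → la_id, or :data:`~lymphagg.io.OUTSIDE`).
    """
    cfg = config or Config()
    seeds = select_chemokine_seed_cells(
        cellmap, pair_radius=cfg.pair_radius,
        positivity_min=cfg.marker_positivity_min,
        self_pairing=cfg.self_pairing)
    clusters = cluster_seed_cells(cellmap, seeds, radius=cfg.dbscan_radius,
                                  min_cells=cfg.min_cluster_cells)
    clusters = merge_clusters(clusters, cellmap, merge_distance=cfg.merge_distance)

    coords = cellmap.cells.set_index("cell_id")[["x", "y"]]
    polygons: list[tuple[int, Polygon, tuple[float, float]]] = []
    meta: dict[int, tuple[Polygon, bool, LACluster]] = {}
    for la_id, cluster in enumerate(clusters):
        pts = coords.loc[cluster.member_ids].to_numpy(dtype=float)
        poly, fb = build_la_polygon(pts, hull_buffer=cfg.hull_buffer,
                                    hull_alpha=cfg.hull_alpha)
        polygons.append((la_id, poly, cluster.centroid))
        meta[la_id] = (poly, fb, cluster)

    membership = assign_cells_to_las(cellmap, polygons)
    types = cellmap.cells.set_index("cell_id")["cell_type"]
    aggregates: list[LymphoidAggregate] = []
    for la_id, (poly, fb, cluster) in meta.items():
        members = sorted(membership.index[membership == la_id])
        counts = types.loc[members].value_counts().to_dict()
        aggregates.append(LymphoidAggregate(
            la_id=la_id, polygon=poly, area_um2=poly.area,
            member_ids=members,
            counts_by_type={k: int(v) for k, v in counts.items()},
            source_cluster_ids=cluster.source_cluster_ids,
            seed_centroid=cluster.centroid,
            convex_fallback=fb))
    logger.info("detected %d lymphoid aggregates from %d seed cells",
                len(aggregates), len(seeds))
    return aggregates, membership
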