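"""IHC-side lymphoid aggregate identification and density analyses.

Works on marker-centroid tables (one row per cell with boolean CD20, CD3,
CD4, CD8, CD23 and MUM1 calls) plus a pathologist-annotated tumor-bed
polygon.  The original identification of LAs on stained sections is
operator-driven; this module substitutes an explicit, fully parameterised
operationalisation so the analysis is reproducible: DBSCAN over CD20+
centroids proposes candidate clusters, a cluster becomes an LA when it holds
strictly more than 50 CD20+ cells and has a proximal CD3+ contingent, and
the LA polygon is the buffered concave hull of its CD20+ members (reusing
the spatial module's hull builder).  Location (intra- vs extra-tumoral) is
called from the polygon centroid against the tumor bed, boundary inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .config import Config
from .errors import FormatError, ValidationError
from .io import RegionPolygon
from .la_detection import _dbscan, build_la_polygon
from .la_statistics import UM2_PER_MM2

logger = logging.getLogger(__name__)

MARKERS = ("cd20", "cd3", "cd4", "cd8", "cd23", "mum1")
LINEAGE_MARKERS = ("cd20", "cd3", "mum1")


@dataclass
class IHCLymphoidAggregate:
    """An LA called from IHC marker centroids."""

    la_id: int
    polygon: Polygon
    area_um2: float
    n_cd20: int
    n_cd3: int
    n_cd23: int
    n_mum1: int
    member_ids: list[str]
    location: str | None = None          # intra_tumoral / extra_tumoral
    cd23_positive: bool = False


def validate_ihc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, unique ids; log lineage co-positivity."""
    for col in ("cell_id", "x", "y") + MARKERS:
        if col not in table.columns:
            raise FormatError(f"IHC table missing column {col!r}")
    if table["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in IHC table")
    co = table[list(LINEAGE_MARKERS)].astype(bool).sum(axis=1) > 1
    if co.any():
        logger.info("IHC table: %d cells positive for more than one "
                    "lineage marker", int(co.sum()))
    return table


def identify_ihc_las(table: pd.DataFrame,
                     config: Config | None = None) -> list[IHCLymphoidAggregate]:
    """Identify LAs as dense CD20+ clusters with proximal CD3+ cells.

    DBSCAN (eps ``ihc_eps``, ``ihc_min_samples``) clusters CD20+ centroids;
    clusters are kept when they hold strictly more than ``ihc_min_cd20``
    CD20+ cells and at least ``cd3_min`` CD3+ cells lie within
    ``cd3_radius`` µm of the cluster's convex hull.  Marker counts are
    tallied inside the buffered concave-hull polygon.
    """
    cfg = config or Config()
    validate_ihc_table(table)
    table = table.sort_values("cell_id").reset_index(drop=True)
    cd20 = table[table["cd20"].astype(bool)]
    if cd20.empty:
        return []
    xy20 = cd20[["x", "y"]].to_numpy(dtype=float)
    labels = _dbscan(xy20, eps=cfg.ihc_eps, min_samples=cfg.ihc_min_samples)

    cd3 = table[table["cd3"].astype(bool)]
    xy3 = cd3[["x", "y"]].to_numpy(dtype=float)

    las: list[IHCLymphoidAggregate] = []
    la_id = 0
    for lab in range(labels.max() + 1 if labels.size else 0):
        mask = labels == lab
        if int(mask.sum()) <= cfg.ihc_min_cd20:     # strict > 50
            continue
        pts = xy20[mask]
        hull = shapely.MultiPoint(pts).convex_hull
        if len(xy3):
            d = shapely.distance(hull, shapely.points(xy3))
            n_near = int((d <= cfg.cd3_radius).sum())
        else:
            n_near = 0
        if n_near < cfg.cd3_min:
            continue
        poly, _ = build_la_polygon(pts, hull_buffer=cfg.ihc_hull_buffer,
                                   hull_alpha=cfg.hull_alpha)
        inside = shapely.intersects_xy(
            poly, table["x"].to_numpy(), table["y"].to_numpy())
        counts = {m: int(table.loc[inside, m].astype(bool).sum())
                  for m in MARKERS}
        member_ids = sorted(cd20["cell_id"].to_numpy()[mask])
        las.append(IHCLymphoidAggregate(
            la_id=la_id, polygon=poly, area_um2=poly.area,
            n_cd20=counts["cd20"], n_cd3=counts["cd3"],
            n_cd23=counts["cd23"], n_mum1=counts["mum1"],
            member_ids=[str(m) for m in member_ids],
            cd23_positive=counts["cd23"] >= cfg.cd23_min_cells))
        la_id += 1
    logger.info("identified %d IHC LAs", len(las))
    return las


def classify_la_location(la: IHCLymphoidAggregate,
                         tumor_bed: RegionPolygon | None) -> str | None:
    """Intra-tumoral iff the LA polygon's centroid lies inside or on the
    tumor bed (boundary inclusive); without a tumor bed the call is skipped."""
    if tumor_bed is None:
        logger.info("LA %d: no tumor bed annotation; location not classified",
                    la.la_id)
        return None
    c = la.polygon.centroid
    intra = bool(shapely.intersects_xy(tumor_bed.polygon, c.x, c.y))
    la.location = "intra_tumoral" if intra else "extra_tumoral"
    return la.location


def intratumoral_pc_density(table: pd.DataFrame,
                            tumor_bed: RegionPolygon) -> float:
    """MUM1+ cells inside the tumor bed per mm² of tumor-bed area."""
    validate_ihc_table(table)
    if tumor_bed is None or tumor_bed.polygon.area <= 0:
        raise ValidationError("tumor bed polygon is missing or degenerate")
    mum1 = table[table["mum1"].astype(bool)]
    inside = shapely.intersects_xy(tumor_bed.polygon,
                                   mum1["x"].to_numpy(), mum1["y"].to_numpy())
    return float(inside.sum()) / tumor_bed.polygon.area * UM2_PER_MM2


def la_density_summaries(las: list[IHCLymphoidAggregate]) -> pd.DataFrame:
    """Per-LA marker densities (cells/mm²), location and CD23 call."""
    rows = []
    for la in las:
        row = {"la_id": la.la_id, "area_um2": la.area_um2,
               "location": la.location, "cd23_positive": la.cd23_positive}
        for m, n in (("cd20", la.n_cd20), ("cd3", la.n_cd3),
                     ("cd23", la.n_cd23), ("mum1", la.n_mum1)):
            row[f"n_{m}"] = n
            row[f"density_{m}"] = n / la.area_um2 * UM2_PER_MM2
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sided Mann-Whitney rank-sum comparison of two density groups."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValidationError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"U": float(u), "p": float(p),
            "n_a": len(values_a), "n_b": len(values_b)}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_value: float
    n: int


def simple_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Least-squares regression of y on x with the two-sided slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("regression requires n >= 3")
    reg = stats.linregress(x, y)
    return RegressionResult(float(reg.slope), float(reg.intercept),
                            float(reg.pvalue), float(reg.rvalue), len(x))


def correlate_pc_with_la_burden(per_tumor: pd.DataFrame) -> dict[str, RegressionResult]:
    """Regress intra-tumoral plasma-cell burden on LA burden per tumor.

    ``per_tumor`` needs columns ``pc_count`` (or ``pc_density``) plus
    ``intra_la_count``/``extra_la_count`` (or the density analogues).  For
    each available predictor column the simple regression of the PC column
    on it is returned.
    """
    response = ("pc_count" if "pc_count" in per_tumor.columns
                else "pc_density" if "pc_density" in per_tumor.columns
                else None)
    if response is None:
        raise ValidationError("per_tumor needs a pc_count or pc_density column")
    predictors = [c for c in ("intra_la_count", "extra_la_count",
                              "intra_la_density", "extra_la_density")
                  if c in per_tumor.columns]
    if not predictors:
        raise ValidationError("per_tumor has no LA burden columns")
    out = {}
    for pred in predictors:
        out[pred] = simple_regression(per_tumor[pred].to_numpy(),
                                      per_tumor[response].to_numpy())
    return out
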