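"""Readers and writers for the external formats the pipeline touches.

Cell tables are delimited text (CSV/TSV) with one row per cell; sparse
expression matrices are MatrixMarket triplets with companion feature/cell
lists; polygons (LA boundaries, tumor bed) are GeoJSON with coordinates in
micrometres in the source frame.  Coordinates are planar µm with y increasing
upward and an arbitrary origin; no axis flip is ever applied implicitly, so
image-convention inputs must be pre-flipped by the caller.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Polygon, mapping, shape
from shapely.geometry.polygon import orient

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Controlled cell-type vocabulary used throughout the package.  ``B`` are
#: B cells, ``PC`` plasma cells, ``T_PEX``/``T_TEX`` progenitor- and
#: terminally-exhausted CD8 T cells, ``T_CM`` central-memory T cells,
#: ``T_other`` the remaining T-cell states pooled.
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "tumor", "fibroblast", "myeloid", "B", "PC",
    "T_CM", "T_other", "T_PEX", "T_TEX",
)

REQUIRED_CELL_COLUMNS = ("cell_id", "x", "y", "cell_type")


@dataclass
class CellMap:
    """Spatial table of cells for one sample.

    ``cells`` has required columns ``cell_id, x, y, cell_type``; every
    remaining column is interpreted as a per-gene transcript count.
    """

    sample_id: str
    cells: pd.DataFrame
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        df = self.cells
        for col in REQUIRED_CELL_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"cell table missing required column {col!r}")
        if df["cell_id"].duplicated().any():
            dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate cell_id {dup!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite cell coordinates")
        unknown = set(df["cell_type"]) - set(self.vocabulary)
        if unknown:
            raise ValidationError(f"cell_type labels outside vocabulary: {sorted(unknown)}")
        for gene in self.gene_columns:
            col = df[gene].to_numpy()
            if np.any(col < 0):
                raise ValidationError(f"negative transcript count in column {gene!r}")
            if not np.allclose(col, np.round(col)):
                raise ValidationError(f"non-integer transcript count in column {gene!r}")
            if df[gene].dtype.kind != "i":
                df[gene] = col.astype(np.int64)
        self.cells = df.reset_index(drop=True)

    @property
    def gene_columns(self) -> list[str]:
        return [c for c in self.cells.columns if c not in REQUIRED_CELL_COLUMNS]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coordinates(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    def counts(self, gene: str) -> np.ndarray:
        if gene not in self.cells.columns:
            raise ValidationError(f"gene column {gene!r} absent from cell table")
        return self.cells[gene].to_numpy()

    def positive(self, gene: str, min_count: int = 1) -> np.ndarray:
        """Boolean mask of cells with ``count >= min_count`` for ``gene``."""
        return self.counts(gene) >= min_count


@dataclass
class RegionPolygon:
    """A labelled planar polygon (µm); canonically counter-clockwise."""

    polygon: Polygon
    label: str | None = None

    def __post_init__(self) -> None:
        poly = self.polygon
        if not isinstance(poly, Polygon) or poly.is_empty:
            raise ValidationError("RegionPolygon requires a non-empty polygon")
        if len(set(poly.exterior.coords[:-1])) < 3:
            raise ValidationError("polygon needs at least 3 distinct vertices")
        if not poly.is_valid:
            raise ValidationError("polygon is self-intersecting or otherwise invalid")
        self.polygon = orient(poly, sign=1.0)
        if self.polygon.area <= 0:
            raise ValidationError("polygon has non-positive area")

    @property
    def area_um2(self) -> float:
        return self.polygon.area


# ---------------------------------------------------------------------------
# cell tables

def read_cell_table(path: str | Path,
                    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
                    sample_id: str | None = None) -> CellMap:
    """Load a delimited cell table into a validated :class:`CellMap`.

    Rows whose ``cell_type`` is outside the vocabulary are rejected and
    logged (never silently dropped); structural problems (missing columns,
    duplicate ids, negative counts) raise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    bad = ~df["cell_type"].isin(vocabulary)
    if bad.any():
        for label, n in df.loc[bad, "cell_type"].value_counts().items():
            logger.warning("%s: rejected %d rows with unknown cell_type %r",
                           path.name, n, label)
        df = df.loc[~bad]
    logger.info("%s: loaded %d cells, rejected %d rows", path.name,
                (~bad).sum(), bad.sum())
    return CellMap(sample_id=sample_id or path.stem, cells=df,
                   vocabulary=tuple(vocabulary))


def write_cell_table(cellmap: CellMap, path: str | Path) -> None:
    """Write a cell table as CSV; coordinates carry 6 decimals."""
    df = cellmap.cells.copy()
    df["x"] = df["x"].map(lambda v: f"{v:.6f}")
    df["y"] = df["y"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sparse expression matrices

def read_expression_matrix(matrix_path: str | Path,
                           features_path: str | Path,
                           cells_path: str | Path,
                           ) -> tuple[list[str], list[str], sp.csr_matrix]:
    """Read a MatrixMarket genes×cells count matrix with companion lists.

    Returns ``(gene_ids, cell_ids, matrix)`` with ``matrix`` CSR of integer
    counts.  Per-cell totals equal the column sums of the sparse matrix.
    """
    genes = Path(features_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    mat = scipy.io.mmread(matrix_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {mat.shape} disagrees with {len(genes)} features "
            f"x {len(cells)} cells")
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValidationError("expression matrix contains non-integer values")
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("expression matrix contains negative values")
    mat.data = mat.data.astype(np.int64)
    return genes, cells, mat


def write_expression_matrix(matrix: sp.spmatrix,
                            gene_ids: Sequence[str],
                            cell_ids: Sequence[str],
                            matrix_path: str | Path,
                            features_path: str | Path,
                            cells_path: str | Path) -> None:
    mat = sp.coo_matrix(matrix)
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise ValidationError("matrix shape disagrees with id lists")
    scipy.io.mmwrite(str(matrix_path), mat, field="integer")
    Path(features_path).write_text("\n".join(gene_ids) + ("\n" if gene_ids else ""))
    Path(cells_path).write_text("\n".join(cell_ids) + ("\n" if cell_ids else ""))


# ---------------------------------------------------------------------------
# GeoJSON polygons

def _polygon_to_geojson(poly: Polygon) -> dict:
    return mapping(orient(poly, sign=1.0))


def write_la_geojson(aggregates: Iterable, path: str | Path) -> None:
    """Serialize detected LAs as a GeoJSON FeatureCollection (coords in µm).

    Feature properties carry ``la_id``, ``area_um2``, per-type counts and the
    plasma-cell-to-B-cell ratio when B/PC counts are available.
    """
    from .la_statistics import pbr  # local import to avoid a cycle

    features = []
    for la in aggregates:
        poly = la.polygon
        if not isinstance(poly, Polygon) or poly.is_empty or not poly.is_valid:
            raise ValidationError(f"LA {la.la_id}: invalid polygon, cannot serialize")
        props: dict = {
            "la_id": la.la_id,
            "area_um2": la.area_um2,
            "n_cells": int(sum(la.counts_by_type.values())),
        }
        for cell_type, n in sorted(la.counts_by_type.items()):
            props[f"n_{cell_type}"] = int(n)
        if "PC" in la.counts_by_type or "B" in la.counts_by_type:
            props["pbr"] = pbr(la.counts_by_type.get("PC", 0),
                               la.counts_by_type.get("B", 0))
        features.append({
            "type": "Feature",
            "geometry": _polygon_to_geojson(poly),
            "properties": props,
        })
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=1))


def read_la_geojson(path: str | Path) -> list[tuple[dict, Polygon]]:
    """Read back a FeatureCollection; returns ``(properties, polygon)`` pairs."""
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    out = []
    for feat in data["features"]:
        out.append((feat.get("properties", {}), shape(feat["geometry"])))
    return out


def write_region_geojson(region: RegionPolygon, path: str | Path) -> None:
    feature = {
        "type": "Feature",
        "geometry": _polygon_to_geojson(region.polygon),
        "properties": {"label": region.label},
    }
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": [feature]}, indent=1))


def read_region_geojson(path: str | Path) -> RegionPolygon:
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    if len(feats) != 1:
        raise FormatError(f"expected exactly one polygon feature, found {len(feats)}")
    geom = shape(feats[0]["geometry"])
    return RegionPolygon(polygon=geom, label=feats[0].get("properties", {}).get("label"))


# ---------------------------------------------------------------------------
# membership tables

OUTSIDE = -1  # membership code for cells not assigned to any LA


def write_membership(membership: pd.Series, path: str | Path) -> None:
    """Write a ``cell_id,la_id`` CSV; unassigned cells get ``outside``."""
    df = pd.DataFrame({
        "cell_id": membership.index,
        "la_id": [("outside" if v == OUTSIDE else int(v)) for v in membership],
    })
    df.to_csv(path, index=False)


def read_membership(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    for col in ("cell_id", "la_id"):
        if col not in df.columns:
            raise FormatError(f"membership table missing column {col!r}")
    values = [OUTSIDE if v == "outside" else int(v) for v in df["la_id"]]
    return pd.Series(values, index=df["cell_id"], name="la_id")
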