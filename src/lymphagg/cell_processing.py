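"""Cell-level processing upstream of niche analysis.

Three steps that precede LA demarcation on image-based spatial data:

* QC filtering — keep cells with at least ``min_genes`` detected genes and
  ``min_transcripts`` total transcripts (both boundaries inclusive);
* representative subsampling — per cluster, retain up to ``n_max`` cells
  whose expression profiles are most similar to the cluster's mean profile;
* low-confidence filtering — label-transfer prediction scores strictly below
  the threshold become "unassigned" and drop out of downstream denominators.

Clustering itself (graph-based clustering, PCA, label transfer) is upstream:
this module consumes its outputs.  Similarity for representative selection is
Euclidean distance on per-cell depth-normalised, log1p-transformed counts by
default (Pearson correlation distance is available); the cluster mean is
computed in the same transformed space, and ties are broken by ascending
cell id so results are reproducible without a seed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

logger = logging.getLogger(__name__)


def qc_filter_cells(matrix: sp.spmatrix,
                    cell_ids: Sequence[str],
                    min_genes: int = 10,
                    min_transcripts: int = 20,
                    ) -> tuple[list[str], list[str]]:
    """Partition cells into kept/rejected by the detected-gene and
    total-transcript thresholds (kept iff both are met, inclusive).

    ``matrix`` is genes x cells.
    """
    mat = sp.csc_matrix(matrix)
    if mat.shape[1] != len(cell_ids):
        raise ValidationError("cell_ids length disagrees with matrix columns")
    n_genes = mat.getnnz(axis=0)
    totals = np.asarray(mat.sum(axis=0)).ravel()
    keep = (n_genes >= min_genes) & (totals >= min_transcripts)
    kept = [cid for cid, k in zip(cell_ids, keep) if k]
    rejected = [cid for cid, k in zip(cell_ids, keep) if not k]
    logger.info("QC kept %d / %d cells", len(kept), len(cell_ids))
    return kept, rejected


def normalize_log1p(matrix: sp.spmatrix, target_sum: float = 1e4) -> np.ndarray:
    """Per-cell depth normalisation to ``target_sum`` followed by log1p.

    Returns a dense genes x cells float array; all-zero cells stay zero.
    """
    mat = sp.csc_matrix(matrix, dtype=float)
    totals = np.asarray(mat.sum(axis=0)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    out = mat.toarray() * scale[np.newaxis, :]
    return np.log1p(out)


def select_representative_cells(matrix: sp.spmatrix,
                                cell_ids: Sequence[str],
                                labels: Sequence[str],
                                n_max: int = 500,
                                metric: str = "euclidean",
                                ) -> dict[str, list[str]]:
    """Per cluster, select up to ``n_max`` cells nearest the cluster mean.

    Distances are computed on depth-normalised log1p counts; every selected
    cell is at least as close to its cluster's mean as every unselected cell
    of the same cluster, with ties broken by ascending cell id.  Returns a
    mapping cluster label -> selected cell ids (in selection order).
    """
    if len(cell_ids) != len(labels):
        raise ValidationError("labels must cover every cell")
    if metric not in ("euclidean", "correlation"):
        raise ValidationError(f"unknown metric {metric!r}")
    X = normalize_log1p(matrix)  # genes x cells
    ids = np.asarray(cell_ids, dtype=object)
    labels = np.asarray(labels, dtype=object)
    selected: dict[str, list[str]] = {}
    for lab in pd.unique(labels):
        cols = np.flatnonzero(labels == lab)
        if len(cols) == 0:
            logger.info("cluster %r is empty; skipped", lab)
            continue
        sub = X[:, cols]
        mean = sub.mean(axis=1)
        if metric == "euclidean":
            dist = np.linalg.norm(sub - mean[:, np.newaxis], axis=0)
        else:
            centered = sub - sub.mean(axis=0, keepdims=True)
            mc = mean - mean.mean()
            denom = (np.linalg.norm(centered, axis=0) * np.linalg.norm(mc))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.where(denom > 0, centered.T @ mc / denom, 0.0)
            dist = 1.0 - corr
        order = np.lexsort((ids[cols], dist))
        take = order[: min(n_max, len(cols))]
        selected[str(lab)] = [str(i) for i in ids[cols][take]]
    return selected


def filter_low_confidence(labels: pd.Series,
                          scores: pd.Series,
                          threshold: float = 0.6) -> pd.Series:
    """Set labels with prediction score strictly below ``threshold`` to
    ``"unassigned"``; scores at or above the threshold keep their label.

    Every labelled cell must carry a score.
    """
    scores = scores.reindex(labels.index)
    if scores.isna().any():
        missing = labels.index[scores.isna()][0]
        raise ValidationError(f"missing prediction score for cell {missing!r}")
    if ((scores < 0) | (scores > 1)).any():
        raise ValidationError("prediction scores must lie in [0, 1]")
    out = labels.copy()
    out[scores < threshold] = "unassigned"
    n = int((scores < threshold).sum())
    logger.info("%d / %d cells designated unassigned", n, len(labels))
    return out
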