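"""Statistics over demarcated lymphoid aggregates.

The central quantity is the plasma-cell-to-B-cell ratio

    PBR = log2(n_PC + 1) - log2(n_B + 1),

with "high PBR" meaning more plasma cells than B cells (PBR > 0).  The module
also computes pooled inside/outside compartment fractions, log2 enrichment
scores, per-LA subset densities (cells/mm²), the log2 ratio of terminally- to
progenitor-exhausted T-cell counts (with the same +1 pseudocount as the PBR),
and the association analyses: Spearman rank correlation (exact permutation p
for n <= 9, t-approximation otherwise) together with a simple least-squares
regression for trend lines.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import OUTSIDE, CellMap
from .la_detection import LymphoidAggregate

logger = logging.getLogger(__name__)

UM2_PER_MM2 = 1e6


def pbr(n_pc: int, n_b: int) -> float:
    """Plasma-cell-to-B-cell ratio: log2(n_PC+1) - log2(n_B+1).

    Antisymmetric under swapping the arguments.
    """
    if n_pc < 0 or n_b < 0:
        raise ValidationError("pbr requires non-negative counts")
    return math.log2(n_pc + 1) - math.log2(n_b + 1)


def log2_count_ratio(n_num: int, n_den: int) -> float:
    """log2((n_num + 1) / (n_den + 1)); pseudocount mirrors the PBR."""
    if n_num < 0 or n_den < 0:
        raise ValidationError("counts must be non-negative")
    return math.log2(n_num + 1) - math.log2(n_den + 1)


@dataclass
class CompartmentFractions:
    """Relative cell-type fractions inside all LAs and in outside tissue."""

    inside: dict[str, float]
    outside: dict[str, float]
    n_inside: int
    n_outside: int


def compartment_fractions(cellmap: CellMap,
                          membership: pd.Series,
                          supergroups: dict[str, str] | None = None,
                          mode: str = "pooled") -> CompartmentFractions:
    """Relative fraction of each cell type inside LAs vs outside.

    ``supergroups`` optionally maps fine types onto combined groups (e.g.
    pooling the T-cell clusters into one "T" group) before fractions are
    taken.  Cells labelled ``unassigned`` are excluded from denominators.

    ``mode="pooled"`` (default) pools counts over all LA member cells;
    ``mode="per_la_mean"`` averages each LA's own fraction vector instead.
    """
    df = cellmap.cells.set_index("cell_id")
    types = df["cell_type"]
    if supergroups:
        types = types.map(lambda t: supergroups.get(t, t))
    keep = types != "unassigned"
    types = types[keep]
    inside_mask = membership.reindex(types.index).ne(OUTSIDE)
    n_in = int(inside_mask.sum())
    n_out = int((~inside_mask).sum())
    if n_in == 0 or n_out == 0:
        raise ValidationError(
            "a compartment contains zero cells; fractions are undefined")
    if mode == "pooled":
        frac_in = (types[inside_mask].value_counts() / n_in).to_dict()
        frac_out = (types[~inside_mask].value_counts() / n_out).to_dict()
    elif mode == "per_la_mean":
        las = membership.reindex(types.index)
        per_la = []
        for la_id, grp in types[inside_mask].groupby(las[inside_mask]):
            per_la.append(grp.value_counts(normalize=True))
        frac_in = pd.DataFrame(per_la).fillna(0.0).mean(axis=0).to_dict()
        frac_out = (types[~inside_mask].value_counts() / n_out).to_dict()
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    all_types = sorted(set(types))
    inside = {t: float(frac_in.get(t, 0.0)) for t in all_types}
    outside = {t: float(frac_out.get(t, 0.0)) for t in all_types}
    return CompartmentFractions(inside=inside, outside=outside,
                                n_inside=n_in, n_outside=n_out)


def enrichment_score(frac_in: float, frac_out: float,
                     pseudo: float = 0.0) -> float:
    """log2 ratio of relative fractions inside vs outside.

    With ``pseudo`` 0 and both fractions positive this is a pure log2 ratio
    and is antisymmetric; with both fractions zero and no pseudocount the
    score is undefined and returned as NaN.
    """
    if not (0.0 <= frac_in <= 1.0 and 0.0 <= frac_out <= 1.0):
        raise ValidationError("fractions must lie in [0, 1]")
    if pseudo < 0:
        raise ValidationError("pseudocount must be non-negative")
    num, den = frac_in + pseudo, frac_out + pseudo
    if num == 0.0 and den == 0.0:
        return math.nan
    if num == 0.0 or den == 0.0:
        return -math.inf if num == 0.0 else math.inf
    return math.log2(num / den)


def enrichment_table(fractions: CompartmentFractions) -> pd.DataFrame:
    """Per-type enrichment with an automatic pseudocount where needed.

    Types with both fractions positive use the raw log2 ratio (pseudo 0);
    a type absent from one compartment uses half of one cell over that
    compartment's total, and the pseudocount used is declared in the output.
    """
    rows = []
    for t in fractions.inside:
        fi, fo = fractions.inside[t], fractions.outside[t]
        if fi > 0 and fo > 0:
            pseudo = 0.0
        else:
            pseudo = 0.5 / min(fractions.n_inside, fractions.n_outside)
        rows.append({"cell_type": t, "frac_inside": fi, "frac_outside": fo,
                     "pseudo": pseudo,
                     "enrichment": enrichment_score(fi, fo, pseudo)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-LA profiles

def la_profiles(aggregates: list[LymphoidAggregate],
                subset_vocab: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-LA profile table: counts, PBR, densities, exhaustion log-ratio.

    Densities are cells/mm² (count / area_um2 * 1e6).  ``log2_tex_pex`` is
    the +1-pseudocount log2 ratio of terminally- to progenitor-exhausted
    T-cell counts; ``high_pbr`` flags LAs with more plasma cells than B cells.
    """
    rows = []
    for la in aggregates:
        if la.area_um2 <= 0:
            raise ValidationError(f"LA {la.la_id} has non-positive area")
        counts = la.counts_by_type
        types = subset_vocab or tuple(sorted(counts))
        row: dict = {"la_id": la.la_id, "area_um2": la.area_um2,
                     "n_cells": int(sum(counts.values()))}
        for t in types:
            n = int(counts.get(t, 0))
            row[f"n_{t}"] = n
            row[f"density_{t}"] = n / la.area_um2 * UM2_PER_MM2
        n_pc, n_b = counts.get("PC", 0), counts.get("B", 0)
        row["pbr"] = pbr(n_pc, n_b)
        row["log2_tex_pex"] = log2_count_ratio(counts.get("T_TEX", 0),
                                               counts.get("T_PEX", 0))
        row["high_pbr"] = n_pc > n_b
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association analyses

@dataclass
class AssociationResult:
    """Spearman correlation plus least-squares trend line."""

    spearman_rho: float
    spearman_p: float
    ls_slope: float
    ls_intercept: float
    n: int


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (all n! orderings of y)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rp = ry[list(perm)]
        rho = np.corrcoef(rx, rp)[0, 1]
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def associate(x: np.ndarray, y: np.ndarray,
              exact_max_n: int = 9) -> AssociationResult:
    """Spearman rho (average ranks for ties) + simple linear regression.

    p is two-sided: exact permutation for n <= ``exact_max_n``, otherwise the
    t-approximation.  Zero variance in either variable leaves rho undefined
    (NaN) and is logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("association requires n >= 3 paired observations")
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance: rho and slope undefined")
        slope = math.nan
        intercept = float(np.mean(y)) if np.ptp(x) == 0 else math.nan
        return AssociationResult(math.nan, math.nan, slope, intercept, n)
    reg = stats.linregress(x, y)
    rho, p = stats.spearmanr(x, y)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    return AssociationResult(float(rho), float(p),
                             float(reg.slope), float(reg.intercept), n)


def associate_pbr(profiles: pd.DataFrame,
                  response_field: str) -> AssociationResult:
    """Association of a per-LA response (e.g. a subset density or the
    exhaustion log-ratio) with the PBR across LAs."""
    if response_field not in profiles.columns:
        raise ValidationError(f"profiles lack column {response_field!r}")
    return associate(profiles["pbr"].to_numpy(),
                     profiles[response_field].to_numpy())


def inside_outside_patient_ratio(per_patient: dict[str, tuple[CellMap, pd.Series]],
                                 ) -> tuple[pd.DataFrame, AssociationResult]:
    """Per-patient exhausted-T log2 ratios inside vs outside LAs.

    For each patient, counts of T_TEX and T_PEX cells are pooled over all of
    that patient's LA member cells (inside) and over all non-LA cells
    (outside); the log2 ratio uses the +1 pseudocount.  Both compartments of
    one tissue share the same area within a compartment, so the ratio of
    densities equals the ratio of counts.  Patients with no LA cells are
    excluded (logged).  Association across patients requires n >= 3.
    """
    rows = []
    for patient, (cellmap, membership) in sorted(per_patient.items()):
        types = cellmap.cells.set_index("cell_id")["cell_type"]
        inside = membership.reindex(types.index).ne(OUTSIDE)
        if not inside.any():
            logger.warning("patient %s has no LA cells; excluded", patient)
            continue
        t_in = types[inside].value_counts()
        t_out = types[~inside].value_counts()
        rows.append({
            "patient": patient,
            "log2_tex_pex_inside": log2_count_ratio(
                int(t_in.get("T_TEX", 0)), int(t_in.get("T_PEX", 0))),
            "log2_tex_pex_outside": log2_count_ratio(
                int(t_out.get("T_TEX", 0)), int(t_out.get("T_PEX", 0))),
        })
    table = pd.DataFrame(rows)
    result = associate(table["log2_tex_pex_inside"].to_numpy(),
                       table["log2_tex_pex_outside"].to_numpy())
    return table, result
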