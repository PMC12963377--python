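"""Synthetic spatial tissues, IHC slides, expression matrices and cohorts.

The tissue generator plants lymphoid aggregates (LAs) in a rectangle of
background tissue with full ground truth, emulating the structure the
analysis assumes: each LA is a disc of cells whose type composition is drawn
from a Dirichlet; its chemokine organisers (CCL19- and CXCL13-positive
cells) sit in an inner core of the disc, mirroring the focal chemokine
expression that defines LA centres in real tissue; stray chemokine-positive
singletons are scattered over the tissue as a Poisson noise process; and
each LA's exhausted-T-cell balance is coupled to its plasma-cell-to-B-cell
ratio (PBR) through

    log2(T_TEX : T_PEX) = beta0 + beta1 * PBR + Normal(0, sigma),

implemented on counts (draw T_PEX, then round T_TEX to match the targeted
+1-pseudocount log2 ratio) so that the planted beta1 is recoverable by the
analysis module's own estimator.  Every generator is deterministic under its
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry import Polygon

from .clinical import ClinicalRecord
from .errors import GenerationError, ValidationError
from .io import DEFAULT_VOCABULARY, CellMap, RegionPolygon

logger = logging.getLogger(__name__)

#: Background (non-LA) tissue composition: tumor-dominant with sparse
#: lymphocytes, so enrichment scores inside LAs are finite and nontrivial.
DEFAULT_BACKGROUND_PROBS: dict[str, float] = {
    "tumor": 0.55, "fibroblast": 0.20, "myeloid": 0.10,
    "B": 0.02, "PC": 0.03, "T_CM": 0.04, "T_other": 0.03,
    "T_PEX": 0.02, "T_TEX": 0.01,
}

#: Dirichlet concentrations for LA composition (exhausted T subsets are
#: drawn separately through the PBR coupling).  Symmetric B/PC weights give
#: roughly half of LAs a high PBR; lymphocytes dominate the composition.
DEFAULT_LA_DIRICHLET: dict[str, float] = {
    "tumor": 1.5, "fibroblast": 1.6, "myeloid": 1.3,
    "B": 1.9, "PC": 1.9, "T_CM": 1.0, "T_other": 0.8,
}


@dataclass
class TissueSimParams:
    """Parameters of the planted-LA tissue generator (distances in µm)."""

    width: float = 5000.0
    height: float = 5000.0
    n_background: int = 5000
    background_type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_PROBS))
    n_las: int = 10
    la_radius_mean: float = 110.0
    la_radius_sd: float = 8.0
    min_la_separation: float = 600.0
    la_n_cells_mean: float = 300.0
    la_composition_dirichlet: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LA_DIRICHLET))
    n_ccl19_per_la: int = 20
    n_cxcl13_per_la: int = 20
    #: radius (µm) of the chemokine organiser niche at the LA centre; kept
    #: below half the pairing/DBSCAN scales so organisers are mutually
    #: in range, mirroring the focal chemokine expression of real LA cores
    organizer_core_radius: float = 35.0
    chemokine_noise_rate: float = 2.0  # stray positives per mm²
    #: mean progenitor-exhausted pool per LA; large enough that count
    #: discretisation is negligible next to pbr_effect_sigma, so the
    #: planted coupling really is log-linear with Gaussian noise
    t_pex_mean: float = 60.0
    pbr_effect_beta0: float = 0.0
    pbr_effect_beta1: float = 1.0
    pbr_effect_sigma: float = 0.25
    #: when set, the background T_TEX:T_PEX balance tracks the tissue's mean
    #: targeted LA ratio (LA-derived exhausted T cells permeate the tumor),
    #: so inside/outside ratios are correlated across patients
    couple_background_exhaustion: bool = True
    seed: int = 0
    strict_recovery: bool = False
    #: hull buffer assumed when validating strict-recovery separation
    recovery_hull_buffer: float = 100.0

    def __post_init__(self) -> None:
        total = sum(self.background_type_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"background_type_probs sum to {total}, expected 1")
        if self.n_las < 0:
            raise ValidationError("n_las must be >= 0")
        if self.strict_recovery:
            needed = 2 * (self.la_radius_mean + self.recovery_hull_buffer)
            if self.min_la_separation <= needed:
                raise ValidationError(
                    "strict recovery requires min_la_separation > "
                    f"2*(la_radius_mean + hull_buffer) = {needed}")

    @classmethod
    def strict_recovery_preset(cls, seed: int = 0, n_las: int = 20,
                               **overrides) -> "TissueSimParams":
        """Well-separated, noise-free tissue where every planted LA should be
        recovered near-perfectly: 20 LAs with 20 organisers of each
        chemokine, >= 1200 µm separation, sparse background, zero noise."""
        params = cls(width=8000.0, height=8000.0, n_background=1000,
                     n_las=n_las, min_la_separation=1200.0,
                     chemokine_noise_rate=0.0, seed=seed,
                     strict_recovery=True)
        return replace(params, **overrides) if overrides else params


@dataclass
class SyntheticGroundTruth:
    """Planted structure of one synthetic tissue."""

    la_centers: list[tuple[float, float]]
    la_radii: list[float]
    la_member_ids: list[list[str]]
    counts_by_type: list[dict[str, int]]
    beta0: float
    beta1: float
    sigma: float
    params: TissueSimParams


def _place_centers(rng: np.random.Generator, n: int, width: float,
                   height: float, min_sep: float, margin: float,
                   max_restarts: int = 50) -> np.ndarray:
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    if n == 0:
        return np.empty((0, 2))
    for _ in range(max_restarts):
        centers: list[np.ndarray] = []
        attempts = 0
        while len(centers) < n and attempts < 2000:
            attempts += 1
            c = rng.uniform([margin, margin], [width - margin, height - margin])
            if all(np.hypot(*(c - o)) >= min_sep for o in centers):
                centers.append(c)
        if len(centers) == n:
            return np.array(centers)
    raise GenerationError(
        f"could not place {n} LA centers with separation {min_sep} "
        f"in a {width}x{height} rectangle")


def _uniform_disc(rng: np.random.Generator, n: int, center: np.ndarray,
                  radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_la_compositions(n_las: int, params: TissueSimParams,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-LA type counts with the PBR -> exhaustion coupling.

    Returns one row per LA with per-type counts, the realised PBR, the
    targeted log2 T_TEX:T_PEX ratio, and total member count.  Used by
    :func:`generate_tissue` and directly by parameter-recovery simulations
    (the coupling lives on counts, independent of spatial placement).
    """
    comp_types = list(params.la_composition_dirichlet)
    conc = np.array([params.la_composition_dirichlet[t] for t in comp_types])
    rows = []
    for _ in range(n_las):
        n_base = max(int(rng.poisson(params.la_n_cells_mean)),
                     params.n_ccl19_per_la + params.n_cxcl13_per_la, 1)
        comp = rng.dirichlet(conc)
        counts = dict(zip(comp_types, rng.multinomial(n_base, comp)))
        realized_pbr = (math.log2(counts.get("PC", 0) + 1)
                        - math.log2(counts.get("B", 0) + 1))
        target = (params.pbr_effect_beta0
                  + params.pbr_effect_beta1 * realized_pbr
                  + rng.normal(0.0, params.pbr_effect_sigma))
        n_pex = int(rng.poisson(params.t_pex_mean))
        n_tex = max(int(round((n_pex + 1) * 2.0 ** target - 1)), 0)
        counts["T_PEX"] = n_pex
        counts["T_TEX"] = n_tex
        rows.append({**{f"n_{t}": int(v) for t, v in counts.items()},
                     "pbr": realized_pbr, "target_log2_tex_pex": target,
                     "n_members": int(sum(counts.values()))})
    return pd.DataFrame(rows)


def generate_tissue(params: TissueSimParams,
                    ) -> tuple[CellMap, SyntheticGroundTruth]:
    """Generate a spatial tissue with planted LAs and full ground truth."""
    rng = np.random.default_rng(params.seed)
    types = list(DEFAULT_VOCABULARY)
    margin = params.la_radius_mean + params.recovery_hull_buffer + 50.0
    centers = _place_centers(rng, params.n_las, params.width, params.height,
                             params.min_la_separation, margin)
    # clip at +-2 sd so the member disc stays within the organiser hull's
    # reach plus the hull buffer (members are then captured by the polygon)
    radii = np.clip(rng.normal(params.la_radius_mean, params.la_radius_sd,
                               size=params.n_las),
                    params.la_radius_mean - 2 * params.la_radius_sd,
                    params.la_radius_mean + 2 * params.la_radius_sd)

    compositions = generate_la_compositions(params.n_las, params, rng)

    bg_types = list(params.background_type_probs)
    bg_probs = np.array([params.background_type_probs[t] for t in bg_types])
    if params.couple_background_exhaustion and params.n_las > 0:
        # the tissue-wide exhausted-T balance follows the mean LA target:
        # keep the total exhausted fraction, reapportion TEX vs PEX
        mean_target = float(compositions["target_log2_tex_pex"].mean())
        i_tex, i_pex = bg_types.index("T_TEX"), bg_types.index("T_PEX")
        p_ex = bg_probs[i_tex] + bg_probs[i_pex]
        w = 2.0 ** mean_target
        bg_probs = bg_probs.copy()
        bg_probs[i_tex] = p_ex * w / (1.0 + w)
        bg_probs[i_pex] = p_ex / (1.0 + w)

    frames: list[pd.DataFrame] = []
    bg_xy = rng.uniform([0, 0], [params.width, params.height],
                        size=(params.n_background, 2))
    bg = pd.DataFrame({
        "cell_id": [f"bg{i:06d}" for i in range(params.n_background)],
        "x": bg_xy[:, 0], "y": bg_xy[:, 1],
        "cell_type": rng.choice(bg_types, size=params.n_background, p=bg_probs),
        "CCL19": 0, "CXCL13": 0,
    })
    frames.append(bg)
    member_ids: list[list[str]] = []
    counts_list: list[dict[str, int]] = []
    for k in range(params.n_las):
        row = compositions.iloc[k]
        counts = {t: int(row.get(f"n_{t}", 0)) for t in types
                  if f"n_{t}" in row.index}
        n_members = int(row["n_members"])
        n_org = params.n_ccl19_per_la + params.n_cxcl13_per_la
        # organisers occupy an inner core of the disc; remaining members
        # fill the full disc
        core_r = min(params.organizer_core_radius, radii[k])
        org_xy = _uniform_disc(rng, n_org, centers[k], core_r)
        rest_xy = _uniform_disc(rng, n_members - n_org, centers[k], radii[k])
        xy = np.vstack([org_xy, rest_xy])
        type_labels = np.repeat(list(counts.keys()),
                                list(counts.values())).astype(object)
        rng.shuffle(type_labels)
        ccl19 = np.zeros(n_members, dtype=int)
        cxcl13 = np.zeros(n_members, dtype=int)
        ccl19[: params.n_ccl19_per_la] = 1
        cxcl13[params.n_ccl19_per_la: n_org] = 1
        ids = [f"la{k:02d}_c{i:04d}" for i in range(n_members)]
        frames.append(pd.DataFrame({
            "cell_id": ids, "x": xy[:, 0], "y": xy[:, 1],
            "cell_type": type_labels, "CCL19": ccl19, "CXCL13": cxcl13,
        }))
        member_ids.append(ids)
        counts_list.append(counts)

    # stray chemokine-positive singletons (stationary Poisson noise)
    area_mm2 = params.width * params.height / 1e6
    n_noise = int(rng.poisson(params.chemokine_noise_rate * area_mm2))
    if n_noise:
        noise_xy = rng.uniform([0, 0], [params.width, params.height],
                               size=(n_noise, 2))
        which = rng.integers(0, 2, size=n_noise)
        frames.append(pd.DataFrame({
            "cell_id": [f"noise{i:04d}" for i in range(n_noise)],
            "x": noise_xy[:, 0], "y": noise_xy[:, 1],
            "cell_type": rng.choice(bg_types, size=n_noise, p=bg_probs),
            "CCL19": (which == 0).astype(int),
            "CXCL13": (which == 1).astype(int),
        }))

    cells = pd.concat(frames, ignore_index=True)
    cellmap = CellMap(sample_id=f"synthetic_seed{params.seed}", cells=cells)
    truth = SyntheticGroundTruth(
        la_centers=[tuple(c) for c in centers],
        la_radii=[float(r) for r in radii],
        la_member_ids=member_ids,
        counts_by_type=counts_list,
        beta0=params.pbr_effect_beta0,
        beta1=params.pbr_effect_beta1,
        sigma=params.pbr_effect_sigma,
        params=params)
    return cellmap, truth


# ---------------------------------------------------------------------------
# IHC slides

@dataclass
class IHCSimParams:
    """Parameters of the synthetic IHC slide generator (distances in µm).

    ``cd20_per_la`` etc. may be scalars (broadcast) or per-LA sequences of
    length ``n_las_intra + n_las_extra``; intra-tumoral LAs are listed first.
    """

    width: float = 4000.0
    height: float = 4000.0
    tumor_bed: RegionPolygon | None = None  # default: left half of the slide
    n_las_intra: int = 3
    n_las_extra: int = 2
    cd20_per_la: int | Sequence[int] = 80
    cd3_per_la: int | Sequence[int] = 30
    cd23_per_la: int | Sequence[int] = 5
    mum1_per_la: int | Sequence[int] = 10
    la_radius: float = 100.0
    min_la_separation: float = 600.0
    mum1_density: float = 50.0  # scattered MUM1+ cells per mm² of tumor bed
    n_background: int = 500    # marker-negative cells
    seed: int = 0

    def bed(self) -> RegionPolygon:
        if self.tumor_bed is not None:
            return self.tumor_bed
        half = Polygon([(0, 0), (self.width / 2, 0),
                        (self.width / 2, self.height), (0, self.height)])
        return RegionPolygon(polygon=half, label="tumor_bed")

    def per_la(self, name: str) -> list[int]:
        value = getattr(self, name)
        n = self.n_las_intra + self.n_las_extra
        if np.isscalar(value):
            return [int(value)] * n
        value = list(value)
        if len(value) != n:
            raise ValidationError(f"{name} must have length {n}")
        return [int(v) for v in value]


IHC_COLUMNS = ("cell_id", "x", "y", "cd20", "cd3", "cd4", "cd8", "cd23", "mum1")


def generate_ihc_slide(params: IHCSimParams,
                       ) -> tuple[pd.DataFrame, RegionPolygon, dict]:
    """Generate a boolean-marker centroid table with planted IHC LAs.

    Intra-tumoral LA centres fall inside the tumor bed, extra-tumoral ones
    outside; each planted LA gets its configured CD20/CD3/CD23/MUM1 counts
    (CD20/CD23/MUM1 inside the LA disc, CD3 in a surrounding ring within
    1.5 radii); scattered MUM1+ cells cover the tumor bed at
    ``mum1_density`` per mm².
    """
    rng = np.random.default_rng(params.seed)
    bed = params.bed()
    n_las = params.n_las_intra + params.n_las_extra
    cd20s = params.per_la("cd20_per_la")
    cd3s = params.per_la("cd3_per_la")
    cd23s = params.per_la("cd23_per_la")
    mum1s = params.per_la("mum1_per_la")

    margin = 2.0 * params.la_radius
    centers: list[np.ndarray] = []
    for k in range(n_las):
        want_intra = k < params.n_las_intra
        for attempt in range(5000):
            c = rng.uniform([margin, margin],
                            [params.width - margin, params.height - margin])
            inside = bool(shapely.intersects_xy(bed.polygon, c[0], c[1]))
            if inside != want_intra:
                continue
            if all(np.hypot(*(c - o)) >= params.min_la_separation
                   for o in centers):
                centers.append(c)
                break
        else:
            raise GenerationError(
                f"could not place IHC LA {k} ({'intra' if want_intra else 'extra'})")

    frames = []
    counter = 0

    def emit(xy: np.ndarray, **markers) -> list[str]:
        nonlocal counter
        n = len(xy)
        ids = [f"ihc{counter + i:06d}" for i in range(n)]
        counter += n
        row = {"cell_id": ids, "x": xy[:, 0], "y": xy[:, 1]}
        for m in ("cd20", "cd3", "cd4", "cd8", "cd23", "mum1"):
            row[m] = np.full(n, bool(markers.get(m, False)))
        frames.append(pd.DataFrame(row))
        return ids

    truth_las = []
    for k, c in enumerate(centers):
        r = params.la_radius
        ids_cd20 = emit(_uniform_disc(rng, cd20s[k], c, r), cd20=True)
        ring = _uniform_disc(rng, cd3s[k], c, 1.5 * r)
        ids_cd3 = emit(ring, cd3=True)
        ids_cd23 = emit(_uniform_disc(rng, cd23s[k], c, r), cd23=True)
        ids_mum1 = emit(_uniform_disc(rng, mum1s[k], c, r), mum1=True)
        truth_las.append({
            "center": tuple(c), "radius": r,
            "intra": k < params.n_las_intra,
            "n_cd20": cd20s[k], "n_cd3": cd3s[k],
            "n_cd23": cd23s[k], "n_mum1": mum1s[k],
            "cd20_ids": ids_cd20,
        })

    # scattered MUM1+ plasma cells inside the tumor bed (Poisson)
    bed_area_mm2 = bed.polygon.area / 1e6
    n_scatter = int(rng.poisson(params.mum1_density * bed_area_mm2))
    pts = []
    minx, miny, maxx, maxy = bed.polygon.bounds
    while len(pts) < n_scatter:
        cand = rng.uniform([minx, miny], [maxx, maxy],
                           size=(max(2 * n_scatter, 16), 2))
        ok = shapely.intersects_xy(bed.polygon, cand[:, 0], cand[:, 1])
        pts.extend(cand[ok][: n_scatter - len(pts)])
    if n_scatter:
        emit(np.array(pts), mum1=True)

    if params.n_background:
        bg = rng.uniform([0, 0], [params.width, params.height],
                         size=(params.n_background, 2))
        emit(bg)

    table = pd.concat(frames, ignore_index=True)
    truth = {"las": truth_las, "mum1_scatter_n": n_scatter,
             "mum1_density": params.mum1_density, "params": params}
    return table, bed, truth


# ---------------------------------------------------------------------------
# expression matrices

def generate_expression_matrix(n_genes: int, n_cells: int,
                               cluster_spec: list[dict],
                               seed: int = 0,
                               ) -> tuple[sp.csr_matrix, list[str], list[str],
                                          np.ndarray]:
    """Poisson count matrix with planted clusters.

    ``cluster_spec`` lists clusters as ``{"size": int, "means": array of
    per-gene Poisson means (length n_genes)}``; sizes must sum to
    ``n_cells``.  Returns (genes x cells CSR counts, gene ids, cell ids,
    true cluster labels).
    """
    sizes = [int(c["size"]) for c in cluster_spec]
    if sum(sizes) != n_cells:
        raise ValidationError("cluster sizes must sum to n_cells")
    rng = np.random.default_rng(seed)
    blocks = []
    labels = []
    for ci, spec in enumerate(cluster_spec):
        means = np.asarray(spec["means"], dtype=float)
        if means.shape != (n_genes,):
            raise ValidationError("means must have length n_genes")
        blocks.append(rng.poisson(means[:, np.newaxis],
                                  size=(n_genes, sizes[ci])))
        labels.extend([ci] * sizes[ci])
    if blocks:
        dense = np.hstack(blocks)
    else:
        dense = np.zeros((n_genes, 0), dtype=int)
    mat = sp.csr_matrix(dense)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    cells = [f"c{i:05d}" for i in range(n_cells)]
    return mat, genes, cells, np.array(labels, dtype=int)


# ---------------------------------------------------------------------------
# clinical cohorts

def _series(days, values, bilirubin=1.0):
    return [{"day": int(d), "value": float(v), "bilirubin": float(bilirubin)}
            for d, v in zip(days, values)]


def generate_clinical_cohort(preset_or_params: str | dict = "trial_2026",
                             seed: int = 0) -> list[ClinicalRecord]:
    """Generate a per-patient cohort table.

    The ``"trial_2026"`` preset emits exactly 28 patients reproducing the
    trial's printed marginal counts: 22 resected / 6 not; CAP scores
    {0: 2, 1: 2, 2: 16, 3: 2}; margins {R0: 19, R1: 3}; pN {0: 11, 1: 7,
    2: 4}; among the 26 patients completing treatment, CA19-9 decreased for
    19 and converted from abnormal (>37 U/mL) to normal for 8; single-lesion
    best change was at or below -30% for 7 and negative for 21; the four
    grade-4 adverse events are 3 decreased neutrophil counts and 1
    hypokalemia.  Continuous values (baselines, magnitudes, survival times)
    are randomised within these strata under the seed.

    Alternatively pass an explicit dict ``{"n": int, ...}`` of count
    parameters (all response flags false by default).
    """
    rng = np.random.default_rng(seed)
    if isinstance(preset_or_params, dict):
        return _cohort_from_params(preset_or_params, rng)
    if preset_or_params != "trial_2026":
        raise ValidationError(f"unknown preset {preset_or_params!r}")

    n = 28
    records: list[ClinicalRecord] = []
    cap_assign = {1: 0, 2: 0, 3: 1, 4: 1}  # patients 5..20 -> CAP 2, 21..22 -> 3
    for i in range(1, n + 1):
        pid = f"p{i:02d}"
        resected = i <= 22
        completed = i <= 26
        cap = margins = pn = None
        if resected:
            cap = cap_assign.get(i, 2 if i <= 20 else 3)
            margins = "R1" if i >= 20 else "R0"         # 3 R1, 19 R0
            pn = 0 if i <= 11 else (1 if i <= 18 else 2)  # 11 / 7 / 4

        # lesion series: 7 PR (<= -30%), 14 shrinking SD, 5 non-shrinking SD,
        # 2 with a single timepoint (no follow-up imaging)
        base = float(rng.uniform(25.0, 45.0))
        if not completed:
            lesions = [{"day": 0, "longest_diameter": base}]
        elif i <= 7:
            change = rng.uniform(-0.60, -0.30)
            lesions = [{"day": 0, "longest_diameter": base},
                       {"day": 84, "longest_diameter": base * (1 + change)}]
        elif i <= 21:
            change = rng.uniform(-0.28, -0.05)
            lesions = [{"day": 0, "longest_diameter": base},
                       {"day": 84, "longest_diameter": base * (1 + change)}]
        else:
            change = rng.uniform(0.01, 0.10)
            lesions = [{"day": 0, "longest_diameter": base},
                       {"day": 84, "longest_diameter": base * (1 + change)}]

        # CA19-9: 8 converters, 11 other decreasers, 7 non-decreasers
        if not completed:
            ca = _series([0], [rng.uniform(50, 300)], bilirubin=3.5)
        elif i <= 8:
            ca = _series([0, 28, 84],
                         [rng.uniform(100, 400), rng.uniform(40, 90),
                          rng.uniform(5, 36)])
        elif i <= 14:
            first = rng.uniform(100, 500)
            ca = _series([0, 84], [first, rng.uniform(40, min(90, first - 1))])
        elif i <= 19:
            first = rng.uniform(15, 35)
            ca = _series([0, 84], [first, rng.uniform(3, first - 1)])
        else:
            first = rng.uniform(30, 200)
            ca = _series([0, 84], [first, first * rng.uniform(1.05, 1.5)])

        aes = []
        if i <= 3:
            aes.append({"term": "neutrophil count decreased", "grade": 4})
        if i == 4:
            aes.append({"term": "hypokalemia", "grade": 4})
        if rng.uniform() < 0.8:
            aes.append({"term": "nausea", "grade": int(rng.integers(1, 3))})
        if rng.uniform() < 0.6:
            aes.append({"term": "diarrhea", "grade": int(rng.integers(1, 3))})

        def surv(median_m: float) -> tuple[float, bool]:
            t = float(rng.exponential(median_m / math.log(2)))
            if t > 48.0:
                return 48.0, False
            return t, True

        dfs = surv(19.7) if resected else (math.nan, False)
        pfs = surv(26.0) if completed else (math.nan, False)
        os_ = surv(38.0) if completed else (math.nan, False)

        records.append(ClinicalRecord(
            patient_id=pid, enrolled=True, completed_treatment=completed,
            resected=resected, cap_score=cap, margins=margins, pn_stage=pn,
            ca199_series=ca, lesion_series=lesions, aes=aes,
            dfs_time=dfs[0], dfs_event=dfs[1],
            pfs_time=pfs[0], pfs_event=pfs[1],
            os_time=os_[0], os_event=os_[1]))
    return records


def _cohort_from_params(params: dict, rng: np.random.Generator,
                        ) -> list[ClinicalRecord]:
    n = int(params.get("n", 0))
    if n <= 0:
        raise ValidationError("cohort size n must be positive")
    for key in ("n_resected",):
        if params.get(key, 0) > n:
            raise ValidationError(f"{key} exceeds cohort size")
    n_resected = int(params.get("n_resected", 0))
    records = []
    for i in range(1, n + 1):
        base = float(rng.uniform(25.0, 45.0))
        records.append(ClinicalRecord(
            patient_id=f"p{i:02d}", enrolled=True,
            completed_treatment=bool(params.get("completed", False)),
            resected=i <= n_resected,
            cap_score=2 if i <= n_resected else None,
            margins="R0" if i <= n_resected else None,
            pn_stage=0 if i <= n_resected else None,
            ca199_series=_series([0, 84], [base, base]),
            lesion_series=[{"day": 0, "longest_diameter": base},
                           {"day": 84, "longest_diameter": base}],
            aes=[], dfs_time=math.nan, dfs_event=False,
            pfs_time=math.nan, pfs_event=False,
            os_time=math.nan, os_event=False))
    return records
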