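"""Pipeline configuration.

All tunable thresholds used anywhere in the pipeline live here with their
defaults, so a single :class:`Config` instance fully determines the behaviour
of every stage.  Distances are micrometres, areas µm², marker thresholds are
transcript counts, clinical thresholds are in the units printed on lab
reports (U/mL, mg/dL, percent).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

from .errors import ValidationError


@dataclass
class Config:
    """Tunables for every pipeline stage.

    Spatial LA demarcation
    ----------------------
    pair_radius
        Maximum distance (µm) from a CCL19-positive cell to the nearest
        CXCL13-positive cell for the former to count as an LA seed.
    dbscan_radius
        DBSCAN eps (µm) for clustering seed cells.
    min_cluster_cells
        DBSCAN core threshold: a seed is a core point when at least this many
        seeds (counting itself) lie within ``dbscan_radius``.
    merge_distance
        Clusters whose centroids lie within this distance (µm) are merged
        (single-linkage, transitive).
    hull_buffer
        Outward buffer (µm) applied to the concave hull of each cluster.
    hull_alpha
        Alpha-shape radius (µm) used to build the concave hull.
    marker_positivity_min
        Transcript count at or above which a cell is "positive" for a gene.
    self_pairing
        Whether a CCL19+CXCL13 double-positive cell may pair with itself.

    Cell-level processing
    ---------------------
    qc_min_genes / qc_min_transcripts
        A cell passes QC when it has at least this many detected genes AND
        at least this many total transcripts.
    rep_cells_max
        Maximum representative cells retained per cluster.
    score_threshold
        Label-transfer prediction scores strictly below this become
        "unassigned".

    IHC analysis
    ------------
    ihc_eps / ihc_min_samples
        DBSCAN parameters for clustering CD20+ centroids.
    ihc_min_cd20
        Clusters must contain strictly more than this many CD20+ cells.
    cd3_min / cd3_radius
        Required number of CD3+ cells within ``cd3_radius`` µm of the CD20
        cluster hull.
    ihc_hull_buffer
        Buffer (µm) for the IHC LA polygon.
    cd23_min_cells
        An LA is CD23-positive when it contains at least this many CD23+ cells.

    Clinical endpoints
    ------------------
    ca199_upper_normal
        CA19-9 values strictly above this (U/mL) are abnormal.
    bilirubin_max
        CA19-9 draws with total bilirubin at or above this (mg/dL) are
        excluded as unevaluable.
    recist_pr / recist_pd
        Percent-change thresholds for partial response (best change at or
        below ``recist_pr``) and progression (any change from nadir at or
        above ``recist_pd`` plus 5 mm absolute).
    """

    pair_radius: float = 50.0
    dbscan_radius: float = 75.0
    min_cluster_cells: int = 15
    merge_distance: float = 400.0
    hull_buffer: float = 100.0
    hull_alpha: float = 150.0
    marker_positivity_min: int = 1
    self_pairing: bool = True

    qc_min_genes: int = 10
    qc_min_transcripts: int = 20
    rep_cells_max: int = 500
    score_threshold: float = 0.6

    ihc_eps: float = 40.0
    ihc_min_samples: int = 5
    ihc_min_cd20: int = 50
    cd3_min: int = 20
    cd3_radius: float = 50.0
    ihc_hull_buffer: float = 50.0
    cd23_min_cells: int = 3

    ca199_upper_normal: float = 37.0
    bilirubin_max: float = 3.0
    recist_pr: float = -30.0
    recist_pd: float = 20.0

    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pair_radius", "dbscan_radius", "merge_distance", "hull_buffer",
            "hull_alpha", "ihc_eps", "cd3_radius", "ihc_hull_buffer",
            "ca199_upper_normal", "bilirubin_max",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"Config.{name} must be strictly positive")
        for name in ("min_cluster_cells", "marker_positivity_min",
                     "ihc_min_samples", "rep_cells_max"):
            if getattr(self, name) < 1:
                raise ValidationError(f"Config.{name} must be >= 1")
        for name in ("qc_min_genes", "qc_min_transcripts", "ihc_min_cd20",
                     "cd3_min", "cd23_min_cells"):
            if getattr(self, name) < 0:
                raise ValidationError(f"Config.{name} must be >= 0")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValidationError("Config.score_threshold must be in [0, 1]")
        if self.recist_pr >= 0 or self.recist_pd <= 0:
            raise ValidationError(
                "recist_pr must be negative and recist_pd positive (percent scale)")

    def to_file(self, path: str | Path) -> None:
        """Write the configuration as ``key=value`` lines."""
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Read a ``key=value`` configuration file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        converters = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"line {lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValidationError(f"line {lineno}: unknown config key {key!r}")
            conv = converters[key]
            if conv is bool:
                kwargs[key] = value.strip().lower() in ("1", "true", "yes")
            else:
                kwargs[key] = conv(value.strip())
        return cls(**kwargs)

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)
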