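# Methods

## LA demarcation

Lymphoid aggregates are demarcated from chemokine co-expression rather than
cellular composition. The procedure assumes planar cell centroids in µm
(y up, arbitrary origin; no implicit axis flipping — image-convention inputs
must be pre-flipped) and integer transcript counts for at least CCL19 and
CXCL13.

**Positivity.** A cell is positive for a gene when its count is at least
`marker_positivity_min` (default 1 transcript). "Positive" otherwise has no
canonical threshold for imaging-based assays; one transcript is the natural
floor and the value is configurable.

**Seeds.** A seed is a CCL19-positive cell whose distance to the nearest
CXCL13-positive cell is at most `pair_radius` = 50 µm. Distances are
center-to-center and all comparisons throughout the pipeline are
boundary-inclusive (`<=`), matching the plain reading of "within". A
CCL19/CXCL13 double-positive cell pairs with itself by default
(`self_pairing`); disabling it requires a distinct partner.

**Clustering.** DBSCAN over seed cells with eps = `dbscan_radius` (75 µm).
A seed is a core point when at least `min_cluster_cells` (15) seeds lie in
its eps-ball *counting itself*; neighbor-count conventions differ between
DBSCAN implementations, so this one is declared and configurable. Cluster
expansion iterates in ascending cell-id order, so a border (non-core) seed
reachable from two clusters deterministically joins the first-discovered
one. Noise seeds are dropped. The expansion is written in-package on top of
a k-d tree neighbor query because the id-ordered border rule is part of the
declared semantics; the test suite checks the stage against an independent
dense-distance-matrix reference on random instances.

**Merging.** Clusters whose centroids lie within `merge_distance` (400 µm)
are merged by single-linkage connected components computed once on the
original centroids. Transitive chains merge (A–B and B–C within range joins
A–C); iterative recomputation of centroids during merging is deliberately
not done — it is order-dependent and could chain indefinitely. The merged
centroid is recomputed once afterwards from the union of members.

**Polygons.** The concave hull of a cluster's seed cells is an alpha shape:
the union of Delaunay triangles with circumradius ≤ `hull_alpha` (default
150 µm, i.e. 2× eps — small enough to follow concavities at the scale of
the clustering neighborhood, large enough not to fragment). The hull is
dilated by `hull_buffer` (100 µm) with round joins at 32 segments per
quarter turn, so closed-form areas (disc, Minkowski sum of a square) are
reproduced well within 1%. Degenerate inputs take closed forms: one point →
disc; two points or collinear sets → capsule. If the alpha shape is empty,
disconnected, invalid, or its buffer fails to cover every input point, the
convex hull is used instead and the fallback is logged.

**Assignment.** Every cell whose point lies inside or on an LA polygon is
assigned to that LA, whatever its type. Buffered polygons of distinct merged
clusters are kept separate even if they overlap (only the 400 µm centroid
rule merges); a cell covered by several polygons goes to the LA with the
nearest source-cluster centroid, ties to the lower LA id. Remaining cells
form the "outside" compartment, so LA memberships plus outside partition the
cell table.

The pipeline is deterministic for fixed input and configuration, invariant
to cell-row order and translation, and rotation-invariant up to
polygonization tolerance.

## LA statistics

- **PBR** = log2(nPC + 1) − log2(nB + 1); antisymmetric; `high_pbr` ⇔
  nPC > nB ⇔ PBR > 0.
- **Compartment fractions**: pooled counts over all LA member cells vs all
  outside cells, cells labelled "unassigned" excluded from denominators.
  "Mean relative fraction" is ambiguous between pooling and per-LA
  averaging; both modes are provided (`mode="pooled"` default,
  `"per_la_mean"` alternative). Fine types can be pooled into supergroups
  (e.g. one combined T-cell group) before fractions are taken.
- **Enrichment** = log2 of the fraction ratio. With both fractions positive
  no pseudocount is used (scores are then antisymmetric); a type absent from
  one compartment gets half of one cell over the smaller compartment total,
  and the pseudocount used is declared in the output table.
- **Densities** are raw count / polygon area × 10⁶ (cells/mm²); the +1
  pseudocount appears only inside log-ratios (mirroring the PBR), never in
  densities.
- **Associations**: Spearman rho with average ranks for ties; two-sided p
  from the t-approximation, replaced by an exact full-permutation p for
  n ≤ 9 (n! ≤ 362,880 orderings); least-squares slope/intercept for trend
  lines. Zero variance in either variable leaves rho undefined (NaN, logged)
  rather than raising.
- **Inside vs outside per patient**: T_TEX and T_PEX counts pooled over all
  of a patient's LA members and over all non-LA cells; the +1-pseudocount
  log2 count ratio equals the density log-ratio because both counts in one
  compartment share the same area. Patients with no LA cells are excluded
  with a log entry; the cross-patient association requires n ≥ 3.

## Cell-level processing

QC keeps cells with ≥ `qc_min_genes` (10) detected genes **and**
≥ `qc_min_transcripts` (20) total transcripts, both inclusive; the filter is
monotone in both thresholds. Representative-cell selection retains up to
`rep_cells_max` (500) cells per cluster nearest the cluster's mean profile.
The notion of "most similar" admits several metrics; the default is
Euclidean distance on depth-normalized (to 10⁴ per cell), log1p-transformed
counts — the common convention — with Pearson correlation distance as a
configurable alternative; the mean is computed in the same transformed
space and ties break by ascending cell id, so selection is reproducible
without a seed and idempotent. Label-transfer prediction scores strictly
below `score_threshold` (0.6) become "unassigned" (a score of exactly 0.6
keeps its label) and unassigned cells drop out of every downstream
denominator.

## IHC analysis

The original identification of LAs on stained serial sections is
operator-driven; this module substitutes an explicit, fully parameterised
surrogate so the analysis is reproducible, not a claim about the manual
process. DBSCAN over CD20⁺ centroids (eps 40 µm, min 5 neighbors) proposes
clusters; a cluster is an LA when it contains strictly more than 50 CD20⁺
cells ("more than 50" is a hard boundary: exactly 50 is rejected) and at
least `cd3_min` (20) CD3⁺ cells lie within `cd3_radius` (50 µm) of its
convex hull — "proximal" and "compact" have no standard quantitative
definition, so these defaults are declared placeholders. The LA polygon is the buffered
concave hull of the CD20⁺ members (buffer 50 µm, reusing the spatial hull
builder); marker counts are tallied inside it. Location is intra-tumoral
iff the polygon centroid lies inside or on the pathologist's tumor-bed
polygon (centroid, not majority-area, for determinism). CD23 positivity
(follicular-dendritic-cell content, a germinal-center marker) defaults to
≥ 3 CD23⁺ cells — a configurable package default.
Intra-tumoral plasma-cell density is MUM1⁺ cells inside the tumor bed per
mm² of bed area. Group density comparisons use the two-sided Mann–Whitney
rank-sum test; burden correlations use simple linear regression with the
two-sided slope p.

## Clinical endpoints

Single-lesion best response: baseline is the first measurement; partial
response when the best change from baseline is ≤ −30% (inclusive, and
checked before progression, so an early PR is not overwritten);
progression requires both ≥ +20% from the running nadir and ≥ 5 mm
absolute; fewer than two measurements → not evaluable. CA19-9: draws with
bilirubin ≥ 3 mg/dL are excluded (strictly-below rule); evaluable with ≥ 2
remaining draws; "decreased" = last < first; "converted" = first strictly
above 37 U/mL and last at or below it (37 itself is normal). Percentages
round to the nearest integer, half away from zero. Denominators: enrolled
patients for the resection rate; resected patients for CAP/margins/pN;
treatment-completers for response and CA19-9 rates (best response is also
tabulated over all enrolled with an NE category, since both views are in
circulation). Grade-4 adverse events are counted as instances summed over
patients. Kaplan–Meier medians use the product-limit estimator
(via lifelines) with log-log 95% CIs; a curve that never reaches 0.5
yields "not reached" (infinity in JSON output, serialized as the string
"not reached" by the CLI).

## Synthetic data

The tissue generator plants `n_las` LAs in a width × height rectangle of
background cells and returns full ground truth (centers, radii, member ids,
per-type counts, coupling parameters). Defaults and what they emulate:

- Background: `n_background` = 5000 cells uniform on a 5 × 5 mm field,
  tumor-dominant composition (55% tumor, 20% fibroblast, 10% myeloid,
  sparse lymphocytes). Every cell type occurs outside LAs so enrichment
  scores are finite and nontrivial.
- LA discs: radius Normal(110, 8) µm clipped at ±2 sd (area ≈ 0.04 mm²,
  the same order as reported mean LA areas), ~Poisson(300) member cells
  uniform in the disc with a Dirichlet-multinomial type composition whose
  symmetric B/PC weights put roughly half the LAs in the high-PBR class.
  Member counts are scaled down from the real median (~700 cells) to keep
  desk-scale simulation cheap; nothing downstream depends on the absolute
  count.
- Chemokine organisers: exactly `n_ccl19_per_la` and `n_cxcl13_per_la`
  (20 + 20) member cells with CCL19/CXCL13 count 1, placed uniformly in a
  35 µm core at the LA center. The focal core mirrors chemokine-expressing
  reticular niches at real LA centers, and it is what makes the published
  demarcation parameters coherent: organisers spread uniformly over a
  ~110 µm disc can never satisfy "15 seeds within 75 µm" with tens of
  organisers, whereas a ≤ 37.5 µm core keeps all organisers mutually within
  eps. With the ±2 sd radius clip the member disc stays within the
  organiser hull's reach plus the 100 µm buffer, so planted members are
  captured by the detected polygon.
- Stray chemokine noise: a stationary Poisson process
  (`chemokine_noise_rate` = 2 false positives/mm², each a single CCL19⁺ or
  CXCL13⁺ cell) — the simplest false-positive model for the seed-pairing
  stage.
- Exhaustion coupling: per LA, the targeted log2 T_TEX:T_PEX ratio is
  β0 + β1·PBR + Normal(0, σ) with defaults β0 = 0, β1 = 1, σ = 0.25,
  implemented on counts: T_PEX ~ Poisson(`t_pex_mean` = 60), then T_TEX is
  rounded to match the targeted +1-pseudocount ratio. The pool size of 60
  keeps the count discretisation (≲ 0.02 in log2 units) negligible against
  σ, so the planted coupling really is log-linear with Gaussian noise and
  the analysis module's own least-squares estimator recovers β1 with
  nominal CI coverage. Optionally (`couple_background_exhaustion`, on by
  default) the background T_TEX:T_PEX balance tracks the tissue's mean
  targeted LA ratio, emulating LA-derived exhausted T cells permeating the
  tumor so that inside/outside ratios correlate across patients.
- `strict_recovery_preset`: 20 LAs on an 8 × 8 mm field with ≥ 1200 µm
  hard-core separation (validated to exceed twice radius-plus-buffer),
  sparse background (1000 cells) and zero chemokine noise — the regime in
  which every planted LA should be recovered with near-perfect membership.
  The 8 mm field matters: 20 centers at 1200 µm separation approach
  random-sequential-adsorption jamming on a 7 mm field, making rejection
  sampling unreliable.

What the generator does **not** emulate: full gene panels, segmentation
errors, transcript bleed-over between adjacent cells, irregular
(non-disc) LA shapes, spatial gradients in background composition, and
cell-density differences between LA core and rim. Passing recovery tests
therefore demonstrates the correctness and calibration of the algorithms
under the stated model, not performance on real tissue, where boundary
effects and segmentation noise will dominate.

The IHC generator plants CD20/CD3/CD23/MUM1 clusters with configured counts
(CD3 in a ring of 1.5 radii around the center, emulating the T-cell mantle),
scatters MUM1⁺ plasma cells over the tumor bed as a Poisson process, and
places intra-/extra-tumoral LA centers inside/outside the bed polygon.

The clinical preset emits exactly 28 patients whose marginal counts equal
the trial's printed figures (22 resected; CAP 2/2/16/2; margins 19/3/0;
pN 11/7/4; of 26 treatment-completers: CA19-9 decreased 19 and converted 8,
lesions shrank 21 with 7 at or beyond −30%; grade-4 events: 3 neutrophil
count decreased, 1 hypokalemia), with continuous values randomised within
strata under the seed. Survival times are exponential draws around the
reported medians with administrative censoring at 48 months — plumbing for
the Kaplan–Meier code, not a calibrated survival model.

## Numerical choices and edge cases

- All random generation uses `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical outputs.
- Sparse matrices are MatrixMarket triplets; cell tables CSV/TSV; polygons
  GeoJSON (µm coordinates; ubiquitous tooling and explicit ring-closure
  rules outweigh the unit mismatch with geographic conventions). Readers
  never silently drop rows: unknown cell-type labels are rejected with a
  logged count; structural violations raise.
- Zero-area polygons, empty compartments, missing prediction scores,
  negative counts and non-increasing series days raise validation errors;
  undefined statistics (rho under zero variance, enrichment of a type
  absent from both compartments) are reported as NaN rather than raised.
- The configuration object is a flat key=value text file echoed next to
  CLI outputs for provenance.

## Known limitations

- The alpha-shape parameter (150 µm) and the IHC surrogate's DBSCAN/CD3
  parameters are package defaults chosen for plausibility; sensitivity to
  them is not explored automatically.
- The exact-permutation Spearman p is O(n!) and capped at n ≤ 9.
- Intra/extra-tumoral classification by polygon centroid misclassifies LAs
  straddling the bed boundary with most of their area on the far side.
- The generator's LAs are discs with independent compositions; spatially
  correlated or nested aggregates are out of scope.
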