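# lymphagg

Spatial demarcation of **lymphoid aggregates (LAs)** in tumor tissue and the
immune statistics built on top of them, together with an IHC-side density
analysis and clinical trial endpoint summaries. Everything is exercisable on
synthetic data generated in-package, with full ground truth.

## The problem

Lymphoid aggregates — up to and including mature tertiary lymphoid
structures — organize anti-tumor immunity, but defining them from their
*expected* cellular content (dense B cells) begs the question when the
phenomenon of interest is LAs that have *lost* their B cells to premature
plasma-cell differentiation. `lymphagg` implements a B-cell-independent
demarcation from image-based single-cell spatial transcriptomics: LAs are
found where the lymphocyte-attracting chemokines **CCL19** and **CXCL13**
are focally co-expressed, regardless of what cells end up inside.

The pipeline, on a table of cells with planar coordinates (µm), a cell-type
label and per-gene transcript counts:

1. **Seeds** — every CCL19⁺ cell with a CXCL13⁺ cell within 50 µm
   (boundary-inclusive, center-to-center).
2. **Clustering** — DBSCAN over seeds, eps = 75 µm, core condition ≥ 15
   seeds in the neighborhood (counting the cell itself).
3. **Merging** — clusters whose centroids lie within 400 µm are merged
   (single-linkage, transitive, computed once).
4. **Geometry** — an alpha-shape concave hull (α = 150 µm) of each merged
   cluster, dilated by a 100 µm buffer; every cell of any type inside or on
   the polygon belongs to the LA.

On the demarcated LAs it computes the statistics of interest:

- **PBR**, the plasma-cell-to-B-cell ratio,
  `PBR = log2(n_PC + 1) − log2(n_B + 1)`; an LA with more plasma cells than
  B cells ("high PBR") is the disordered phenotype.
- Pooled **compartment fractions** of each cell type inside vs outside LAs,
  and **enrichment scores** `log2(frac_inside / frac_outside)`.
- Per-LA **subset densities** (cells/mm²) and the exhausted-T-cell balance
  `log2((n_TEX + 1)/(n_PEX + 1))` (T_TEX = terminally exhausted,
  T_PEX = progenitor exhausted CD8 T cells).
- **Associations** of any per-LA response with the PBR: Spearman rank
  correlation (exact permutation p for n ≤ 9) plus a least-squares trend
  line; and the per-patient inside-vs-outside exhaustion comparison.

Companion modules cover cell-level QC (≥ 10 detected genes and ≥ 20
transcripts), representative-cell subsampling (up to 500 per cluster,
nearest the cluster mean), low-confidence label filtering (< 0.6 prediction
score → "unassigned"), IHC LA identification (> 50 CD20⁺ cells in a compact
cluster with proximal CD3⁺ cells) with intra/extra-tumoral classification
and MUM1⁺ plasma-cell densities, and trial endpoint arithmetic (RECIST 1.1
single-lesion best response, CA19-9 response with the > 37 U/mL cutoff and
bilirubin < 3 mg/dL evaluability, CAP/margin/nodal proportions, grade-4
adverse-event counts, Kaplan–Meier medians).

## Worked example

```python
from lymphagg import TissueSimParams, generate_tissue, detect_lymphoid_aggregates
from lymphagg.la_statistics import la_profiles, associate_pbr

params = TissueSimParams(seed=42, n_las=8)   # synthetic tissue, 8 planted LAs
cellmap, truth = generate_tissue(params)
aggregates, membership = detect_lymphoid_aggregates(cellmap)
profiles = la_profiles(aggregates)
print(profiles[["la_id", "area_um2", "n_cells", "pbr", "log2_tex_pex"]])
res = associate_pbr(profiles, "log2_tex_pex")
print(f"rho={res.spearman_rho:.2f} p={res.spearman_p:.4f} slope={res.ls_slope:.2f}")
```

prints

```
 la_id  area_um2  n_cells   pbr  log2_tex_pex  high_pbr
     0  52626.93      400 -1.23         -1.09     False
     1  52226.30      467  0.47          0.52      True
     2  50909.06      457 -0.25         -0.51     False
     ...
PBR vs log2(TEX:PEX): rho=0.93 p=0.0022 slope=0.87
```

All 8 planted LAs are recovered; each profile row is one LA with its polygon
area, member count, PBR and exhaustion log-ratio. The positive Spearman rho
and near-unit slope recover the coupling the generator planted
(`pbr_effect_beta1 = 1`): high-PBR LAs are enriched for terminally exhausted
T cells at the expense of progenitor-exhausted ones.

The same pipeline is available from a shell:

```bash
lymphagg simulate --seed 42 --n-las 8 --out-dir out/
lymphagg detect-la --cells out/cells.csv --out out/las.geojson \
                   --membership out/membership.csv
lymphagg la-stats  --cells out/cells.csv --las out/las.geojson \
                   --membership out/membership.csv \
                   --out-profiles out/profiles.csv \
                   --out-associations out/assoc.json
lymphagg ihc       --cells out/ihc.csv --tumor-bed out/tumor_bed.geojson \
                   --out out/ihc_las.geojson --summary out/ihc_summary.csv
lymphagg clinical  --cohort out/cohort --out out/clinical.json
```

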