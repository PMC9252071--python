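# Methods

This document states every convention the package commits to, the default
parameters and their rationale, what the synthetic generators do and do not
emulate, and the known limitations. All symbols refer to public names in
`gliaquant`.

## 1. Image model

A `CalibratedStack` is a `(nz, ny, nx)` float64 array with an isotropic
in-plane pixel size in micrometres and a `ChannelRole` naming the stain
(`plaque_6e10`, `plaque_mex04`, `microglia`, `lamp1`, `cd68`, `tau_total`,
`tau_phospho`). 2-D images are one-plane stacks. All areas are reported in
µm²; all fractions are dimensionless pixel-count ratios.

Regions of interest are simple polygons in `(y, x)` pixel coordinates. A
pixel belongs to an ROI when its centre is inside or on the polygon boundary
(shapely `covers`, boundary-inclusive). Every statistic — histograms,
thresholds, areas, fractions — is computed from ROI pixels only.

## 2. Thresholding conventions

Two histogram thresholds are implemented, both on the same carrier:

- the histogram has **256 equal-width bins spanning the observed range** of
  the pixels being thresholded (not a fixed 0–255 grid);
- candidate thresholds are the **interior bin edges** `t = bin_edges[k+1]`;
- foreground is **strictly `> t`**;
- when several splits attain the optimum, the **smallest `t`** is returned;
- a degenerate histogram (fewer than two populated bins) raises
  `DegenerateThresholdWarning` and returns the populated bin's upper edge,
  giving an empty foreground.

`otsu_threshold` maximizes the between-class variance
w₀w₁(µ₀ − µ₁)²; `maxentropy_threshold` (Kapur) maximizes the sum of Shannon
entropies of the renormalized background and foreground distributions. Both
are exhaustive over all 255 splits (vectorized cumulative sums; `argmax`
takes the first maximum, which is the smallest-t tie-break).

**Per-stack thresholds.** For a z-stack metric, one threshold is computed
from the pooled ROI pixels of all planes and applied plane-wise. Rationale:
plane-wise thresholds make plane-to-plane comparisons incoherent when a plane
contains little signal, while a pooled threshold is the 3-D analogue of
thresholding the whole 2-D field of view.

## 3. Morphology and particle analysis

- **Dilation** (`dilate_physical`) is defined in physical units: a pixel is
  foreground when its in-plane Euclidean distance to the original foreground
  is ≤ the radius in µm (exact Euclidean distance transform with the pixel
  size as sampling). It is applied **per z-plane**; no out-of-plane growth.
  With a 1 µm pixel, a single pixel dilated by 3 µm becomes exactly 29
  pixels.
- **Particle analysis** (`label_particles`) uses 8-connected components.
  Components below the minimum area (default **50 µm²**, the conventional
  cut-off separating plaques from puncta and noise specks) are removed but
  preserved in a `removed_mask`, so foreground pixels are conserved.
- Mask algebra (`mask_and`, `mask_subtract`) requires matching shapes and
  calibrations.

## 4. Pathology metrics

Defaults live in `PlaqueParams`: `min_plaque_area_um2 = 50`,
`neurite_halo_um = 25`, `microglia_halo_um = 5`. All metrics return
`MetricValue(name, value, flag)`; an undefined ratio (empty denominator) is
**NaN with an explanatory flag string, never 0**, so downstream averaging
cannot silently absorb missing data.

- **`plaque_burden`** — max-project the 6E10 stack, Otsu-threshold inside the
  ROI. `plaque_area_fraction` is the fraction of ROI pixels above threshold
  (**all** suprathreshold pixels, including sub-cut-off specks, matching the
  area-fraction readout of a thresholded field); `plaque_count` and
  `plaque_mean_size_um2` come from the size-filtered particles only.
- **`mex04_ratio`** — maximum-entropy threshold on the MeX04 channel over
  Otsu on 6E10 (fibrillar fraction). The two conventions reflect the sparse,
  bright MeX04 stain versus the broader antibody signal.
- **`neuritic_damage_ratio`** — per plane: size-filtered plaques are dilated
  by 25 µm; non-microglial LAMP1 (LAMP1 minus the microglia mask) inside that
  halo region is the numerator; the denominator is the non-dilated filtered
  plaque area (`denominator="filtered"`, default) or all suprathreshold
  plaque pixels (`"all"`).
- **`plaque_associated_microglia`** — fraction of size-filtered plaques with
  at least one microglial pixel within a 5 µm halo of the **raw** thresholded
  plaque mask.
- **`cd68_in_microglia`** — CD68⁺ area inside the microglia mask over
  microglial area.
- **`background_subtracted_intensity`** — sum-project, Otsu inside the ROI;
  the mean of sub-threshold pixels is the background estimate; the reported
  value is the background-subtracted mean over suprathreshold pixels (or over
  the whole ROI with `scope="roi"`). Intensity ratios such as
  `tau_epitope_ratio` (phospho/total) are quotients of these, and are
  invariant to affine intensity rescaling applied to both channels.

## 5. Single-cell RNA-seq

`CountMatrix` is genes × cells (dense or CSR), with gene symbols, cell ids,
and group labels.

**QC (`qc_filter`, `QCParams`)** runs in a fixed order:

1. **Gene stage** — drop ribosomal genes (symbol prefixes `Rps`/`Rpl`,
   case-insensitive) and genes detected (count > 0) in fewer than
   `min_cells_per_gene = 3` cells.
2. **Cell stage**, on the gene-filtered matrix — remove cells with fewer than
   `min_features_per_cell = 200` detected genes; cells with mitochondrial
   fraction (symbols prefixed `mt-`) above `max_mito_fraction = 0.05`; and
   cells whose total counts exceed mean + 3 SD, where the mean and SD are
   computed **per group** over the cells passing the other two criteria
   (`count_cap_scope="pooled"` computes one cap over all groups). When no
   mitochondrial genes exist the mito criterion is skipped with a warning and
   recorded in the report.

The per-criterion removal counts and the caps used are returned in
`QCReport`. Note the mean + 3 SD cap is **not idempotent in general**:
removing outliers shrinks the cap, so a second pass can remove more cells.
The filter is a single pass by design.

**Normalization (`log_normalize`)** — per cell, counts are scaled to a total
of 10⁴ and transformed with natural `log1p` (the Seurat convention).
Zero-total cells map to zero columns.

**Markers (`wilcoxon_markers`, `MarkerParams`)** — the log fold change is
`ln(mean(expm1(a)) + 1) − ln(mean(expm1(b)) + 1)` on the normalized matrix.
Genes with |logFC| ≤ 0.25 are **not tested** (NaN p and padj). Tested genes
get a two-sided Wilcoxon rank-sum test using the tie-corrected normal
approximation without continuity correction (`ranksum_test`; identical to
`scipy.stats.mannwhitneyu(method="asymptotic", use_continuity=False)`),
vectorized across genes. Benjamini–Hochberg adjustment runs over the tested
genes only; `significant` marks padj < 0.05. Groups smaller than 3 cells
trigger a reliability warning.

**Enrichment (`hypergeometric_enrichment`)** — one-sided upper-tail
hypergeometric p-value per gene set (`hypergeom.sf(k−1, M, K, N)`), BH across
sets; query genes outside the universe are an error listing the strays.

## 6. Behavior

`discrimination_index` computes DI = (Tn − Tf)/(Tn + Tf). Animals are
excluded (DI = NaN, `excluded=True`) when total exploration Tn + Tf is below
8 s (`rule="total"`, default) or when either object was explored less than
the minimum (`rule="each"`). Negative times are rejected.

## 7. Synthetic generators

**Scenes (`render_scene`, `random_scene_spec`).** A scene is a set of
circular plaque cores with LAMP1-like halos, stick-shaped microglia with CD68
puncta inside them, rendered into five channel stacks. Geometry is constant
across z; independent Gaussian noise (SD 8 on a background of 20) is added
per voxel and clipped at 0. Default random scenes are 3×256×256 at 1 µm/px
with five large plaques (radii 9–14 µm, cores ≈ 250–620 µm²) and three
bright 3 µm specks (≈ 28 µm², below the 50 µm² cut-off), placed without
overlap; core intensity is background + SNR × noise SD (SNR 5 → 60). The
MeX04 channel lights up the inner 70 % of each core radius, emulating a
fibrillar centre. `GroundTruth` carries the noiseless masks and per-plaque
core areas. The generator emulates contrast, noise, sub-resolution clutter,
and spatial association — not optical PSF blur, z-attenuation, uneven
illumination, or realistic cell morphology.

**Count matrices (`sample_matrix`, `MatrixSpec`).** Negative-binomial counts
(dispersion θ = 10, variance µ + µ²/θ) with gene means log-uniform on
[1, 10]; 10 `mt-` genes scaled to a 2 % expected mitochondrial share and 20
`Rps`/`Rpl` genes; two groups of 150 cells. Planted failures: low-feature
cells (~120 genes at one count), high-count cells (totals × 6), high-mito
cells (~10 % mitochondrial fraction); marker genes have their mean multiplied
by `marker_fold` (default 4) in group B. The generator emulates overdispersed
counts and QC failure modes — not zero-inflation/dropout structure, batch
effects, ambient RNA, or doublets.

Both generators are bit-reproducible from their integer seed
(`np.random.default_rng`).

## 8. Numerical and design choices

- Thresholds search bin edges, not pixel values; this makes the oracle (an
  exhaustive per-split loop) exactly reproducible and keeps results invariant
  to pixel ordering.
- `argmax` on the vectorized criterion takes the first optimum, which
  implements the smallest-threshold tie-break. Criteria that differ only at
  double-precision rounding (~1e-15) can legitimately resolve to either of
  two adjacent edges; agreement checks should compare criterion values, not
  only the returned edge.
- Rank-sum p-values use the normal approximation (with tie correction); this
  matches standard single-cell practice at typical group sizes but is not an
  exact test for very small groups (the package warns below 3 cells/group).
- BH adjustment over tested genes only: the logFC gate is part of the testing
  procedure, so untested genes carry NaN rather than an adjusted value.
- CLI configurations reject unknown keys, and every output directory includes
  a `manifest.json` (package version, seed, config SHA-256).

## 9. Limitations

- **Global Otsu needs enough foreground.** When the true suprathreshold
  fraction drops below roughly 2.5 % of the ROI, the between-class-variance
  optimum can migrate into the background noise distribution, inflating the
  area fraction and particle count. Default random scenes sit at 2.7–4.2 %
  burden, where recovery is exact across hundreds of seeds; sparser scenes
  (for example, four plaques without specks) intermittently trip this mode.
  On sparse real data, restrict the ROI to the plaque-bearing region or use
  the maximum-entropy threshold, which is less sensitive to foreground
  prevalence.
- Dilation and particle analysis are strictly 2-D per plane; no 3-D
  connectivity or anisotropic z-spacing is modelled.
- The mean + 3 SD count cap is a single pass (see §5) and assumes roughly
  unimodal library-size distributions within each group.
- Scene geometry is constant across z, so per-plane metrics on synthetic
  data are more correlated across planes than in real stacks.
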